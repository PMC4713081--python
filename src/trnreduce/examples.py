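"""Small built-in example networks for demos and documentation."""

from .network import Edge, Effect, NodeKind, RegulatoryNetwork


def hub_example_network() -> RegulatoryNetwork:
    """A 17-node, 26-interaction network around one global hub, TF_G.

    TF_G regulates 10 target genes and 2 TFs; it co-regulates targets
    with both sigma factors (over TG3, TG4, TG7, TG9, TG10 and TF_2) and
    with all 3 other TFs (over TG1, TG4, TG5, TG6, TG8 and TG9).  Its
    globality components are therefore (TFR, GR, SF, CR) = (2, 10, 2, 3)
    and G(TF_G) = 0.82727... — a near-maximal hub score.
    """
    edges = []
    for i in range(1, 11):
        edges.append(Edge("TF_G", f"TG_{i}", Effect.ACTIVATION))
    edges.append(Edge("TF_G", "TF_1", Effect.ACTIVATION))
    edges.append(Edge("TF_G", "TF_2", Effect.REPRESSION))
    for sf, tgt in [
        ("SF_1", "TG_3"),
        ("SF_1", "TG_4"),
        ("SF_1", "TF_2"),
        ("SF_1", "TG_11"),
        ("SF_2", "TG_7"),
        ("SF_2", "TG_9"),
        ("SF_2", "TG_10"),
        ("SF_2", "TG_4"),
    ]:
        edges.append(Edge(sf, tgt, Effect.ACTIVATION))
    for tf, tgt in [
        ("TF_1", "TG_1"),
        ("TF_1", "TG_8"),
        ("TF_2", "TG_4"),
        ("TF_3", "TG_5"),
        ("TF_3", "TG_6"),
        ("TF_3", "TG_9"),
    ]:
        edges.append(Edge(tf, tgt, Effect.REPRESSION))
    nodes = {tf: NodeKind.TF for tf in ("TF_G", "TF_1", "TF_2", "TF_3")}
    nodes.update({sf: NodeKind.SIGMA for sf in ("SF_1", "SF_2")})
    nodes.update({f"TG_{i}": NodeKind.TG for i in range(1, 12)})
    return RegulatoryNetwork(nodes, edges, name="hub_example")
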