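"""Synthetic genome-reduction scenarios for end-to-end pipeline testing.

The generator emulates the full input stack of the analysis: a clock-like
phylogeny of target genomes, a scale-free-ish reference TRN with typed
TFs, irreversible gene loss along the tree with per-type hazards, genome
sizes as an affine function of surviving gene content, and BLAST-tabular
hit tables (plus protein length tables) that the orthology stage can
consume directly.

The central generative assumption is exponential, irreversible loss: a
gene present at a node survives a daughter branch of length t with
probability exp(-lambda * t), where lambda depends on the gene's class
(activator / repressor / dual / unclassified TF, sigma factor, or target
gene).  Ordering the hazards as lambda_act > lambda_rep > lambda_dual
plants, as recoverable ground truth, the pattern that activators are
shed first and dual regulators retained longest as genomes shrink.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .network import (
    Edge,
    Effect,
    GenomeRecord,
    NodeKind,
    RegType,
    RegulatoryNetwork,
    TFAnnotation,
    write_genome_table,
    write_network,
    write_tf_annotations,
)
from .orthology import Hit, write_hit_table


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceSpec:
    """Shape of the synthetic reference network.

    Defaults reproduce the scale of the E. coli template: 196 TFs (190 of
    them with a classified net regulatory type), 7 sigma factors and
    1,581 target genes — 1,784 nodes — wired by 4,058 interactions.
    """

    n_tf: int = 196
    n_sf: int = 7
    n_g: int = 1581
    n_edges: int = 4058
    type_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "activator": 0.40,
            "repressor": 0.35,
            "dual": 0.22,
            "unclassified": 0.03,
        }
    )
    n_nap: int = 12
    hub_exponent: float = 1.0  # regulon sizes ~ rank^-hub_exponent
    regulator_target_fraction: float = 0.07  # extra edges aimed at TFs/sigmas

    def __post_init__(self) -> None:
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type proportions must sum to 1, got {total}")
        if self.n_tf < 1 or self.n_sf < 0 or self.n_g < 0:
            raise ValueError("node counts must be non-negative (n_tf >= 1)")


@dataclass(frozen=True)
class GenomeSizeModel:
    """Affine map from surviving gene count to genome size in bp.

    Defaults anchor the endpoints to realistic gamma-proteobacterial
    scales: a genome retaining all 1,784 network genes sits near 4.6 Mbp
    and one retaining almost none near 0.16 Mbp, the span between a
    free-living enteric genome and a tiny endosymbiont.
    """

    bp_per_gene: float = 2516.0
    intercept: float = 150_000.0
    noise_sd: float = 20_000.0


@dataclass(frozen=True)
class ReductionScenario:
    """Complete specification of one synthetic genome-reduction study."""

    n_genomes: int = 64
    reference_spec: ReferenceSpec = field(default_factory=ReferenceSpec)
    loss_hazards: Mapping[str, float] = field(
        default_factory=lambda: {
            "activator": 0.8,
            "repressor": 0.5,
            "dual": 0.1,
            "unclassified": 0.3,
            "sigma": 0.3,
            "tg": 0.3,
        }
    )
    genome_size_model: GenomeSizeModel = field(default_factory=GenomeSizeModel)
    birth_rate: float = 1.0
    tree_height: float = 1.0  # expected-loss units from root to every tip
    rate_sd: float = 1.0  # lognormal sigma of per-branch loss-rate multipliers
    decoy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        required = {"activator", "repressor", "dual", "unclassified", "sigma", "tg"}
        missing = required - set(self.loss_hazards)
        if missing:
            raise ValueError(f"loss_hazards missing classes: {sorted(missing)}")
        if any(v < 0 for v in self.loss_hazards.values()):
            raise ValueError("hazards must be non-negative")


@dataclass
class HitBundle:
    """Forward/reverse hit tables and length tables for one genome pair."""

    genome_id: str
    forward: list[Hit]
    reverse: list[Hit]
    ref_lengths: dict[str, int]
    target_lengths: dict[str, int]


@dataclass
class ScenarioBundle:
    """Everything one synthetic scenario produces, in memory."""

    scenario: ReductionScenario
    reference: RegulatoryNetwork
    annotations: dict[str, TFAnnotation]
    tree: dendropy.Tree
    presence: dict[str, np.ndarray]  # leaf label -> bool vector over gene_ids
    gene_ids: list[str]
    genome_records: dict[str, GenomeRecord]
    hit_bundles: dict[str, HitBundle]


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def simulate_tree(
    n_leaves: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    height: float | None = None,
    label_prefix: str = "G",
) -> dendropy.Tree:
    """Simulate an ultrametric Yule (pure-birth) tree.

    Lineages split at rate ``birth_rate`` each; after the n-th lineage
    appears, one further exponential waiting time extends all tips to the
    present, so every root-to-tip path has equal length.  If ``height``
    is given, branch lengths are rescaled so that common depth equals it.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active: list[tuple[dendropy.Node, float]] = [(c1, 0.0), (c2, 0.0)]
    t = 0.0
    while len(active) < n_leaves:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.edge.length = t - born
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        active.append((a, t))
        active.append((b, t))
    t += rng.exponential(1.0 / (birth_rate * n_leaves))
    width = len(str(n_leaves))
    for i, (node, born) in enumerate(active):
        node.edge.length = t - born
        node.taxon = taxon_namespace.new_taxon(f"{label_prefix}{i + 1:0{width}d}")
    if height is not None:
        scale = height / t
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return tree


# ---------------------------------------------------------------------------
# Reference network
# ---------------------------------------------------------------------------

def _allocate_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n items across proportions."""
    keys = sorted(proportions)
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_reference_network(
    spec: ReferenceSpec = ReferenceSpec(), seed: int = 0
) -> tuple[RegulatoryNetwork, dict[str, TFAnnotation]]:
    """Build a synthetic reference TRN with exact node and edge totals.

    Out-degrees follow a rank^-gamma weight profile (a few hub regulons,
    many small ones).  Hubs are preferentially dual regulators: the dual
    TFs occupy the top weight ranks, followed by sigma factors, then the
    remaining TFs.  The highest-weight dual TFs are flagged as NAPs and
    the top decile of regulators by realized out-degree as global
    regulators, so that dual type, globality and NAP function correlate
    in the reference, as they do in E. coli.
    """
    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i + 1:03d}" for i in range(spec.n_tf)]
    sf_ids = [f"Sigma{i + 1}" for i in range(spec.n_sf)]
    tg_ids = [f"g{i + 1:04d}" for i in range(spec.n_g)]

    counts = _allocate_counts(spec.n_tf, spec.type_proportions)
    shuffled = list(tf_ids)
    rng.shuffle(shuffled)
    type_of: dict[str, RegType] = {}
    pos = 0
    for type_name in ("dual", "activator", "repressor", "unclassified"):
        for tf in shuffled[pos : pos + counts.get(type_name, 0)]:
            type_of[tf] = RegType(type_name)
        pos += counts.get(type_name, 0)

    # weight ranks: duals first (hubs), then sigmas, then the rest
    duals = [tf for tf in shuffled if type_of[tf] is RegType.DUAL]
    others = [tf for tf in shuffled if type_of[tf] is not RegType.DUAL]
    regulators = duals + sf_ids + others
    weights = np.array(
        [(i + 1.0) ** (-spec.hub_exponent) for i in range(len(regulators))]
    )
    weights /= weights.sum()

    n_regulators = len(regulators)
    edges: set[tuple[str, str]] = set()

    # 1) every target gene gets one regulator (hub-weighted)
    if spec.n_g:
        owners = rng.choice(n_regulators, size=spec.n_g, p=weights)
        for tg, ridx in zip(tg_ids, owners):
            edges.add((regulators[int(ridx)], tg))
    # 2) every regulator gets at least one target
    covered = {r for r, _ in edges}
    for reg in regulators:
        if reg not in covered:
            if spec.n_g:
                edges.add((reg, tg_ids[int(rng.integers(spec.n_g))]))
            else:
                choices = [r for r in regulators if r != reg]
                edges.add((reg, choices[int(rng.integers(len(choices)))]))
    if len(edges) > spec.n_edges:
        raise ValueError(
            f"n_edges={spec.n_edges} too small to cover all "
            f"{n_regulators + spec.n_g} nodes (needs >= {len(edges)})"
        )
    # 3) remaining edges: hub-weighted regulator, mostly TG targets
    while len(edges) < spec.n_edges:
        need = spec.n_edges - len(edges)
        ridx = rng.choice(n_regulators, size=2 * need + 8, p=weights)
        to_reg = rng.random(len(ridx)) < spec.regulator_target_fraction
        for i, r in enumerate(ridx):
            reg = regulators[int(r)]
            if to_reg[i] or not spec.n_g:
                tgt = regulators[int(rng.integers(n_regulators))]
                if tgt == reg:
                    continue
            else:
                tgt = tg_ids[int(rng.integers(spec.n_g))]
            edges.add((reg, tgt))
            if len(edges) >= spec.n_edges:
                break

    nodes: dict[str, NodeKind] = {tf: NodeKind.TF for tf in tf_ids}
    nodes.update({sf: NodeKind.SIGMA for sf in sf_ids})
    nodes.update({tg: NodeKind.TG for tg in tg_ids})

    effect_for = {
        RegType.ACTIVATOR: Effect.ACTIVATION,
        RegType.REPRESSOR: Effect.REPRESSION,
        RegType.UNCLASSIFIED: Effect.UNKNOWN,
    }
    edge_objs = []
    for reg, tgt in sorted(edges):
        if reg in sf_ids or nodes[reg] is NodeKind.SIGMA:
            eff = Effect.ACTIVATION
        else:
            rt = type_of[reg]
            if rt is RegType.DUAL:
                eff = Effect(
                    ("activation", "repression", "dual")[int(rng.integers(3))]
                )
            else:
                eff = effect_for[rt]
        edge_objs.append(Edge(reg, tgt, eff))
    net = RegulatoryNetwork(nodes, edge_objs, name="synthetic_reference")

    # annotations: NAPs sampled among the top-weight duals (not exactly the
    # top-n, so NAP and global flags correlate without coinciding),
    # globality by out-degree
    nap_pool = duals[: min(len(duals), 2 * spec.n_nap)]
    n_nap = min(spec.n_nap, len(nap_pool))
    nap_set = (
        set(rng.choice(nap_pool, size=n_nap, replace=False)) if n_nap else set()
    )
    out_degree = {tf: len(net.targets_of(tf)) for tf in tf_ids}
    n_global = max(1, round(0.1 * spec.n_tf))
    global_set = set(
        sorted(tf_ids, key=lambda tf: (-out_degree[tf], tf))[:n_global]
    )
    annotations = {
        tf: TFAnnotation(
            tf,
            type_of[tf],
            is_nap=tf in nap_set,
            is_global=tf in global_set,
        )
        for tf in tf_ids
    }
    return net, annotations


# ---------------------------------------------------------------------------
# Gene loss along the tree
# ---------------------------------------------------------------------------

def _gene_hazards(
    reference: RegulatoryNetwork,
    annotations: Mapping[str, TFAnnotation],
    hazards: Mapping[str, float],
) -> tuple[list[str], np.ndarray]:
    gene_ids = sorted(reference.nodes)
    lam = np.empty(len(gene_ids))
    for i, g in enumerate(gene_ids):
        kind = reference.kind(g)
        if kind is NodeKind.TG:
            lam[i] = hazards["tg"]
        elif kind is NodeKind.SIGMA:
            lam[i] = hazards["sigma"]
        else:
            ann = annotations.get(g)
            key = ann.reg_type.value if ann is not None else "unclassified"
            lam[i] = hazards[key]
    return gene_ids, lam


def simulate_gene_loss(
    tree: dendropy.Tree,
    reference: RegulatoryNetwork,
    annotations: Mapping[str, TFAnnotation],
    hazards: Mapping[str, float],
    size_model: GenomeSizeModel = GenomeSizeModel(),
    seed: int = 0,
    rate_sd: float = 0.0,
) -> tuple[dict[str, np.ndarray], list[str], dict[str, GenomeRecord]]:
    """Irreversible per-gene loss along the tree.

    Every gene is present at the root.  Along each branch of length t a
    still-present gene survives with probability exp(-lambda * m * t)
    for its class hazard lambda; once lost it is absent in the entire
    subtree.  ``m`` is a per-branch loss-rate multiplier, lognormal with
    median 1 and log-sd ``rate_sd`` (0 = strict loss clock): a relaxed
    clock emulating lifestyle heterogeneity, where host-restricted
    lineages shed genes much faster than free-living ones.  The
    multiplier applies to every gene class alike, so the per-type hazard
    ratios are preserved along every branch.

    Returns (presence-by-leaf boolean vectors, the gene id order those
    vectors index, per-genome records).  Genome size in bp is affine in
    the surviving gene count with Gaussian noise, floored at 1; leaves
    are binned into the four lifestyle categories by quartile of
    surviving gene count (fewest-gene quartile = 'tiny').
    """
    rng = np.random.default_rng(seed)
    gene_ids, lam = _gene_hazards(reference, annotations, hazards)
    n_genes = len(gene_ids)
    presence: dict[str, np.ndarray] = {}
    state: dict[int, np.ndarray] = {id(tree.seed_node): np.ones(n_genes, bool)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = state[id(node.parent_node)]
        t = node.edge.length or 0.0
        m = rng.lognormal(0.0, rate_sd) if rate_sd > 0 else 1.0
        survive = rng.random(n_genes) < np.exp(-lam * m * t)
        node_state = parent_state & survive
        state[id(node)] = node_state
        if node.is_leaf():
            presence[node.taxon.label] = node_state

    counts = {leaf: int(v.sum()) for leaf, v in presence.items()}
    order = sorted(counts, key=lambda g: (counts[g], g))
    n = len(order)
    categories = {}
    for rank, leaf in enumerate(order):
        q = rank / n
        if q < 0.25:
            categories[leaf] = "tiny"
        elif q < 0.5:
            categories[leaf] = "obligate"
        elif q < 0.75:
            categories[leaf] = "host_restricted"
        else:
            categories[leaf] = "free_living"
    records = {}
    for leaf in sorted(presence):
        size = (
            size_model.intercept
            + size_model.bp_per_gene * counts[leaf]
            + rng.normal(0.0, size_model.noise_sd)
        )
        records[leaf] = GenomeRecord(
            leaf, max(1, int(round(size))), categories[leaf]
        )
    return presence, gene_ids, records


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

def _reference_protein_lengths(gene_ids: Sequence[str], seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {g: int(l) for g, l in zip(gene_ids, rng.integers(100, 1001, len(gene_ids)))}


def emit_hit_tables(
    present_genes: Sequence[str],
    genome_id: str,
    ref_lengths: Mapping[str, int],
    seed: int = 0,
    decoy_fraction: float = 0.0,
) -> HitBundle:
    """Synthesize reciprocal BLAST-tabular hits for one genome.

    Every present reference gene gets a forward and a reverse hit against
    its target-genome counterpart, with identity ~ U(35, 95), e-value
    10^-U(8, 50) and 80% coverage — comfortably inside the acceptance
    thresholds.  A ``decoy_fraction`` of additional hits is injected,
    half failing the identity threshold and half lacking a reciprocal
    partner; decoys use fresh gene ids so the recovered ortholog map must
    be exactly the set of present genes.
    """
    rng = np.random.default_rng(seed)
    present = list(present_genes)
    n = len(present)
    identity = rng.uniform(35.0, 95.0, n)
    evalue = 10.0 ** (-rng.uniform(8.0, 50.0, n))
    forward: list[Hit] = []
    reverse: list[Hit] = []
    target_lengths: dict[str, int] = {}
    ref_lengths = dict(ref_lengths)
    for i, g in enumerate(present):
        L = ref_lengths[g]
        t_id = f"{genome_id}|{g}"
        target_lengths[t_id] = L
        aln = int(0.8 * L) + 1
        mism = int(aln * (1.0 - identity[i] / 100.0))
        bits = round(1.9 * aln, 1)
        common = dict(
            percent_identity=round(float(identity[i]), 1),
            alignment_length=aln,
            mismatches=mism,
            gap_opens=0,
            qstart=1,
            qend=aln,
            sstart=1,
            send=aln,
            evalue=float(evalue[i]),
            bitscore=bits,
        )
        forward.append(
            Hit(query_id=g, subject_id=t_id, query_length=L, subject_length=L, **common)
        )
        reverse.append(
            Hit(query_id=t_id, subject_id=g, query_length=L, subject_length=L, **common)
        )

    n_decoys = int(round(decoy_fraction * n))
    for j in range(n_decoys):
        L = int(rng.integers(100, 1001))
        aln = int(0.8 * L) + 1
        if j % 2 == 0:
            # sub-threshold: fails the identity predicate only
            q = f"decoyq_{genome_id}_{j}"
            s = f"{genome_id}|decoys_{j}"
            ident = round(float(rng.uniform(10.0, 29.0)), 1)
        else:
            # passes thresholds but has no reciprocal partner
            q = f"decoyq_{genome_id}_{j}"
            s = f"{genome_id}|decoys_{j}"
            ident = round(float(rng.uniform(35.0, 95.0)), 1)
        ref_lengths[q] = L
        target_lengths[s] = L
        hit = Hit(
            query_id=q,
            subject_id=s,
            percent_identity=ident,
            alignment_length=aln,
            mismatches=int(aln * (1 - ident / 100)),
            gap_opens=0,
            qstart=1,
            qend=aln,
            sstart=1,
            send=aln,
            evalue=float(10.0 ** (-rng.uniform(8.0, 50.0))),
            bitscore=round(1.9 * aln, 1),
            query_length=L,
            subject_length=L,
        )
        forward.append(hit)
        if j % 2 == 0:
            # give the sub-threshold decoy a reciprocal (also sub-threshold)
            reverse.append(
                hit._replace(query_id=s, subject_id=q)
            )
        # odd decoys: forward-only, hence non-reciprocal
    return HitBundle(
        genome_id=genome_id,
        forward=forward,
        reverse=reverse,
        ref_lengths=ref_lengths,
        target_lengths=target_lengths,
    )


# ---------------------------------------------------------------------------
# Brownian traits
# ---------------------------------------------------------------------------

def simulate_brownian_trait(
    tree: dendropy.Tree,
    rate: float = 1.0,
    root_value: float = 0.0,
    seed: int = 0,
) -> dict[str, float]:
    """Evolve a continuous trait by Brownian motion along the tree.

    child = parent + Normal(0, rate * branch_length); the returned map
    gives the trait value at each leaf.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.seed_node): float(root_value)}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        v = values[id(node.parent_node)] + rng.normal(0.0, np.sqrt(rate * t))
        values[id(node)] = v
        if node.is_leaf():
            out[node.taxon.label] = float(v)
    return out


# ---------------------------------------------------------------------------
# Whole scenarios
# ---------------------------------------------------------------------------

def generate_scenario(scenario: ReductionScenario = ReductionScenario()) -> ScenarioBundle:
    """Generate every input the pipeline needs, deterministically by seed."""
    ss = np.random.SeedSequence(scenario.seed)
    seeds = ss.generate_state(4)
    tree = simulate_tree(
        scenario.n_genomes,
        birth_rate=scenario.birth_rate,
        seed=int(seeds[0]),
        height=scenario.tree_height,
    )
    reference, annotations = simulate_reference_network(
        scenario.reference_spec, seed=int(seeds[1])
    )
    presence, gene_ids, records = simulate_gene_loss(
        tree,
        reference,
        annotations,
        scenario.loss_hazards,
        scenario.genome_size_model,
        seed=int(seeds[2]),
        rate_sd=scenario.rate_sd,
    )
    ref_lengths = _reference_protein_lengths(gene_ids, int(seeds[3]))
    hit_bundles = {}
    hit_seed_root = np.random.SeedSequence(int(seeds[3]))
    child_seeds = hit_seed_root.generate_state(len(presence) + 1)[1:]
    for i, leaf in enumerate(sorted(presence)):
        mask = presence[leaf]
        present = [g for g, m in zip(gene_ids, mask) if m]
        hit_bundles[leaf] = emit_hit_tables(
            present,
            leaf,
            ref_lengths,
            seed=int(child_seeds[i]),
            decoy_fraction=scenario.decoy_fraction,
        )
    return ScenarioBundle(
        scenario=scenario,
        reference=reference,
        annotations=annotations,
        tree=tree,
        presence=presence,
        gene_ids=gene_ids,
        genome_records=records,
        hit_bundles=hit_bundles,
    )


def write_scenario(bundle: ScenarioBundle, out_dir: str | Path) -> Path:
    """Write a scenario to disk in every dialect the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_network(bundle.reference, out / "reference_network.tsv")
    write_tf_annotations(bundle.annotations, out / "tf_annotations.tsv")
    write_genome_table(bundle.genome_records, out / "genomes.tsv")
    with (out / "tree.nwk").open("w", encoding="utf-8") as fh:
        fh.write(
            bundle.tree.as_string(schema="newick", suppress_rooting=True)
        )
    with (out / "reference_lengths.tsv").open("w", encoding="utf-8") as fh:
        for g in bundle.gene_ids:
            fh.write(f"{g}\t{bundle.hit_bundles[next(iter(sorted(bundle.presence)))].ref_lengths[g]}\n")
    hits_dir = out / "hits"
    hits_dir.mkdir(exist_ok=True)
    for leaf, hb in bundle.hit_bundles.items():
        write_hit_table(hb.forward, hits_dir / f"{leaf}.forward.tsv")
        write_hit_table(hb.reverse, hits_dir / f"{leaf}.reverse.tsv")
        with (hits_dir / f"{leaf}.ref_lengths.tsv").open("w", encoding="utf-8") as fh:
            for g, L in sorted(hb.ref_lengths.items()):
                fh.write(f"{g}\t{L}\n")
        with (hits_dir / f"{leaf}.target_lengths.tsv").open("w", encoding="utf-8") as fh:
            for g, L in sorted(hb.target_lengths.items()):
                fh.write(f"{g}\t{L}\n")
    return out
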