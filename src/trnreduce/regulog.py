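"""Regulog reconstruction of target-genome TRNs from a reference network.

The regulog rule: if a regulatory interaction TF -> TG is known in the
reference network and both endpoints have orthologs in a target genome,
the interaction is inferred as conserved there.  This module applies that
rule and tabulates, per genome, the conserved transcription factors by
their net regulatory type (activator / repressor / dual).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

from .network import (
    Edge,
    NodeKind,
    RegType,
    RegulatoryNetwork,
    TFAnnotation,
)
from .orthology import OrthologMap


class UndefinedFractionError(ValueError):
    """Raised when TF-type fractions are requested for a genome that
    conserves no transcription factor (n = 0)."""


@dataclass(frozen=True)
class TypeCounts:
    """Conserved-TF counts for one genome.

    ``n`` is the number of reference TFs with an ortholog in the genome;
    it includes unclassified TFs, so the per-type counts need not sum to
    ``n``.
    """

    genome_id: str
    n: int
    k_activators: int
    k_repressors: int
    k_duals: int

    def __post_init__(self) -> None:
        if self.k_activators + self.k_repressors + self.k_duals > self.n:
            raise ValueError("type counts exceed total conserved TFs")

    def k_of(self, reg_type: RegType) -> int:
        return {
            RegType.ACTIVATOR: self.k_activators,
            RegType.REPRESSOR: self.k_repressors,
            RegType.DUAL: self.k_duals,
        }[reg_type]


def reconstruct_trn(
    reference: RegulatoryNetwork, omap: OrthologMap
) -> RegulatoryNetwork:
    """Project the reference network through an ortholog map.

    Nodes are the target-genome orthologs of reference nodes, keeping the
    reference kind; an edge survives iff both its endpoints have
    orthologs.  Orthologous nodes whose every reference interaction
    involves a lost partner are retained as isolated nodes.
    """
    mapping = omap.by_ref
    unknown = set(mapping) - set(reference.nodes)
    if unknown:
        raise ValueError(
            f"ortholog map names genes absent from the reference network: "
            f"{sorted(unknown)[:5]}"
        )
    nodes = {t: reference.kind(r) for r, t in mapping.items()}
    edges = [
        Edge(mapping[e.regulator], mapping[e.target], e.effect)
        for e in reference.edges
        if e.regulator in mapping and e.target in mapping
    ]
    return RegulatoryNetwork(nodes, edges, name=omap.genome_id or "reconstructed")


def count_conserved_tf_types(
    reference: RegulatoryNetwork,
    omap: OrthologMap,
    annotations: Mapping[str, TFAnnotation],
) -> TypeCounts:
    """Count conserved TFs by regulatory type.

    ``n`` counts every reference TF with an ortholog (sigma factors are
    never counted); ``k_type`` counts, among those, the TFs annotated
    with the given net regulatory type.  A conserved TF missing from the
    annotation table is counted in ``n`` only, with a warning.
    """
    conserved_tfs = [
        r for r in omap.by_ref if reference.kind(r) is NodeKind.TF
    ]
    k = {RegType.ACTIVATOR: 0, RegType.REPRESSOR: 0, RegType.DUAL: 0}
    for tf in conserved_tfs:
        ann = annotations.get(tf)
        if ann is None:
            warnings.warn(
                f"conserved TF {tf!r} has no annotation; counted in n only",
                stacklevel=2,
            )
            continue
        if ann.reg_type in k:
            k[ann.reg_type] += 1
    return TypeCounts(
        genome_id=omap.genome_id,
        n=len(conserved_tfs),
        k_activators=k[RegType.ACTIVATOR],
        k_repressors=k[RegType.REPRESSOR],
        k_duals=k[RegType.DUAL],
    )


def tf_fractions(tc: TypeCounts) -> tuple[float, float, float]:
    """Per-type fractions (activator, repressor, dual) of conserved TFs.

    The denominator is ``n``, the total conserved-TF count (unclassified
    TFs included), so fractions sum to at most 1.
    """
    if tc.n == 0:
        raise UndefinedFractionError(
            f"genome {tc.genome_id!r} conserves no TFs; fractions undefined"
        )
    return (
        tc.k_activators / tc.n,
        tc.k_repressors / tc.n,
        tc.k_duals / tc.n,
    )
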