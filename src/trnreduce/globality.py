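"""Global-regulator metric G(x) for transcription factors in a TRN.

The score aggregates four normalized connectivity components of a TF x:

* TFR(x): regulators (TFs or sigma factors) that x regulates, normalized
  by N_TF + N_SF - 1 (every other regulator in the network);
* GR(x): non-regulatory target genes x regulates, normalized by N_G;
* SF(x): sigma factors sharing at least one target with x, normalized by
  N_SF;
* CR(x): other TFs sharing at least one target with x, normalized by
  N_TF - 1.

G(x) is the mean of the four ratios and lies in [0, 1]; hubs score high.
Auto-regulation is excluded from TFR and CR, matching the "-1"
denominators that exclude x itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .network import NodeKind, RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GlobalityScore:
    tf_id: str
    TFR: int
    GR: int
    SF: int
    CR: int
    G: float
    rank: int | None = None
    is_global: bool = False


def tf_regulatory_stats(
    net: RegulatoryNetwork, tf_id: str
) -> tuple[int, int, int, int]:
    """Return (TFR, GR, SF, CR) for one TF.

    SF and CR count co-regulators: sigma factors (resp. other TFs) with
    at least one target in common with x, targets of any kind.
    """
    if tf_id not in net.nodes:
        raise KeyError(f"unknown node id {tf_id!r}")
    if net.kind(tf_id) is not NodeKind.TF:
        raise ValueError(f"node {tf_id!r} is not a TF")
    targets = net.targets_of(tf_id)
    tfr = sum(
        1
        for t in targets
        if t != tf_id and net.kind(t) in (NodeKind.TF, NodeKind.SIGMA)
    )
    gr = sum(1 for t in targets if net.kind(t) is NodeKind.TG)
    co_regulators: set[str] = set()
    for t in targets:
        co_regulators |= net.regulators_of(t)
    co_regulators.discard(tf_id)
    sf = sum(1 for c in co_regulators if net.kind(c) is NodeKind.SIGMA)
    cr = sum(1 for c in co_regulators if net.kind(c) is NodeKind.TF)
    return tfr, gr, sf, cr


def globality_score(
    stats: tuple[int, int, int, int], summary: tuple[int, int, int]
) -> float:
    """G = (TFR/(N_TF+N_SF-1) + GR/N_G + SF/N_SF + CR/(N_TF-1)) / 4.

    A non-positive denominator makes the corresponding term degenerate
    (the network has nothing of that kind to regulate or co-regulate
    with); the term contributes 0 and a warning is logged.
    """
    tfr, gr, sf, cr = stats
    n_tf, n_sf, n_g = summary
    terms = (
        (tfr, n_tf + n_sf - 1, "TFR"),
        (gr, n_g, "GR"),
        (sf, n_sf, "SF"),
        (cr, n_tf - 1, "CR"),
    )
    total = 0.0
    for numer, denom, label in terms:
        if denom <= 0:
            logger.warning(
                "degenerate network: %s denominator %d <= 0; term set to 0",
                label,
                denom,
            )
            continue
        total += numer / denom
    return total / 4.0


def score_tf(net: RegulatoryNetwork, tf_id: str) -> GlobalityScore:
    stats = tf_regulatory_stats(net, tf_id)
    g = globality_score(stats, (net.n_tf, net.n_sf, net.n_g))
    return GlobalityScore(tf_id, *stats, G=g)


def rank_global_regulators(
    net: RegulatoryNetwork, global_quantile: float = 0.9
) -> list[GlobalityScore]:
    """Score every TF and rank descending by G (ties lexicographic).

    TFs in the top (1 - global_quantile) share of the G distribution are
    flagged as global regulators; the decile cutoff is a configurable
    operational convention, not a biological constant.
    """
    scored = [score_tf(net, tf) for tf in sorted(net.ids_of_kind(NodeKind.TF))]
    scored.sort(key=lambda s: (-s.G, s.tf_id))
    if not scored:
        return []
    gs = sorted(s.G for s in scored)
    idx = min(int(global_quantile * len(gs)), len(gs) - 1)
    cutoff = gs[idx]
    return [
        GlobalityScore(
            s.tf_id,
            s.TFR,
            s.GR,
            s.SF,
            s.CR,
            s.G,
            rank=i + 1,
            is_global=s.G >= cutoff and s.G > 0,
        )
        for i, s in enumerate(scored)
    ]
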