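"""End-to-end orchestration: orthology -> regulog -> conservation tests ->
globality -> independent contrasts -> multivariate regression.

The entry point is :func:`run_pipeline`, which takes the full input stack
(reference network, TF annotations, per-genome hit tables, genome
metadata, phylogeny) and returns every intermediate and final table as a
:class:`PipelineResult`.  :func:`write_report` serializes the result as
TSVs plus a human-readable summary; :func:`run_full_analysis` wires both
to a config of file paths for the CLI.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from . import conservation, globality, pic, regulog
from .conservation import CombinedResult, ConservationTest, ReferenceTypeCounts
from .network import (
    CLASSIFIED_TYPES,
    GenomeRecord,
    NodeKind,
    RegType,
    RegulatoryNetwork,
    TFAnnotation,
    read_genome_table,
    read_network,
    read_tf_annotations,
    write_network,
)
from .orthology import (
    OrthologMap,
    Thresholds,
    bidirectional_best_hits,
    read_hit_table,
    read_length_table,
)
from .regression import (
    RegressionResult,
    compare_predictors,
    fit_multivariate,
    predictor_redundancy,
)
from .simulate import ScenarioBundle

logger = logging.getLogger(__name__)

#: Variables carried into the contrast analyses, each paired against
#: genome size (the S5-style variable list).
CONTRAST_VARIABLES = (
    "genome_size",
    "freq_activators",
    "freq_repressors",
    "freq_duals",
    "frac_activators",
    "frac_repressors",
    "frac_duals",
    "frac_global",
    "frac_nap",
)


@dataclass(frozen=True)
class PipelineConfig:
    thresholds: Thresholds = Thresholds()
    alpha: float = 0.05
    global_quantile: float = 0.9
    positivize: bool = True
    regression_mode: str = "raw"  # "raw" (with intercept) or "contrasts"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.regression_mode not in ("raw", "contrasts"):
            raise ValueError("regression_mode must be 'raw' or 'contrasts'")


@dataclass
class PipelineResult:
    config: PipelineConfig
    ortholog_maps: dict[str, OrthologMap]
    reconstructed: dict[str, RegulatoryNetwork]
    type_counts: pd.DataFrame
    conservation_tests: pd.DataFrame
    combined: dict[RegType, CombinedResult]
    reference_globality: pd.DataFrame
    traits: pd.DataFrame
    contrast_stats: pd.DataFrame
    regressions: dict[RegType, RegressionResult]
    predictor_redundancy_r: float


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def reference_type_counts(
    reference: RegulatoryNetwork, annotations: Mapping[str, TFAnnotation]
) -> ReferenceTypeCounts:
    """Tally the reference TF pool: N total, K per classified type."""
    tf_ids = reference.ids_of_kind(NodeKind.TF)
    k = {t: 0 for t in CLASSIFIED_TYPES}
    for tf in tf_ids:
        ann = annotations.get(tf)
        if ann is not None and ann.reg_type in k:
            k[ann.reg_type] += 1
    return ReferenceTypeCounts(
        N=len(tf_ids),
        K_activators=k[RegType.ACTIVATOR],
        K_repressors=k[RegType.REPRESSOR],
        K_duals=k[RegType.DUAL],
    )


def genome_trait_table(
    reference: RegulatoryNetwork,
    annotations: Mapping[str, TFAnnotation],
    ortholog_maps: Mapping[str, OrthologMap],
    genome_records: Mapping[str, GenomeRecord],
) -> pd.DataFrame:
    """Per-genome trait table for contrasts and regression.

    Count traits (freq_*) are defined for every genome; fraction traits
    are NaN for genomes conserving no TF (n = 0), which are pruned from
    the corresponding contrast analyses.
    """
    rows = []
    for gid in sorted(ortholog_maps):
        omap = ortholog_maps[gid]
        tc = regulog.count_conserved_tf_types(reference, omap, annotations)
        conserved_tfs = [
            r for r in omap.by_ref if reference.kind(r) is NodeKind.TF
        ]
        n_global = sum(
            1 for tf in conserved_tfs
            if tf in annotations and annotations[tf].is_global
        )
        n_nap = sum(
            1 for tf in conserved_tfs
            if tf in annotations and annotations[tf].is_nap
        )
        row = {
            "genome_id": gid,
            "genome_size": genome_records[gid].size_bp,
            "category": genome_records[gid].category,
            "n_conserved_tfs": tc.n,
            "freq_activators": tc.k_activators,
            "freq_repressors": tc.k_repressors,
            "freq_duals": tc.k_duals,
        }
        if tc.n > 0:
            f_act, f_rep, f_dual = regulog.tf_fractions(tc)
            row.update(
                frac_activators=f_act,
                frac_repressors=f_rep,
                frac_duals=f_dual,
                frac_global=n_global / tc.n,
                frac_nap=n_nap / tc.n,
            )
        else:
            row.update(
                frac_activators=np.nan,
                frac_repressors=np.nan,
                frac_duals=np.nan,
                frac_global=np.nan,
                frac_nap=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("genome_id")


def contrast_analysis(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    x_var: str = "genome_size",
    variables: tuple[str, ...] = CONTRAST_VARIABLES,
    positivize: bool = True,
) -> pd.DataFrame:
    """Standardized contrasts of every variable against ``x_var``.

    For each variable the tree is pruned to the genomes where both the
    variable and ``x_var`` are defined, contrasts are computed on the
    pruned tree, x-contrasts are positivized (paired y signs flipped),
    and correlation and regression through the origin are reported.
    """
    work_tree = tree
    if not pic.is_bifurcating(work_tree):
        work_tree = pic.resolve_polytomies(work_tree, seed=0)
    rows = []
    for var in variables:
        cols = [x_var] if var == x_var else [x_var, var]
        sub = traits[cols].dropna()
        leaves = [l for l in pic.leaf_labels(work_tree) if l in sub.index]
        if len(leaves) < 3:
            logger.warning("variable %s defined on <3 genomes; skipped", var)
            continue
        t = (
            work_tree
            if len(leaves) == len(pic.leaf_labels(work_tree))
            else pic.prune_to_leaves(work_tree, leaves)
        )
        cx = pic.compute_contrasts(t, sub[x_var].to_dict(), trait_name=x_var)
        cy = pic.compute_contrasts(t, sub[var].to_dict(), trait_name=var)
        if positivize:
            cx, cy = pic.positivize(cx, cy)
        try:
            corr = pic.correlation_through_origin(cx, cy)
            reg = pic.regression_through_origin(cx, cy)
        except ValueError as exc:
            logger.warning("contrast stats for %s undefined: %s", var, exc)
            continue
        rows.append(
            {
                "x": x_var,
                "y": var,
                "n_genomes": len(leaves),
                "n_contrasts": cx.n_contrasts,
                "r": corr.r,
                "t": corr.t,
                "df": corr.df,
                "p": corr.p,
                "slope": reg.slope,
                "slope_se": reg.se,
                "slope_p": reg.p,
            }
        )
    return pd.DataFrame(rows)


def _tests_frame(tests: list[ConservationTest]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome_id": t.genome_id,
            "tf_type": t.tf_type.value,
            "N": t.N,
            "K": t.K,
            "n": t.n,
            "k": t.k,
            "f_i": t.f_i,
            "f_r": t.f_r,
            "p_value": t.p_value,
            "status": "ok" if t.testable else "untestable",
            "reject_at_alpha": t.reject_at_alpha,
        }
        for t in tests
    )


# ---------------------------------------------------------------------------
# The full run
# ---------------------------------------------------------------------------

def run_pipeline(
    reference: RegulatoryNetwork,
    annotations: Mapping[str, TFAnnotation],
    hit_bundles: Mapping[str, "object"],
    genome_records: Mapping[str, GenomeRecord],
    tree: dendropy.Tree,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Execute every analysis stage on in-memory inputs.

    ``hit_bundles`` maps genome id to an object with ``forward`` and
    ``reverse`` hit lists (e.g. :class:`trnreduce.simulate.HitBundle`).
    """
    # 1) orthology
    ortholog_maps = {
        gid: bidirectional_best_hits(
            hb.forward, hb.reverse, config.thresholds, genome_id=gid
        )
        for gid, hb in hit_bundles.items()
    }
    return run_pipeline_from_orthologs(
        reference, annotations, ortholog_maps, genome_records, tree, config
    )


def run_pipeline_from_orthologs(
    reference: RegulatoryNetwork,
    annotations: Mapping[str, TFAnnotation],
    ortholog_maps: Mapping[str, OrthologMap],
    genome_records: Mapping[str, GenomeRecord],
    tree: dendropy.Tree,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Pipeline stages downstream of orthology."""
    # 2) regulog reconstruction + per-genome counts
    reconstructed = {
        gid: regulog.reconstruct_trn(reference, omap)
        for gid, omap in ortholog_maps.items()
    }
    ref_counts = reference_type_counts(reference, annotations)
    tests: list[ConservationTest] = []
    for gid in sorted(ortholog_maps):
        tc = regulog.count_conserved_tf_types(
            reference, ortholog_maps[gid], annotations
        )
        for tf_type in CLASSIFIED_TYPES:
            tests.append(
                conservation.conservation_test(
                    ref_counts, tc, tf_type, alpha=config.alpha
                )
            )
    combined = {
        tf_type: conservation.combine_by_type(tests, tf_type)
        for tf_type in CLASSIFIED_TYPES
    }

    # 3) reference globality ranking
    scored = globality.rank_global_regulators(
        reference, global_quantile=config.global_quantile
    )
    ref_glob = pd.DataFrame(
        {
            "tf_id": s.tf_id,
            "TFR": s.TFR,
            "GR": s.GR,
            "SF": s.SF,
            "CR": s.CR,
            "G": s.G,
            "rank": s.rank,
            "is_global": s.is_global,
        }
        for s in scored
    )

    # 4) traits + contrasts
    traits = genome_trait_table(
        reference, annotations, ortholog_maps, genome_records
    )
    type_counts = traits[
        ["n_conserved_tfs", "freq_activators", "freq_repressors", "freq_duals"]
    ].copy()
    contrast_stats = contrast_analysis(
        tree, traits, positivize=config.positivize
    )

    # 5) multivariate regression per TF type
    regressions: dict[RegType, RegressionResult] = {}
    reg_data = traits.dropna(
        subset=["frac_activators", "frac_repressors", "frac_duals",
                "frac_global", "frac_nap"]
    )
    criterion_col = {
        RegType.ACTIVATOR: "frac_activators",
        RegType.REPRESSOR: "frac_repressors",
        RegType.DUAL: "frac_duals",
    }
    if config.regression_mode == "raw":
        X = reg_data[["genome_size", "frac_global", "frac_nap"]].to_numpy()
        for tf_type, col in criterion_col.items():
            regressions[tf_type] = fit_multivariate(
                reg_data[col].to_numpy(), X, criterion=col
            )
        redundancy_r, _ = predictor_redundancy(
            reg_data["frac_global"].to_numpy(), reg_data["frac_nap"].to_numpy()
        )
    else:
        # origin-constrained regression on contrasts of each predictor
        redundancy_r, regressions = _contrast_mode_regression(
            tree, traits, criterion_col
        )

    return PipelineResult(
        config=config,
        ortholog_maps=dict(ortholog_maps),
        reconstructed=reconstructed,
        type_counts=type_counts,
        conservation_tests=_tests_frame(tests),
        combined=combined,
        reference_globality=ref_glob,
        traits=traits,
        contrast_stats=contrast_stats,
        regressions=regressions,
        predictor_redundancy_r=redundancy_r,
    )


def _contrast_mode_regression(tree, traits, criterion_col):
    """Regression on standardized contrasts (no intercept in spirit, but
    fit with one on the contrast scale for coefficient comparability)."""
    cols = ["genome_size", "frac_global", "frac_nap"] + list(criterion_col.values())
    sub = traits[cols].dropna()
    work = tree
    if not pic.is_bifurcating(work):
        work = pic.resolve_polytomies(work, seed=0)
    leaves = [l for l in pic.leaf_labels(work) if l in sub.index]
    t = (
        work
        if len(leaves) == len(pic.leaf_labels(work))
        else pic.prune_to_leaves(work, leaves)
    )
    con = {
        c: pic.compute_contrasts(t, sub[c].to_dict(), trait_name=c).standardized
        for c in cols
    }
    X = np.column_stack([con["genome_size"], con["frac_global"], con["frac_nap"]])
    regressions = {}
    for tf_type, col in criterion_col.items():
        regressions[tf_type] = fit_multivariate(
            con[col], X, criterion=col + "_contrasts"
        )
    r, _ = predictor_redundancy(con["frac_global"], con["frac_nap"])
    return r, regressions


def run_pipeline_on_bundle(
    bundle: ScenarioBundle, config: PipelineConfig = PipelineConfig()
) -> PipelineResult:
    """Convenience wrapper: run the full pipeline on a synthetic scenario."""
    return run_pipeline(
        bundle.reference,
        bundle.annotations,
        bundle.hit_bundles,
        bundle.genome_records,
        bundle.tree,
        config,
    )


# ---------------------------------------------------------------------------
# Reporting and file-based entry point
# ---------------------------------------------------------------------------

def write_report(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write every pipeline table as TSV plus a summary.txt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nets_dir = out / "reconstructed_networks"
    nets_dir.mkdir(exist_ok=True)
    for gid in sorted(result.reconstructed):
        write_network(result.reconstructed[gid], nets_dir / f"{gid}.tsv")
    result.type_counts.to_csv(out / "type_counts.tsv", sep="\t")
    result.conservation_tests.to_csv(
        out / "conservation_tests.tsv", sep="\t", index=False
    )
    result.reference_globality.to_csv(
        out / "reference_globality.tsv", sep="\t", index=False
    )
    result.traits.to_csv(out / "genome_traits.tsv", sep="\t")
    result.contrast_stats.to_csv(out / "contrast_stats.tsv", sep="\t", index=False)

    comb_rows = [
        {
            "tf_type": t.value,
            "statistic": c.statistic,
            "df": c.degrees_of_freedom,
            "combined_p": c.combined_p,
            "n_tests": c.n_tests,
        }
        for t, c in result.combined.items()
    ]
    pd.DataFrame(comb_rows).to_csv(out / "combined_pvalues.tsv", sep="\t", index=False)

    reg_rows = []
    for tf_type, rr in result.regressions.items():
        for name, b, p in zip(rr.predictors, rr.standardized_b, rr.p_values[1:]):
            reg_rows.append(
                {
                    "criterion": rr.criterion,
                    "predictor": name,
                    "b": b,
                    "p_value": p,
                    "r_squared": rr.r_squared,
                    "n": rr.n,
                }
            )
    pd.DataFrame(reg_rows).to_csv(out / "regression_table.tsv", sep="\t", index=False)

    lines = ["trnreduce pipeline summary", "=" * 30, ""]
    lines.append("Fisher-combined conservation p-values:")
    for t, c in result.combined.items():
        lines.append(
            f"  {t.value:<10s} X={c.statistic:.3f} df={c.degrees_of_freedom} "
            f"p={c.combined_p:.3e} ({c.n_tests} genomes)"
        )
    untestable = result.conservation_tests.query("status == 'untestable'")[
        "genome_id"
    ].unique()
    lines.append(f"Untestable genomes (n=0): {', '.join(untestable) or 'none'}")
    lines.append("")
    lines.append("Contrast correlations vs genome size (through origin):")
    for _, row in result.contrast_stats.iterrows():
        lines.append(
            f"  {row['y']:<18s} r={row['r']:+.3f} p={row['p']:.3e} "
            f"slope={row['slope']:+.3e}"
        )
    lines.append("")
    lines.append("Standardized partial regression coefficients:")
    for tf_type, rr in result.regressions.items():
        coef = ", ".join(
            f"{nm}: b={b:+.2f} (p={p:.3g})"
            for nm, b, p in zip(rr.predictors, rr.standardized_b, rr.p_values[1:])
        )
        lines.append(f"  {rr.criterion:<18s} {coef}")
        ranked = compare_predictors(rr)
        influential = [e.name for e in ranked if e.significant]
        lines.append(f"    influential: {', '.join(influential) or 'none'}")
    lines.append("")
    lines.append(
        f"Pearson r(global fraction, NAP fraction) = "
        f"{result.predictor_redundancy_r:+.3f}"
    )
    (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out


@dataclass(frozen=True)
class InputPaths:
    network: Path
    annotations: Path
    genomes: Path
    tree: Path
    hits_dir: Path  # per genome: <id>.forward.tsv, <id>.reverse.tsv, length tables


def load_hit_bundles(hits_dir: str | Path, genome_ids) -> dict[str, "object"]:
    """Load per-genome forward/reverse hit tables written by the scenario
    writer (or by a BLAST post-processing step following the same layout)."""
    from .simulate import HitBundle

    hits_dir = Path(hits_dir)
    out = {}
    for gid in genome_ids:
        ref_len = read_length_table(hits_dir / f"{gid}.ref_lengths.tsv")
        tgt_len = read_length_table(hits_dir / f"{gid}.target_lengths.tsv")
        fwd = read_hit_table(hits_dir / f"{gid}.forward.tsv", ref_len, tgt_len)
        rev = read_hit_table(hits_dir / f"{gid}.reverse.tsv", tgt_len, ref_len)
        out[gid] = HitBundle(gid, fwd, rev, ref_len, tgt_len)
    return out


def run_full_analysis(
    paths: InputPaths,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> Path:
    """File-based full run: read all inputs, run every stage, write the
    report directory.  Any stage failure leaves a FAILED marker naming
    the stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    try:
        reference = read_network(paths.network)
        annotations = read_tf_annotations(paths.annotations)
        genome_records = read_genome_table(paths.genomes)
        tree = pic.read_newick(paths.tree)
        bundles = load_hit_bundles(paths.hits_dir, sorted(genome_records))
        stage = "pipeline"
        result = run_pipeline(
            reference, annotations, bundles, genome_records, tree, config
        )
        stage = "report"
        write_report(result, out)
    except Exception as exc:
        (out / "FAILED").write_text(
            f"stage={stage}\nerror={type(exc).__name__}: {exc}\n",
            encoding="utf-8",
        )
        raise
    return out
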