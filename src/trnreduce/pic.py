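"""Felsenstein's phylogenetically independent contrasts (PIC).

Trait values observed at the tips of a phylogeny are not independent
samples: closely related lineages inherit correlated values.  Under a
Brownian-motion model of trait evolution, the differences ("contrasts")
between the two daughters at each bifurcation, divided by the square root
of their summed expected variances, are independent and identically
distributed N(0, sigma^2).  The recursion also produces a weighted
ancestral value at each node and augments the node's own branch length by
v_a*v_b/(v_a+v_b) to carry the uncertainty upward.

Because contrasts have an arbitrary sign (which daughter is subtracted
from which), bivariate analyses are done through the origin after
"positivizing" the X-axis contrasts: wherever an x-contrast is negative,
the signs of both the x- and the paired y-contrast are flipped.
Correlation and regression through the origin then use n_contrasts - 1
degrees of freedom.

Trees are handled with dendropy; branch lengths are in expected-variance
units of the Brownian model.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class NewickError(ValueError):
    pass


class DegenerateVarianceError(ValueError):
    pass


@dataclass(frozen=True)
class Contrast:
    node_id: str
    raw: float
    standardized: float
    combined_variance: float


@dataclass(frozen=True)
class ContrastSet:
    trait_name: str
    contrasts: tuple[Contrast, ...]

    @property
    def n_contrasts(self) -> int:
        return len(self.contrasts)

    @property
    def standardized(self) -> np.ndarray:
        return np.array([c.standardized for c in self.contrasts])

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(c.node_id for c in self.contrasts)


# ---------------------------------------------------------------------------
# Tree I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree with branch lengths.

    The Newick root is taken as the tree root; input explicitly marked
    unrooted (``[&U]``) is rejected.
    """
    if "[&U]" in text or "[&u]" in text:
        raise NewickError("unrooted tree rejected; PIC requires a rooted tree")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"newick parse error: {exc}") from exc
    leaf_ids = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaf_ids)) != len(leaf_ids):
        raise NewickError("duplicate leaf labels")
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def resolve_polytomies(tree: dendropy.Tree, seed: int = 0) -> dendropy.Tree:
    """Return a strictly bifurcating copy of the tree.

    Multifurcations are expanded into caterpillars of zero-length
    internal branches; the expansion order is deterministic for a given
    seed.
    """
    out = tree.clone(depth=1)
    rng = random.Random(seed)
    out.resolve_polytomies(rng=rng)
    for edge in out.preorder_edge_iter():
        if edge.head_node is not out.seed_node and edge.length is None:
            edge.length = 0.0
    return out


def is_bifurcating(tree: dendropy.Tree) -> bool:
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) != 2:
            return False
    return True


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def compute_contrasts(
    tree: dendropy.Tree,
    trait: Mapping[str, float],
    trait_name: str = "trait",
    zero_branch_epsilon: float = 1e-8,
) -> ContrastSet:
    """Compute standardized independent contrasts for one trait.

    Post-order over a bifurcating tree: at each internal node with
    daughters (a, b) carrying working values (x_a, x_b) and adjusted
    branch lengths (v_a, v_b),

        raw       = x_a - x_b
        variance  = v_a + v_b
        contrast  = raw / sqrt(variance)
        ancestor  = (x_a/v_a + x_b/v_b) / (1/v_a + 1/v_b)

    and the node's own branch length is augmented by v_a*v_b/(v_a+v_b).
    When both daughter variances are zero the contrast is degenerate; if
    ``zero_branch_epsilon`` is positive the two variances are perturbed
    by it (logged), otherwise a DegenerateVarianceError is raised.
    """
    missing = [
        lf.taxon.label
        for lf in tree.leaf_node_iter()
        if lf.taxon.label not in trait
    ]
    if missing:
        raise KeyError(f"trait undefined for leaves: {missing[:5]}")
    if not is_bifurcating(tree):
        raise ValueError("tree has polytomies; resolve them first")

    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    contrasts: list[Contrast] = []
    counter = 0
    for node in tree.postorder_node_iter():
        edge_len = node.edge.length if node.edge.length is not None else 0.0
        if node.is_leaf():
            values[id(node)] = float(trait[node.taxon.label])
            lengths[id(node)] = float(edge_len)
            continue
        a, b = node.child_nodes()
        xa, xb = values[id(a)], values[id(b)]
        va, vb = lengths[id(a)], lengths[id(b)]
        if va + vb == 0.0:
            node_id = node.label or f"node{counter}"
            if zero_branch_epsilon and zero_branch_epsilon > 0:
                logger.warning(
                    "zero combined variance at %s; perturbing daughter "
                    "branches by %g",
                    node_id,
                    zero_branch_epsilon,
                )
                va = vb = zero_branch_epsilon
            else:
                raise DegenerateVarianceError(
                    f"combined variance is zero at node {node_id}"
                )
        raw = xa - xb
        var = va + vb
        contrasts.append(
            Contrast(
                node_id=node.label or f"node{counter}",
                raw=raw,
                standardized=raw / math.sqrt(var),
                combined_variance=var,
            )
        )
        counter += 1
        values[id(node)] = (xa / va + xb / vb) / (1.0 / va + 1.0 / vb)
        lengths[id(node)] = float(edge_len) + va * vb / (va + vb)
    return ContrastSet(trait_name=trait_name, contrasts=tuple(contrasts))


def positivize(cx: ContrastSet, cy: ContrastSet) -> tuple[ContrastSet, ContrastSet]:
    """Flip paired contrast signs so every x-contrast is non-negative."""
    if cx.node_ids != cy.node_ids:
        raise ValueError("contrast sets come from different trees or orders")
    new_x, new_y = [], []
    for a, b in zip(cx.contrasts, cy.contrasts):
        if a.standardized < 0:
            a = Contrast(a.node_id, -a.raw, -a.standardized, a.combined_variance)
            b = Contrast(b.node_id, -b.raw, -b.standardized, b.combined_variance)
        new_x.append(a)
        new_y.append(b)
    return (
        ContrastSet(cx.trait_name, tuple(new_x)),
        ContrastSet(cy.trait_name, tuple(new_y)),
    )


# ---------------------------------------------------------------------------
# Through-origin statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OriginCorrelation:
    r: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class OriginRegression:
    slope: float
    se: float
    t: float
    df: int
    p: float


def _as_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    xv = x.standardized if isinstance(x, ContrastSet) else np.asarray(x, float)
    yv = y.standardized if isinstance(y, ContrastSet) else np.asarray(y, float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(xv) < 2:
        raise ValueError("need at least 2 contrast pairs")
    return xv, yv


def correlation_through_origin(x, y) -> OriginCorrelation:
    """Pearson correlation constrained through the origin.

    r = sum(x*y) / sqrt(sum(x^2) * sum(y^2)); tested against t with
    n_contrasts - 1 degrees of freedom (the through-origin convention on
    contrasts).
    """
    xv, yv = _as_arrays(x, y)
    sxx, syy = float(xv @ xv), float(yv @ yv)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero-norm contrast vector; correlation undefined")
    r = float(xv @ yv) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    df = len(xv) - 1
    if 1.0 - r * r <= 0.0:
        return OriginCorrelation(r=r, t=math.inf if r > 0 else -math.inf, df=df, p=0.0)
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return OriginCorrelation(r=r, t=t, df=df, p=p)


def regression_through_origin(x, y) -> OriginRegression:
    """Least-squares slope through the origin with its t-test.

    slope = sum(x*y)/sum(x^2); residual degrees of freedom are
    n_contrasts - 1.
    """
    xv, yv = _as_arrays(x, y)
    sxx = float(xv @ xv)
    if sxx == 0.0:
        raise ValueError("sum of squared x is zero; slope undefined")
    slope = float(xv @ yv) / sxx
    resid = yv - slope * xv
    df = len(xv) - 1
    rss = float(resid @ resid)
    se = math.sqrt(rss / df / sxx) if df > 0 else math.nan
    if se == 0.0:
        return OriginRegression(
            slope=slope,
            se=0.0,
            t=math.inf if slope >= 0 else -math.inf,
            df=df,
            p=0.0,
        )
    t = slope / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return OriginRegression(slope=slope, se=se, t=t, df=df, p=p)


def contrast_diagnostics(cs: ContrastSet) -> dict[str, float]:
    """Normality and standardization diagnostics for a contrast set.

    Reports the Shapiro-Wilk p-value of the standardized contrasts and
    the slope of |contrast| on sqrt(combined variance) (a non-zero slope
    suggests branch lengths mis-scale the trait's variance).  Purely
    advisory; nothing downstream gates on these.
    """
    std = cs.standardized
    out: dict[str, float] = {"n_contrasts": float(cs.n_contrasts)}
    if 3 <= len(std) <= 5000 and np.ptp(std) > 0:
        out["shapiro_p"] = float(stats.shapiro(std).pvalue)
    else:
        out["shapiro_p"] = math.nan
    sv = np.sqrt([c.combined_variance for c in cs.contrasts])
    if len(std) >= 3 and np.ptp(sv) > 0:
        slope, _, _, p, _ = stats.linregress(sv, np.abs(std))
        out["abs_contrast_vs_sd_slope"] = float(slope)
        out["abs_contrast_vs_sd_p"] = float(p)
    else:
        out["abs_contrast_vs_sd_slope"] = math.nan
        out["abs_contrast_vs_sd_p"] = math.nan
    return out


def prune_to_leaves(tree: dendropy.Tree, keep: Sequence[str]) -> dendropy.Tree:
    """Copy of the tree restricted to the given leaf labels."""
    out = tree.clone(depth=1)
    taxa = [t for t in out.taxon_namespace if t.label in set(keep)]
    out.retain_taxa(taxa)
    return out
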