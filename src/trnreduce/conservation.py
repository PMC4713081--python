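"""Hypergeometric tests of preferential TF conservation, with Fisher
combination across genomes.

For each genome and regulator type the question is whether the fraction
of conserved TFs of that type, f_i = k/n, exceeds the reference fraction
f_r = K/N more than sampling without replacement would explain.  Under
the null (no preferential conservation) the number k of conserved TFs of
the type, out of n conserved TFs drawn from a reference pool of N TFs of
which K are of the type, is Hypergeometric(N, K, n); the one-sided
p-value is the upper tail P(X >= k).  Per-type p-values across genomes
are combined with Fisher's method: X = -2 * sum(ln p_i) ~ chi-square with
2m degrees of freedom under the joint null.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .network import RegType
from .regulog import TypeCounts


@dataclass(frozen=True)
class ReferenceTypeCounts:
    """Reference-genome TF totals: N TFs overall, K per classified type."""

    N: int
    K_activators: int
    K_repressors: int
    K_duals: int

    def __post_init__(self) -> None:
        if self.K_activators + self.K_repressors + self.K_duals > self.N:
            raise ValueError("per-type totals exceed N")

    def K_of(self, reg_type: RegType) -> int:
        return {
            RegType.ACTIVATOR: self.K_activators,
            RegType.REPRESSOR: self.K_repressors,
            RegType.DUAL: self.K_duals,
        }[reg_type]


@dataclass(frozen=True)
class ConservationTest:
    genome_id: str
    tf_type: RegType
    N: int
    K: int
    n: int
    k: int
    f_i: float | None
    f_r: float
    p_value: float | None
    reject_at_alpha: bool
    alpha: float = 0.05

    @property
    def testable(self) -> bool:
        return self.p_value is not None


@dataclass(frozen=True)
class CombinedResult:
    tf_type: RegType
    statistic: float
    degrees_of_freedom: int
    combined_p: float
    n_tests: int


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), X ~ Hyp(N, K, n).

    The tail includes the observed k.  Computed via scipy's survival
    function, which works in log space and is stable for N well beyond
    10,000.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= n):
        raise ValueError(
            f"invalid hypergeometric parameters N={N}, K={K}, n={n}, k={k}"
        )
    if k > K:
        return 0.0
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def conservation_test(
    ref_counts: ReferenceTypeCounts,
    tc: TypeCounts,
    tf_type: RegType,
    alpha: float = 0.05,
) -> ConservationTest:
    """One-sided test of preferential conservation of one TF type in one
    genome (H0: f_i <= f_r against H1: f_i > f_r).

    A genome conserving no TFs (n = 0) is untestable: the fractions are
    undefined and the p-value is reported as None.
    """
    N, K = ref_counts.N, ref_counts.K_of(tf_type)
    n, k = tc.n, tc.k_of(tf_type)
    f_r = K / N
    if n == 0:
        return ConservationTest(
            genome_id=tc.genome_id,
            tf_type=tf_type,
            N=N,
            K=K,
            n=0,
            k=0,
            f_i=None,
            f_r=f_r,
            p_value=None,
            reject_at_alpha=False,
            alpha=alpha,
        )
    p = hypergeom_upper_tail(N, K, n, k)
    return ConservationTest(
        genome_id=tc.genome_id,
        tf_type=tf_type,
        N=N,
        K=K,
        n=n,
        k=k,
        f_i=k / n,
        f_r=f_r,
        p_value=p,
        reject_at_alpha=p < alpha,
        alpha=alpha,
    )


def fisher_combine(
    pvalues: Sequence[float], tf_type: RegType | None = None
) -> CombinedResult:
    """Combine independent one-sided p-values with Fisher's method.

    X = -2 * sum(ln p_i) is referred to a chi-square distribution with
    2m degrees of freedom.  Zero p-values are clamped to the smallest
    positive float with a warning (they would otherwise give X = inf).
    """
    if len(pvalues) == 0:
        raise ValueError("cannot combine an empty list of p-values")
    clamped = []
    for p in pvalues:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value out of range: {p}")
        if p == 0.0:
            warnings.warn(
                "p-value of 0 clamped to smallest positive float", stacklevel=2
            )
            p = sys.float_info.min
        clamped.append(p)
    import math

    x = -2.0 * sum(math.log(p) for p in clamped)
    df = 2 * len(clamped)
    combined_p = float(stats.chi2.sf(x, df))
    return CombinedResult(
        tf_type=tf_type,
        statistic=x,
        degrees_of_freedom=df,
        combined_p=combined_p,
        n_tests=len(clamped),
    )


def combine_by_type(
    tests: Sequence[ConservationTest], tf_type: RegType
) -> CombinedResult:
    """Fisher-combine the testable per-genome p-values for one TF type.

    Untestable genomes (n = 0) are dropped from the combination.
    """
    ps = [t.p_value for t in tests if t.tf_type is tf_type and t.testable]
    if not ps:
        raise ValueError(f"no testable genomes for type {tf_type.value}")
    return fisher_combine(ps, tf_type=tf_type)
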