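"""Multivariate regression of TF-type fractions on genome-level predictors.

Each criterion variable Y (the fraction of activators, repressors, or
dual regulators conserved in a genome) is regressed on three predictors:
genome size (X1), global-regulator fraction (X2), and NAP fraction (X3),

    Y = b0 + b1*X1 + b2*X2 + b3*X3 + e .

Because the raw partial coefficients carry the predictors' units, they
are also reported as standardized partial coefficients
b_j = beta_j * sd(X_j) / sd(Y) (sample sd, n-1 denominator), which are
unit-free and directly comparable across predictors.  Predictor
importance is judged by |b| among coefficients significant at alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats


class CollinearityError(ValueError):
    pass


class StandardizationError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    criterion: str
    predictors: tuple[str, ...]
    beta: tuple[float, ...]          # (b0, b1, b2, b3)
    standardized_b: tuple[float, ...]  # (b1, b2, b3)
    p_values: tuple[float, ...]      # per coefficient, intercept first
    r_squared: float
    n: int
    condition_number: float
    vif: tuple[float, ...]


@dataclass(frozen=True)
class PredictorEffect:
    name: str
    b: float
    p: float
    significant: bool


def fit_multivariate(
    Y: np.ndarray,
    X: np.ndarray,
    predictor_names: tuple[str, ...] = ("genome_size", "global_fraction", "nap_fraction"),
    criterion: str = "tf_fraction",
    condition_threshold: float = 1e8,
) -> RegressionResult:
    """Ordinary least squares with intercept, plus standardized coefficients.

    ``X`` is n x p (p predictors, no intercept column).  Per-coefficient
    two-sided t-tests use n - p - 1 residual degrees of freedom.  An
    ill-conditioned design triggers a warning with variance-inflation
    factors; exact rank deficiency is an error, as is a constant Y
    (whose sd of zero makes standardization undefined).
    """
    Y = np.asarray(Y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D design matrix")
    n, p = X.shape
    if len(predictor_names) != p:
        raise ValueError("predictor_names must match X's column count")
    if len(Y) != n:
        raise ValueError("Y length does not match X rows")
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} observations, got {n}")

    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < p + 1:
        raise CollinearityError("design matrix is exactly rank deficient")

    sd_y = float(np.std(Y, ddof=1))
    if sd_y == 0.0:
        raise StandardizationError("Y is constant; standardized coefficients undefined")

    model = sm.OLS(Y, design).fit()
    cond = float(np.linalg.cond(design))
    vifs = _variance_inflation(X)
    if cond > condition_threshold:
        warnings.warn(
            f"ill-conditioned design (condition number {cond:.3g}); "
            f"VIF per predictor: "
            + ", ".join(f"{nm}={v:.2f}" for nm, v in zip(predictor_names, vifs)),
            stacklevel=2,
        )

    sd_x = np.std(X, axis=0, ddof=1)
    beta = tuple(float(b) for b in model.params)
    standardized = tuple(
        float(model.params[j + 1] * sd_x[j] / sd_y) for j in range(p)
    )
    return RegressionResult(
        criterion=criterion,
        predictors=tuple(predictor_names),
        beta=beta,
        standardized_b=standardized,
        p_values=tuple(float(pv) for pv in model.pvalues),
        r_squared=float(model.rsquared),
        n=n,
        condition_number=cond,
        vif=tuple(vifs),
    )


def _variance_inflation(X: np.ndarray) -> list[float]:
    n, p = X.shape
    if p == 1:
        return [1.0]
    vifs = []
    for j in range(p):
        others = np.delete(X, j, axis=1)
        design = sm.add_constant(others, has_constant="add")
        r2 = sm.OLS(X[:, j], design).fit().rsquared
        vifs.append(float("inf") if r2 >= 1.0 else 1.0 / (1.0 - r2))
    return vifs


def compare_predictors(
    result: RegressionResult, alpha: float = 0.05
) -> list[PredictorEffect]:
    """Rank predictors by |standardized b|, significant ones first.

    Returns every predictor as a PredictorEffect; those with p >= alpha
    are flagged non-significant and sorted after the significant block.
    """
    effects = [
        PredictorEffect(
            name=name,
            b=b,
            p=p,
            significant=p < alpha,
        )
        for name, b, p in zip(
            result.predictors, result.standardized_b, result.p_values[1:]
        )
    ]
    return sorted(effects, key=lambda e: (not e.significant, -abs(e.b)))


def predictor_redundancy(
    x2: np.ndarray, x3: np.ndarray, threshold: float = 0.7
) -> tuple[float, bool]:
    """Ordinary Pearson correlation between two predictors.

    Returns (r, redundant) where redundant means |r| exceeds the
    threshold — a sign the two predictors carry overlapping information
    (as global-regulator and NAP fractions do).
    """
    x2 = np.asarray(x2, float).ravel()
    x3 = np.asarray(x3, float).ravel()
    if len(x2) != len(x3) or len(x2) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.std(x2) == 0.0 or np.std(x3) == 0.0:
        raise ValueError("zero-variance predictor; correlation undefined")
    r = float(stats.pearsonr(x2, x3).statistic)
    return r, abs(r) > threshold
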