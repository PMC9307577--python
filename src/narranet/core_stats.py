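"""Shared statistical machinery.

Permutation p-values with the add-one convention, Benjamini-Hochberg FDR,
a mixed-effects model contract (logistic / linear families with crossed
random intercepts and likelihood-ratio tests), and confidence intervals
for differences between dependent overlapping correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glmm import GLMMFit, fit_glmm

__all__ = [
    "PermutationResult",
    "MixedModelResult",
    "permutation_pvalue",
    "bh_fdr",
    "fit_mixed_model",
    "compare_dependent_correlations",
]

DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_FDR_Q = 0.05


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the add-one p-value.

    With ``m`` null samples the attainable p-values are k/(m+1) for
    k = 1..m+1, so the smallest reportable value is 1/(m+1) (e.g. .000999
    for 1000 permutations) and 0 is never returned.
    """

    observed: float
    null_samples: np.ndarray
    tail: str
    p_value: float
    seed: int | None = None

    def to_dict(self, include_null: bool = False) -> dict:
        d = {"observed": self.observed, "tail": self.tail,
             "p_value": self.p_value, "n_permutations": int(len(self.null_samples)),
             "seed": self.seed}
        if include_null:
            d["null_samples"] = [float(x) for x in self.null_samples]
        return d


@dataclass
class MixedModelResult:
    """Fixed-effect estimates and likelihood-ratio tests from a mixed model."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    family: str
    converged: bool
    lrt: dict[str, tuple[float, float]] = field(default_factory=dict)
    message: str = ""
    loglik: float = float("nan")
    sigma: dict[str, float] = field(default_factory=dict)
    fit: GLMMFit | None = None

    @property
    def lrt_chi2(self) -> float:
        if len(self.lrt) != 1:
            raise ValueError("lrt_chi2 is defined only when exactly one predictor was tested")
        return next(iter(self.lrt.values()))[0]

    @property
    def lrt_p(self) -> float:
        if len(self.lrt) != 1:
            raise ValueError("lrt_p is defined only when exactly one predictor was tested")
        return next(iter(self.lrt.values()))[1]


def permutation_pvalue(
    observed: float,
    null_samples,
    tail: str = "one-tailed-greater",
    seed: int | None = None,
) -> PermutationResult:
    """Permutation p-value with the add-one (never-zero) convention.

    One-tailed: p = (#{null >= observed} + 1) / (m + 1).
    Two-tailed: extremity is absolute distance from 0 (the null statistics
    handed in are differences constructed to be mean-zero), so
    p = (#{|null| >= |observed|} + 1) / (m + 1).
    """
    null = np.asarray(null_samples, dtype=float).ravel()
    if null.size == 0:
        raise ValueError("null_samples must be non-empty")
    if not np.isfinite(null).all():
        raise ValueError("null_samples must all be finite")
    if not np.isfinite(observed):
        raise ValueError("observed statistic must be finite")
    m = null.size
    if tail in ("one-tailed-greater", "greater", "one-tailed"):
        tail = "one-tailed-greater"
        b = int(np.sum(null >= observed))
    elif tail in ("two-tailed", "two-sided"):
        tail = "two-tailed"
        b = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown tail '{tail}'")
    p = (b + 1) / (m + 1)
    return PermutationResult(observed=float(observed), null_samples=null,
                             tail=tail, p_value=float(p), seed=seed)


def bh_fdr(p_values, q: float = DEFAULT_FDR_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject, p_adjusted)``. Rejection flags are monotone in the
    raw p-values.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def fit_mixed_model(
    outcome,
    fixed: pd.DataFrame | dict,
    random_intercepts: dict,
    family: str = "logistic",
    lrt_predictors: list[str] | str | None = None,
    add_intercept: bool = True,
) -> MixedModelResult:
    """Fit a mixed-effects model with crossed random intercepts (ML).

    Parameters
    ----------
    outcome : array (n,)
        Binary outcome for ``family='logistic'``, real for ``'linear'``.
    fixed : DataFrame or dict of arrays
        Fixed-effect predictors (an intercept is added unless
        ``add_intercept=False``).
    random_intercepts : dict
        Factor name -> length-n array of group labels; every factor needs
        at least two levels.
    family : 'logistic' or 'linear'
    lrt_predictors : list / str / None
        Predictors to test with a likelihood-ratio test of the full model
        against the model omitting that predictor (chi2 with 1 df). None
        tests nothing (cheapest); ``'all'`` tests every fixed predictor.

    Notes
    -----
    Random effects are intercepts only. Non-convergence and separation are
    flagged on the result, never silent.
    """
    fam = {"logistic": "binomial", "linear": "gaussian"}.get(family)
    if fam is None:
        raise ValueError(f"family must be 'logistic' or 'linear', got '{family}'")
    fx = pd.DataFrame(fixed)
    names = list(fx.columns)
    y = np.asarray(outcome, dtype=float).ravel()
    if family == "logistic" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("logistic family requires a binary 0/1 outcome")
    X = fx.to_numpy(dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["(Intercept)"] + names
    groups = {g: np.asarray(v) for g, v in random_intercepts.items()}

    full = fit_glmm(y, X, groups, family=fam, names=names)

    if lrt_predictors == "all":
        lrt_predictors = [n for n in names if n != "(Intercept)"]
    elif isinstance(lrt_predictors, str):
        lrt_predictors = [lrt_predictors]
    lrt: dict[str, tuple[float, float]] = {}
    if lrt_predictors and full.converged:
        for pred in lrt_predictors:
            if pred not in names:
                raise ValueError(f"unknown predictor '{pred}'")
            keep = [j for j, n in enumerate(names) if n != pred]
            red = fit_glmm(y, X[:, keep], groups, family=fam,
                           names=[names[j] for j in keep])
            chi2 = max(0.0, 2.0 * (full.loglik - red.loglik))
            lrt[pred] = (chi2, float(stats.chi2.sf(chi2, df=1)))

    return MixedModelResult(coefficients=full.coefficients,
                            std_errors=full.std_errors,
                            family=family, converged=full.converged,
                            lrt=lrt, message=full.message,
                            loglik=full.loglik, sigma=full.sigma, fit=full)


def compare_dependent_correlations(
    r_ab: float, r_ac: float, r_bc: float, n: int, conf: float = 0.95
) -> tuple[float, float]:
    """CI for the difference of two overlapping dependent correlations.

    ``r_ab`` and ``r_ac`` share the variable *a* (here: event centrality
    correlated with ISFC of two region pairs); ``r_bc`` is the correlation
    between the two non-shared variables. Uses Zou's (2007) asymptotic
    method: Fisher-z limits for each correlation are combined with the
    estimated correlation between the two sample correlations.

    Returns the (lower, upper) CI for ``r_ab - r_ac``; the difference is
    significant at the complementary level iff the CI excludes 0.
    """
    for name, r in (("r_ab", r_ab), ("r_ac", r_ac), ("r_bc", r_bc)):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("n must be at least 4")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    se_z = 1.0 / np.sqrt(n - 3)

    def fisher_limits(r):
        zr = np.arctanh(r)
        return np.tanh(zr - z * se_z), np.tanh(zr + z * se_z)

    l1, u1 = fisher_limits(r_ab)
    l2, u2 = fisher_limits(r_ac)
    # correlation between the two dependent sample correlations (Zou 2007,
    # eq. for overlapping case)
    num = ((r_bc - 0.5 * r_ab * r_ac) * (1 - r_ab ** 2 - r_ac ** 2 - r_bc ** 2)
           + r_bc ** 3)
    den = (1 - r_ab ** 2) * (1 - r_ac ** 2)
    c = num / den
    c = float(np.clip(c, -1.0, 1.0))
    diff = r_ab - r_ac
    lower = diff - np.sqrt((r_ab - l1) ** 2 + (u2 - r_ac) ** 2
                           - 2 * c * (r_ab - l1) * (u2 - r_ac))
    upper = diff + np.sqrt((u1 - r_ab) ** 2 + (r_ac - l2) ** 2
                           - 2 * c * (u1 - r_ab) * (r_ac - l2))
    return float(lower), float(upper)
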