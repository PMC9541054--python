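"""Comparison statistics for two coding algorithms.

* Standardized mean differences (SMD) for covariate balance, with the usual
  0.10 balance threshold. Binary covariates use
  ``|p_a - p_b| / sqrt((p_a(1-p_a) + p_b(1-p_b))/2)``; continuous ones
  ``|m_a - m_b| / sqrt((s_a^2 + s_b^2)/2)``. The two algorithm arms are
  treated as independent groups even though they score the same patients —
  the classical two-group SMD, reported as such.
* Per-condition patient-overlap 2x2 counts (both / neither / A only / B only).
* Univariable logistic regression of one-year mortality on the CCI
  (maximum likelihood via IRLS, tolerance 1e-8, max 25 iterations) and its
  concordance statistic (c = AUC), with a seeded percentile-bootstrap CI.

The c-statistic is the concordance probability over all (case, control)
pairs with ties counting one half — the rank-sum formulation, computed in
O(n log n) from midranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .codesets import CONDITION_ORDER
from .errors import ContractError, EstimationError

SMD_BALANCE_THRESHOLD = 0.10


# -- standardized mean differences ----------------------------------------

def smd_binary(p_a: float, p_b: float) -> float:
    """SMD between two proportions."""
    for p in (p_a, p_b):
        if not 0.0 <= p <= 1.0:
            raise ContractError(f"proportion out of [0, 1]: {p}")
    spread = (p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0
    return _smd(abs(p_a - p_b), spread)


def smd_continuous(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """SMD between two means with group standard deviations."""
    if sd_a < 0 or sd_b < 0:
        raise ContractError("standard deviations must be non-negative")
    spread = (sd_a ** 2 + sd_b ** 2) / 2.0
    return _smd(abs(mean_a - mean_b), spread)


def _smd(diff: float, pooled_var: float) -> float:
    if pooled_var == 0.0:
        # degenerate groups: identical constants are balanced, different
        # constants are infinitely imbalanced
        return 0.0 if diff == 0.0 else math.inf
    return diff / math.sqrt(pooled_var)


def smd(stat_a, stat_b) -> float:
    """Dispatch on input shape: scalars are proportions, (mean, sd) pairs
    are continuous summaries."""
    if np.isscalar(stat_a) and np.isscalar(stat_b):
        return smd_binary(float(stat_a), float(stat_b))
    (m_a, s_a), (m_b, s_b) = stat_a, stat_b
    return smd_continuous(float(m_a), float(s_a), float(m_b), float(s_b))


# -- patient overlap -------------------------------------------------------

def overlap_table(flags_a: pd.DataFrame, flags_b: pd.DataFrame) -> pd.DataFrame:
    """Per-condition 2x2 overlap between two algorithms' patient flags.

    Inputs are flag frames (one row per person, boolean columns per
    condition plus ``person_id``), e.g. from
    :func:`snomedcci.cci.results_frame`. Both must cover the same persons.
    """
    a = flags_a.set_index("person_id").sort_index()
    b = flags_b.set_index("person_id").sort_index()
    if not a.index.equals(b.index):
        raise ContractError("flag frames cover different person sets")
    n = len(a)
    rows = []
    for cond in CONDITION_ORDER:
        fa = a[cond].to_numpy(dtype=bool)
        fb = b[cond].to_numpy(dtype=bool)
        n_both = int((fa & fb).sum())
        n_a_only = int((fa & ~fb).sum())
        n_b_only = int((~fa & fb).sum())
        rows.append({
            "condition": cond,
            "n_both": n_both,
            "n_neither": n - n_both - n_a_only - n_b_only,
            "n_a_only": n_a_only,
            "n_b_only": n_b_only,
        })
    return pd.DataFrame(rows)


def balance_table(
    score_a: np.ndarray,
    score_b: np.ndarray,
    flags_a: pd.DataFrame,
    flags_b: pd.DataFrame,
    label_a: str = "snomed",
    label_b: str = "quan",
) -> pd.DataFrame:
    """Covariate balance between algorithms: the CCI (mean/sd) and each
    condition's prevalence, with SMDs and the 0.10 imbalance flag."""
    rows = [{
        "covariate": "cci",
        f"stat_{label_a}": float(np.mean(score_a)),
        f"stat_{label_b}": float(np.mean(score_b)),
        f"sd_{label_a}": float(np.std(score_a, ddof=1)) if len(score_a) > 1 else 0.0,
        f"sd_{label_b}": float(np.std(score_b, ddof=1)) if len(score_b) > 1 else 0.0,
    }]
    rows[0]["smd"] = smd_continuous(
        rows[0][f"stat_{label_a}"], rows[0][f"sd_{label_a}"],
        rows[0][f"stat_{label_b}"], rows[0][f"sd_{label_b}"],
    )
    a = flags_a.set_index("person_id").sort_index()
    b = flags_b.set_index("person_id").sort_index()
    for cond in CONDITION_ORDER:
        p_a = float(a[cond].mean()) if len(a) else 0.0
        p_b = float(b[cond].mean()) if len(b) else 0.0
        rows.append({
            "covariate": cond,
            f"stat_{label_a}": p_a, f"stat_{label_b}": p_b,
            f"sd_{label_a}": float("nan"), f"sd_{label_b}": float("nan"),
            "smd": smd_binary(p_a, p_b),
        })
    df = pd.DataFrame(rows)
    df["imbalanced"] = df["smd"] > SMD_BALANCE_THRESHOLD
    return df


# -- discrimination --------------------------------------------------------

def c_statistic(scores, outcomes) -> float:
    """Concordance probability of a score for a binary outcome.

    Equals the probability a random case outranks a random control, ties
    counting 0.5 — i.e. the trapezoidal area under the ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape or s.ndim != 1:
        raise ContractError("scores and outcomes must be equal-length 1-d arrays")
    y = y.astype(bool)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise EstimationError("c-statistic undefined: only one outcome class present")
    ranks = rankdata(s)  # midranks handle ties exactly
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class ModelPerformance:
    """Univariable logistic model summary for one coding algorithm."""

    algorithm: str
    intercept: float
    slope: float
    c_statistic: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.c_statistic <= 1.0):
            raise ContractError("c-statistic outside [0, 1]")
        if not (self.ci_low <= self.c_statistic <= self.ci_high):
            raise ContractError("confidence interval does not bracket the estimate")


def fit_mortality_model(
    scores,
    outcomes,
    algorithm: str = "",
    n_boot: int = 2000,
    seed: int = 0,
    tol: float = 1e-8,
    maxiter: int = 25,
) -> ModelPerformance:
    """Fit ``outcome ~ intercept + slope * score`` by maximum likelihood and
    summarize discrimination.

    The c-statistic is computed from the fitted probabilities (identical to
    computing it on the raw scores, the link being monotone); its CI is a
    seeded percentile bootstrap (``n_boot`` resamples of patients).
    """
    import statsmodels.api as sm

    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ContractError("scores and outcomes must be equal-length 1-d arrays")
    n1 = int(y.sum())
    if n1 == 0 or n1 == len(y):
        raise EstimationError("model not estimable: only one outcome class present")

    if np.ptp(s) == 0.0:
        # constant score: slope 0 is the stationary point, no discrimination
        p = y.mean()
        intercept = float(np.log(p / (1 - p)))
        slope = 0.0
        fitted = np.full_like(s, p)
        c = 0.5
    else:
        X = sm.add_constant(s)
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=maxiter, tol=tol, tol_criterion="params")
        if not res.converged:
            raise EstimationError(
                f"IRLS did not converge within {maxiter} iterations"
            )
        intercept, slope = (float(v) for v in res.params)
        fitted = np.asarray(res.fittedvalues)
        c = c_statistic(fitted, y)

    rng = np.random.default_rng(seed)
    n = len(y)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        while True:  # redraw single-class resamples (vanishing probability at scale)
            idx = rng.integers(0, n, size=n)
            yy = y[idx]
            if 0 < yy.sum() < n:
                break
        ss = s[idx]
        boot[i] = 0.5 if np.ptp(ss) == 0.0 else c_statistic(ss, yy)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])

    return ModelPerformance(
        algorithm=algorithm,
        intercept=intercept,
        slope=slope,
        c_statistic=c,
        ci_low=float(min(ci_low, c)),
        ci_high=float(max(ci_high, c)),
        n=n,
        n_events=n1,
    )
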