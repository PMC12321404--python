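"""Association statistics linking subtype, heterogeneity, Ki-67, organ
site, genomics, and clinical durations.

Rank-based tests (Kruskal-Wallis, Mann-Whitney with Holm adjustment,
Hodges-Lehmann median differences with distribution-free CIs) follow the
standard nonparametric toolkit. NE-positivity vs anatomic site is modelled
with a logistic regression containing a per-patient random intercept,
fitted by maximum likelihood via Gauss-Hermite quadrature, with bone as
the reference site.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.numdiff import approx_hess1

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ComparisonResult:
    groups: tuple[str, ...]
    statistic_name: str
    statistic: float
    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float
    p_adjusted: float | None = None
    adjustment: str | None = None
    n: tuple[int, ...] = ()


def kw_test(groups: Mapping[str, Sequence[float]]) -> ComparisonResult:
    """Kruskal-Wallis H test across >= 2 groups (tie-corrected)."""
    names = tuple(groups)
    if len(names) < 2:
        raise ValueError("Kruskal-Wallis requires at least two groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence of any difference
        return ComparisonResult(names, "kruskal_H", 0.0, None, None, None, 1.0,
                                n=tuple(a.size for a in arrays))
    h, p = stats.kruskal(*arrays)
    return ComparisonResult(
        names, "kruskal_H", float(h), None, None, None, float(p),
        n=tuple(a.size for a in arrays),
    )


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U: exact for small untied samples, else normal approx
    with continuity correction."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def pairwise_mwu_holm(groups: Mapping[str, Sequence[float]]) -> list[ComparisonResult]:
    """All pairwise Mann-Whitney comparisons with Holm step-down adjustment."""
    names = [g for g in groups]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    usable = []
    for g in names:
        if len(groups[g]) == 0:
            warnings.warn(f"group {g!r} is empty and was skipped", stacklevel=2)
        else:
            usable.append(g)
    pairs = list(combinations(usable, 2))
    raw: list[tuple[tuple[str, str], float, float, int, int]] = []
    for a, b in pairs:
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        u, p = _mwu(x, y)
        raw.append(((a, b), u, p, x.size, y.size))
    adj = multipletests([r[2] for r in raw], method="holm")[1]
    return [
        ComparisonResult(
            pair, "mann_whitney_U", u, None, None, None, p,
            p_adjusted=float(pa), adjustment="holm", n=(nx, ny),
        )
        for (pair, u, p, nx, ny), pa in zip(raw, adj)
    ]


def median_diff_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Hodges-Lehmann shift estimate (x - y) with a distribution-free CI.

    The estimate is the median of all pairwise differences x_i - y_j; the
    CI is inverted from the Mann-Whitney statistic via the normal
    approximation to its null distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    hl = float(np.median(diffs))
    n, m = x.size, y.size
    nm = n * m
    z = stats.norm.ppf(1 - alpha / 2)
    k = int(math.floor(nm / 2 - z * math.sqrt(nm * (n + m + 1) / 12.0)))
    k = max(k, 0)
    ci_low = float(diffs[k]) if k < nm else float(diffs[0])
    ci_high = float(diffs[nm - 1 - k]) if k < nm else float(diffs[-1])
    _, p = _mwu(x, y)
    return ComparisonResult(
        ("x", "y"), "hodges_lehmann_shift", hl, hl, ci_low, ci_high, p, n=(n, m)
    )


def bonferroni_gate(
    p_values: Sequence[float], m: int = 21, alpha: float = 0.05
) -> list[bool]:
    """Significance under a fixed Bonferroni family: significant iff p < alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    cut = alpha / m
    return [float(p) < cut for p in p_values]


# ---------------------------------------------------------------------------
# random-intercept logistic regression (maximum likelihood, Gauss-Hermite)
# ---------------------------------------------------------------------------


@dataclass
class MixedLogitResult:
    """Fitted random-intercept logistic model of NE positivity on site."""

    reference: str
    sites: tuple[str, ...]
    coef: dict[str, float]          # log-odds per site vs reference (+ intercept)
    se: dict[str, float]
    odds_ratios: dict[str, float]
    or_ci: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    sigma: float                    # random-intercept SD
    converged: bool
    loglik: float
    non_estimable: tuple[str, ...] = ()
    n_obs: int = 0
    n_patients: int = 0


def _mixed_logit_nll(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    log_weights: np.ndarray,
    fix_sigma: float | None,
) -> float:
    if fix_sigma is None:
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
    else:
        beta, sigma = params, fix_sigma
    eta = X @ beta                                   # (n_obs,)
    # (n_obs, K): linear predictor at each quadrature node
    lin = eta[:, None] + math.sqrt(2.0) * sigma * nodes[None, :]
    # log Bernoulli likelihood, numerically stable
    ll_obs = np.where(y[:, None] == 1, -np.logaddexp(0, -lin), -np.logaddexp(0, lin))
    # sum within patient -> (n_groups, K)
    ll_grp = np.zeros((n_groups, nodes.size))
    np.add.at(ll_grp, groups, ll_obs)
    # integrate over the random intercept
    from scipy.special import logsumexp

    ll = logsumexp(ll_grp + log_weights[None, :], axis=1) - 0.5 * math.log(math.pi)
    return -float(np.sum(ll))


def ne_site_model(
    samples: pd.DataFrame,
    outcome: str = "ne_positive",
    site_col: str = "site",
    patient_col: str = "patient_id",
    reference: str = "bone",
    n_quadrature: int = 25,
    fix_sigma: float | None = None,
    alpha: float = 0.05,
) -> MixedLogitResult:
    """Odds of NE-positive disease by anatomic site, clustered by patient.

    Fits logit P(NE+ | site, patient) = beta_0 + beta_site + u_patient with
    u ~ N(0, sigma^2) by maximum likelihood (Gauss-Hermite quadrature over
    the random intercept). Returns per-site odds ratios vs the reference
    site with Wald CIs. Sites whose outcome is constant are flagged
    non-estimable. ``fix_sigma=0`` constrains the model to ordinary
    logistic regression (used for equivalence checks).
    """
    df = samples[[patient_col, site_col, outcome]].dropna()
    sites = sorted(df[site_col].unique())
    if reference not in sites:
        raise ValueError(f"reference site {reference!r} absent from data")
    if len(sites) < 2:
        raise ValueError("need at least two sites including the reference")
    if df[patient_col].nunique() < 2:
        raise ValueError("need at least two patients")

    non_estimable = tuple(
        s for s in sites
        if s != reference and df.loc[df[site_col] == s, outcome].nunique() < 2
    )

    others = [s for s in sites if s != reference]
    X = np.column_stack(
        [np.ones(len(df))] + [(df[site_col] == s).to_numpy(float) for s in others]
    )
    y = df[outcome].to_numpy(float)
    codes, uniq = pd.factorize(df[patient_col])
    n_groups = len(uniq)

    nodes, weights = np.polynomial.hermite.hermgauss(n_quadrature)
    log_weights = np.log(weights)

    # pooled logistic start values
    from statsmodels.api import Logit

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            start_beta = Logit(y, X).fit(disp=0, maxiter=200).params
        except Exception:
            start_beta = np.zeros(X.shape[1])
    start_beta = np.nan_to_num(np.clip(start_beta, -10, 10))

    if fix_sigma is None:
        x0 = np.append(start_beta, np.log(0.7))
    else:
        x0 = start_beta
    args = (X, y, codes, n_groups, nodes, log_weights, fix_sigma)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(_mixed_logit_nll, x0, args=args, method="BFGS",
                                options={"maxiter": 500, "gtol": 1e-6})
        # BFGS can stop on precision loss with the optimum already reached;
        # accept the fit if the gradient is (relatively) flat
        grad = optimize.approx_fprime(res.x, _mixed_logit_nll, 1e-6, *args)
        converged = bool(res.success) or float(np.max(np.abs(grad))) < 1e-2 * (
            1.0 + abs(res.fun)
        )
    params = res.x
    if fix_sigma is None:
        beta = params[:-1]
        sigma = float(np.exp(params[-1]))
    else:
        beta = params
        sigma = float(fix_sigma)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hess = approx_hess1(params, _mixed_logit_nll, args=args)
        try:
            cov = np.linalg.inv(hess)
            se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se_all = np.full(params.size, np.nan)

    z = stats.norm.ppf(1 - alpha / 2)
    names = ["intercept"] + others
    coef = dict(zip(names, map(float, beta)))
    se = dict(zip(names, map(float, se_all[: len(names)])))
    odds, ci, pvals = {}, {}, {}
    for s in others:
        b, s_e = coef[s], se[s]
        odds[s] = math.exp(b)
        if s in non_estimable or not np.isfinite(s_e) or s_e == 0:
            ci[s] = (float("nan"), float("nan"))
            pvals[s] = float("nan")
        else:
            ci[s] = (math.exp(b - z * s_e), math.exp(b + z * s_e))
            pvals[s] = float(2 * stats.norm.sf(abs(b / s_e)))

    return MixedLogitResult(
        reference=reference,
        sites=tuple(sites),
        coef=coef,
        se=se,
        odds_ratios=odds,
        or_ci=ci,
        p_values=pvals,
        sigma=sigma,
        converged=converged,
        loglik=-float(res.fun),
        non_estimable=non_estimable,
        n_obs=len(df),
        n_patients=n_groups,
    )


# ---------------------------------------------------------------------------
# clinical durations
# ---------------------------------------------------------------------------

EVENT_COLUMNS = (
    "diagnosis_day",
    "adt_start_day",
    "first_bone_met_day",
    "castration_resistance_day",
    "death_day",
)


@dataclass(frozen=True)
class ClinicalTimeline:
    """Day-offsets of disease milestones for one patient."""

    patient_id: str
    diagnosis_day: float | None = None
    adt_start_day: float | None = None
    first_bone_met_day: float | None = None
    castration_resistance_day: float | None = None
    death_day: float | None = None
    last_psa: float | None = None

    def __post_init__(self) -> None:
        present = [
            getattr(self, c)
            for c in EVENT_COLUMNS
            if getattr(self, c) is not None
        ]
        if any(b < a for a, b in zip(present, present[1:])):
            raise ValueError(f"event days not non-decreasing for {self.patient_id}")
        if self.last_psa is not None and self.last_psa < 0:
            raise ValueError("last_psa must be non-negative")

    def duration_years(self, start: str, end: str = "death_day") -> float | None:
        a, b = getattr(self, start), getattr(self, end)
        if a is None or b is None:
            return None
        return (b - a) / DAYS_PER_YEAR


@dataclass
class DurationStats:
    interval: str
    per_group: dict[str, dict[str, float]]       # median / q1 / q3 / n
    global_test: ComparisonResult | None
    pairwise: list[ComparisonResult] = field(default_factory=list)
    n_excluded: int = 0


def duration_stats(
    timelines: Sequence[ClinicalTimeline],
    grouping: Mapping[str, str],
    start: str = "first_bone_met_day",
    end: str = "death_day",
) -> DurationStats:
    """Per-group median/IQR of an event-to-event interval plus comparisons.

    ``grouping`` maps patient_id to a group label (e.g. dominant subtype or
    high/low HI). Patients with a missing endpoint are excluded and counted.
    """
    groups: dict[str, list[float]] = {}
    excluded = 0
    for t in timelines:
        d = t.duration_years(start, end)
        g = grouping.get(t.patient_id)
        if d is None or g is None:
            excluded += 1
            continue
        groups.setdefault(g, []).append(d)
    per_group = {
        g: {
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
            "n": len(v),
        }
        for g, v in groups.items()
    }
    global_test = kw_test(groups) if len(groups) >= 2 else None
    pairwise = pairwise_mwu_holm(groups) if len(groups) >= 2 else []
    return DurationStats(
        interval=f"{start}->{end}",
        per_group=per_group,
        global_test=global_test,
        pairwise=pairwise,
        n_excluded=excluded,
    )
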