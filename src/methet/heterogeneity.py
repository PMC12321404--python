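"""Pair-discordance heterogeneity indices and BCa bootstrap summaries.

The heterogeneity index (HI) is the probability, scaled to 0-100, that two
tumor samples drawn without replacement from the same patient carry
discordant labels. For category counts n_1..n_K with n = sum(n_k),

    HI = 100 * (C(n,2) - sum_k C(n_k,2)) / C(n,2)

which is the exact hypergeometric pair-discordance probability. Unlike the
plug-in Gini-Simpson index 1 - sum p_k^2, it carries the finite-sampling
correction (sampling without replacement); the two agree as n -> infinity.

Cohort-level means are summarized with bias-corrected and accelerated
(BCa) bootstrap 95% confidence intervals over patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

KI67_THRESHOLD = 20.0
HI_DICHOTOMY_CUTOFF = 50.0


@dataclass(frozen=True)
class HIResult:
    """A heterogeneity index with its pair bookkeeping.

    ``value`` is on the 0-100 scale and ``None`` when fewer than two
    units are available (``defined`` is False).
    """

    value: float | None
    n_units: int
    n_pairs: int
    n_discordant: int
    defined: bool

    @staticmethod
    def undefined(n_units: int) -> "HIResult":
        return HIResult(value=None, n_units=n_units, n_pairs=0, n_discordant=0, defined=False)


def _c2(a: int) -> int:
    return a * (a - 1) // 2


def subtype_hi(counts: Mapping[str, int]) -> HIResult:
    """HI over categorical labels from per-category counts.

    Exact probability that two samples drawn without replacement have
    different labels. Patients with fewer than two samples get an
    undefined result rather than an exception.
    """
    vals = []
    for k, v in counts.items():
        iv = int(v)
        if iv != v or iv < 0:
            raise ValueError(f"count for {k!r} must be a non-negative integer, got {v}")
        vals.append(iv)
    n = sum(vals)
    if n < 2:
        return HIResult.undefined(n)
    n_pairs = _c2(n)
    n_concordant = sum(_c2(v) for v in vals)
    n_disc = n_pairs - n_concordant
    return HIResult(
        value=100.0 * n_disc / n_pairs,
        n_units=n,
        n_pairs=n_pairs,
        n_discordant=n_disc,
        defined=True,
    )


def ki67_patient_hi(
    ki67_values: Sequence[float], threshold: float = KI67_THRESHOLD
) -> HIResult:
    """Intrapatient Ki-67 HI: discordant positivity across samples.

    A pair is discordant when one sample has Ki-67 <= threshold (low) and
    the other > threshold (high); the default 20% cut is the clinical
    convention used here.
    """
    if not (0 < threshold < 100):
        raise ValueError(f"threshold must be in (0, 100), got {threshold}")
    vals = [float(v) for v in ki67_values]
    if any(not (0 <= v <= 100) for v in vals):
        raise ValueError("Ki-67 values must be in [0, 100]")
    n = len(vals)
    if n < 2:
        return HIResult.undefined(n)
    n_high = sum(v > threshold for v in vals)
    n_low = n - n_high
    n_pairs = _c2(n)
    n_disc = n_low * n_high
    return HIResult(
        value=100.0 * n_disc / n_pairs,
        n_units=n,
        n_pairs=n_pairs,
        n_discordant=n_disc,
        defined=True,
    )


def ki67_intratumoral_hi(
    blocks: Mapping[str, Sequence[float]],
    threshold: float = KI67_THRESHOLD,
    pool: bool = True,
) -> HIResult:
    """Intratumoral Ki-67 HI: discordant pairs within the same tissue block.

    Blocks with fewer than two cores contribute no pairs. With
    ``pool=True`` (default) discordant and total pair counts are pooled
    across blocks; ``pool=False`` averages the per-block indices instead.
    """
    if len(blocks) == 0:
        raise ValueError("at least one block required")
    per_block: list[HIResult] = []
    for block_id, values in blocks.items():
        if len(values) >= 2:
            per_block.append(ki67_patient_hi(values, threshold=threshold))
    n_units = sum(len(v) for v in blocks.values())
    if not per_block:
        return HIResult.undefined(n_units)
    if pool:
        n_pairs = sum(r.n_pairs for r in per_block)
        n_disc = sum(r.n_discordant for r in per_block)
        return HIResult(
            value=100.0 * n_disc / n_pairs,
            n_units=n_units,
            n_pairs=n_pairs,
            n_discordant=n_disc,
            defined=True,
        )
    value = float(np.mean([r.value for r in per_block]))
    return HIResult(
        value=value,
        n_units=n_units,
        n_pairs=sum(r.n_pairs for r in per_block),
        n_discordant=sum(r.n_discordant for r in per_block),
        defined=True,
    )


def pair_discordance_oracle(labels: Sequence) -> float:
    """Brute-force discordant fraction over all unordered pairs.

    Independent verification oracle for the closed-form indices: it
    enumerates every pair explicitly and must agree with ``subtype_hi``
    (divided by 100) on the same data.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two labels")
    discordant = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if labels[i] != labels[j]:
                discordant += 1
    return discordant / total


def dichotomize_hi(
    hi_value: float | None, cutoff: float = HI_DICHOTOMY_CUTOFF
) -> str | None:
    """Split HI into 'high' (> cutoff) vs 'low'.

    Exactly-cutoff values are 'low' under the strict '>' definition;
    undefined HIs yield None.
    """
    if hi_value is None:
        return None
    return "high" if hi_value > cutoff else "low"


@dataclass(frozen=True)
class BootstrapSummary:
    point_estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    degenerate: bool = False


def bootstrap_mean_ci(
    per_patient_values: Iterable[float],
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapSummary:
    """BCa bootstrap CI for the mean of per-patient values.

    Bias correction z0 comes from the fraction of bootstrap means below
    the observed mean; acceleration comes from the jackknife skewness.
    Values are sorted before resampling so the interval does not depend
    on input row order; the generator is seeded for exact repeatability.
    All-identical inputs return the degenerate interval [v, v], flagged.
    """
    x = np.sort(np.asarray(list(per_patient_values), dtype=float))
    if x.size < 2:
        raise ValueError("need at least two values to bootstrap")
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite values in bootstrap input")
    theta = float(x.mean())
    if np.all(x == x[0]):
        return BootstrapSummary(theta, theta, theta, n_boot, seed, degenerate=True)

    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = x[idx].mean(axis=1)

    # bias correction
    prop = np.mean(boot < theta)
    prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = stats.norm.ppf(prop)

    # acceleration from jackknife
    jack = (x.sum() - x) / (n - 1)
    d = jack.mean() - jack
    denom = 6.0 * (np.sum(d**2) ** 1.5)
    a = float(np.sum(d**3) / denom) if denom > 0 else 0.0

    lo, hi = _bca_percentiles(z0, a, alpha)
    ci_low, ci_high = np.quantile(boot, [lo, hi])
    return BootstrapSummary(theta, float(ci_low), float(ci_high), n_boot, seed)


def _bca_percentiles(z0: float, a: float, alpha: float) -> tuple[float, float]:
    """Adjusted percentile levels for the BCa interval."""
    out = []
    for z_alpha in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        num = z0 + z_alpha
        adj = z0 + num / (1.0 - a * num)
        out.append(float(stats.norm.cdf(adj)))
    lo, hi = out
    eps = 1e-12
    return min(max(lo, eps), 1 - eps), min(max(hi, eps), 1 - eps)


def expected_hi_dirichlet_multinomial(alpha: Sequence[float]) -> float:
    """Closed-form expected HI when labels follow a Dirichlet-multinomial.

    For DM parameters alpha with A = sum(alpha), the probability two
    samples from the same patient share a category is
    sum_k alpha_k (alpha_k + 1) / (A (A + 1)), independent of the number
    of samples, so E[HI] = 100 * (1 - that).
    """
    a = np.asarray(alpha, dtype=float)
    if np.any(a <= 0):
        raise ValueError("Dirichlet parameters must be positive")
    A = a.sum()
    same = float(np.sum(a * (a + 1)) / (A * (A + 1)))
    return 100.0 * (1.0 - same)
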