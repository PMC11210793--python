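"""Bootstrap estimation statistics for chemotaxis effect sizes.

The screen quantifies responses as *effect sizes* rather than test statistics:
the difference in mean worm position (mm) between a test condition and a null
reference, with a 95% confidence interval obtained by resampling the pooled
per-worm positions 5,000 times with replacement.  The point estimate is always
the plain difference of sample means; only the interval (and the p-value
derived from it) involves resampling.

Two-factor contrasts ("delta-delta") compare how two genotypes shift between
the control and a test compound::

    D1 = mean(G1, control) - mean(G2, control)
    D2 = mean(G1, test)    - mean(G2, test)
    DD = D1 - D2

so DD isolates the genotype-by-condition interaction, akin to a two-way
ANOVA.  CIs come from jointly resampling all four groups.

Confidence intervals are converted to exact two-sided p-values through the
bootstrap ECDF at zero, and Benjamini-Hochberg step-up controls the false
discovery rate across a screen's worth of comparisons.

Reproducibility: one top-level seed; each comparison derives an independent
stream from ``(seed, crc32(label))`` so partial reruns reproduce bit-for-bit.
Percentile intervals use ``numpy.percentile`` with its default (linear)
interpolation; the bias-corrected accelerated (BCa) variant is available via
``method="bca"``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectSize",
    "DeltaDelta",
    "PAdjustRecord",
    "AgreementStats",
    "rng_for",
    "bootstrap_mean_difference",
    "ci_to_pvalue",
    "benjamini_hochberg",
    "mann_whitney_u",
    "delta_delta",
    "agreement_stats",
]

DEFAULT_RESAMPLES = 5000


def rng_for(seed: int, label: str = "") -> np.random.Generator:
    """Deterministic per-comparison stream derived from (seed, label)."""
    key = zlib.crc32(label.encode("utf-8")) if label else 0
    return np.random.default_rng(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, key)))


@dataclass
class EffectSize:
    """Bootstrap mean difference (mm) with 95% CI and derived p-value."""

    mean_difference: float
    ci_low: float
    ci_high: float
    n_test: int
    n_control: int
    n_resamples: int
    seed: int
    p_value: float
    label: str = ""

    @property
    def significant(self) -> bool:
        """True iff the 95% CI excludes zero."""
        return self.ci_low > 0 or self.ci_high < 0


@dataclass
class DeltaDelta:
    """Two-factor effect DD = D1 - D2 (mm) with 95% CI."""

    delta1: float
    delta2: float
    delta_delta: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int
    label: str = ""

    @property
    def abs_value(self) -> float:
        return abs(self.delta_delta)

    @property
    def significant(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


@dataclass
class PAdjustRecord:
    raw_p: float
    adjusted_p: float
    rejected: bool


@dataclass
class AgreementStats:
    """Pearson/least-squares agreement between two scorings of the same assays."""

    pearson_r: float
    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray


def _as_sample(x, name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} values, got {arr.size}")
    return arr


def bootstrap_mean_difference(
    test_z,
    control_z,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
    label: str = "",
    method: str = "percentile",
    return_distribution: bool = False,
):
    """Effect size of a test condition vs a null reference.

    The point estimate is ``mean(test) - mean(control)`` exactly (it is not
    bootstrapped).  The 95% CI comes from the bootstrap distribution of the
    resampled mean difference, resampling each group independently with
    replacement ``n_resamples`` times; ``method="bca"`` swaps in the
    bias-corrected accelerated interval.
    """
    test = _as_sample(test_z, "test sample")
    control = _as_sample(control_z, "control sample")
    point = float(test.mean() - control.mean())

    rng = rng_for(seed, label)
    idx_t = rng.integers(0, test.size, size=(n_resamples, test.size))
    idx_c = rng.integers(0, control.size, size=(n_resamples, control.size))
    dist = test[idx_t].mean(axis=1) - control[idx_c].mean(axis=1)

    if method == "percentile":
        ci_low, ci_high = np.percentile(dist, [2.5, 97.5])
    elif method == "bca":
        res = sp_stats.bootstrap(
            (test, control),
            lambda t, c, axis=-1: np.mean(t, axis=axis) - np.mean(c, axis=axis),
            n_resamples=n_resamples,
            confidence_level=0.95,
            method="BCa",
            random_state=np.random.default_rng(rng.integers(2**31)),
        )
        ci_low, ci_high = res.confidence_interval.low, res.confidence_interval.high
    else:
        raise ValueError(f"unknown CI method {method!r}")

    effect = EffectSize(
        mean_difference=point,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_test=test.size,
        n_control=control.size,
        n_resamples=n_resamples,
        seed=seed,
        p_value=ci_to_pvalue(dist),
        label=label,
    )
    if return_distribution:
        return effect, dist
    return effect


def ci_to_pvalue(bootstrap_distribution) -> float:
    """Two-sided p-value from the bootstrap ECDF evaluated at zero.

    ``p = 2 * min(F(0), 1 - F(0))`` with ``F`` the ECDF of the resampled
    effect, floored at ``2 / (B + 1)`` (one can never claim a p-value smaller
    than the resolution of B resamples) and capped at 1.
    """
    dist = np.asarray(bootstrap_distribution, dtype=float).ravel()
    if dist.size < 100:
        raise ValueError("need at least 100 resampled values")
    f0 = float(np.mean(dist <= 0.0))
    p = 2.0 * min(f0, 1.0 - f0)
    return float(min(1.0, max(p, 2.0 / (dist.size + 1))))


def benjamini_hochberg(p_values, fdr: float = 0.05) -> list[PAdjustRecord]:
    """Benjamini-Hochberg step-up FDR control.

    Returns one record per input p-value in the original order; the set of
    rejections is a prefix of the p-sorted list and adjusted p-values are
    monotone in the raw ones.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return [
        PAdjustRecord(raw_p=float(rp), adjusted_p=float(ap), rejected=bool(rj))
        for rp, ap, rj in zip(p, adjusted, rejected)
    ]


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided).

    Exact enumeration for small samples without ties, normal approximation
    with tie correction otherwise (scipy's ``method="auto"`` policy).
    """
    a = _as_sample(sample_a, "sample_a", min_n=1)
    b = _as_sample(sample_b, "sample_b", min_n=1)
    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def delta_delta(
    g1_control,
    g1_test,
    g2_control,
    g2_test,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
    label: str = "",
    strict_literal: bool = False,
    return_distribution: bool = False,
):
    """Two-factor (genotype x condition) bootstrap contrast.

    ``delta1`` contrasts the two genotypes under the control condition,
    ``delta2`` under the test condition, and ``delta_delta = delta1 - delta2``
    isolates the interaction.  The CI jointly resamples all four groups.

    ``strict_literal=True`` reproduces the printed form of the second
    contrast (test group 1 vs *control* group 2); the default contrasts the
    two test conditions, which is the form consistent with a two-way-ANOVA
    style interaction.
    """
    g1c = _as_sample(g1_control, "g1_control")
    g1t = _as_sample(g1_test, "g1_test")
    g2c = _as_sample(g2_control, "g2_control")
    g2t = _as_sample(g2_test, "g2_test")

    def _dd(a, b, c, d):
        d1 = a.mean(axis=-1) - c.mean(axis=-1)
        second = c if strict_literal else d
        d2 = b.mean(axis=-1) - second.mean(axis=-1)
        return d1, d2, d1 - d2

    d1, d2, dd = _dd(g1c, g1t, g2c, g2t)

    rng = rng_for(seed, label)
    boot = np.empty(n_resamples)
    groups = (g1c, g1t, g2c, g2t)
    idx = [rng.integers(0, g.size, size=(n_resamples, g.size)) for g in groups]
    rs = [g[i] for g, i in zip(groups, idx)]
    _, _, boot = _dd(*rs)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])

    result = DeltaDelta(
        delta1=float(d1),
        delta2=float(d2),
        delta_delta=float(dd),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_resamples=n_resamples,
        seed=seed,
        label=label,
    )
    if return_distribution:
        return result, boot
    return result


def agreement_stats(x, y) -> AgreementStats:
    """Pearson r and least-squares fit between two paired measurement sets.

    Used to benchmark one scoring of a set of assays against another (e.g.
    automated counts vs a human scorer, or index vs mean position).
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("x and y must be equal-length with at least 3 points")
    if np.ptp(xa) == 0:
        raise ValueError("zero variance in x: fit undefined")
    fit = sp_stats.linregress(xa, ya)
    residuals = ya - (fit.slope * xa + fit.intercept)
    return AgreementStats(
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residuals=residuals,
    )
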