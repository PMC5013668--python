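"""Statistical primitives for the cfDNA emergence analysis.

The central Bayesian piece: let P be the probability that a TP53 mutation
is called from a single normal cfDNA sample. With a uniform Beta(1,1)
prior and zero detections in nine healthy-donor samples the posterior is
Beta(1,10). The posterior predictive for k detections in n future samples
is then beta-binomial; comparing the predictive probability of the
baseline outcome (0/14) with that of the on-treatment outcome (12/25)
quantifies how unlikely the treatment detections are under the
normal-plasma noise process.

Frequentist companions: an exact binomial lower tail (rational arithmetic
at p=1/2) for the transversion-spectrum test, a Pearson correlation test
with Fisher-Z confidence interval, a linear-log regression of tumour-size
change on log10 burden, Welch two-sample t-tests, and the qPCR delta-delta-Ct
relative copy-number rule (amplified iff > 5 copies).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import special, stats as sps


# ---------------------------------------------------------------------------
# beta-binomial posterior predictive


@dataclass(frozen=True)
class BetaPosterior:
    """Beta(alpha, beta) posterior for the per-sample detection probability."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def beta_posterior(
    detections: int,
    n_samples: int,
    prior_alpha: float = 1.0,
    prior_beta: float = 1.0,
) -> BetaPosterior:
    """Conjugate update of a Beta prior with binomial detection data."""
    if detections < 0 or n_samples < 0:
        raise ValueError("counts must be non-negative")
    if detections > n_samples:
        raise ValueError(f"detections {detections} exceed n_samples {n_samples}")
    return BetaPosterior(
        alpha=prior_alpha + detections,
        beta=prior_beta + n_samples - detections,
    )


def beta_binomial_pmf(k: int, n: int, post: BetaPosterior) -> float:
    """Posterior predictive P(exactly k detections in n samples).

    C(n,k) B(alpha+k, beta+n-k) / B(alpha, beta), evaluated in log space.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    log_p = (
        _log_comb(n, k)
        + special.betaln(post.alpha + k, post.beta + n - k)
        - special.betaln(post.alpha, post.beta)
    )
    return float(math.exp(log_p))


def beta_binomial_sf(k: int, n: int, post: BetaPosterior) -> float:
    """Posterior predictive upper tail P(at least k detections in n)."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    return float(sum(beta_binomial_pmf(i, n, post) for i in range(k, n + 1)))


def predictive_fold_change(p_baseline: float, p_treatment: float) -> float:
    """Ratio of the baseline predictive probability to the treatment one."""
    if p_treatment <= 0:
        raise ValueError("treatment predictive probability must be positive")
    return p_baseline / p_treatment


def _log_comb(n: int, k: int) -> float:
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


# ---------------------------------------------------------------------------
# exact binomial tail (transversion-spectrum test)


def binomial_tail_lower(k: int, n: int, p: float = 0.5) -> float:
    """Exact lower tail P(X <= k) for X ~ Binomial(n, p).

    For p = 1/2 the tail is an exact rational sum(C(n,i)) / 2^n evaluated
    in big-integer arithmetic before conversion to float, so printed
    values are reproducible to full double precision.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    frac = Fraction(p).limit_denominator(10**9)
    if frac == Fraction(1, 2):
        total = sum(math.comb(n, i) for i in range(k + 1))
        return float(Fraction(total, 2**n))
    q = 1 - frac
    tail = sum(math.comb(n, i) * frac**i * q ** (n - i) for i in range(k + 1))
    return float(tail)


# ---------------------------------------------------------------------------
# correlation and regression


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    p_two_sided: float
    ci95: tuple[float, float]

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass(frozen=True)
class RegressionFit:
    intercept: float
    slope: float
    slope_se: float
    slope_t: float
    slope_p: float
    f_stat: float
    f_p: float
    r_squared: float
    n: int

    def significant(self, alpha: float = 0.05) -> bool:
        """Both the overall F-test and the slope t-test significant."""
        return self.f_p < alpha and self.slope_p < alpha


def pearson_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with t-test (n-2 df) and an asymptotic 95% CI
    from the Fisher Z-transform, tanh(atanh(r) +/- 1.96 / sqrt(n-3))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-15:
        # degenerate perfect correlation
        t = math.inf if r > 0 else -math.inf
        return CorrelationResult(r=r, n=n, t_stat=t, p_two_sided=0.0, ci95=(r, r))
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    if n >= 4:
        z = math.atanh(r)
        half = sps.norm.ppf(0.975) / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        ci = (-1.0, 1.0)
    return CorrelationResult(r=r, n=n, t_stat=t, p_two_sided=p, ci95=ci)


def linear_log_regression(
    ct_change: Sequence[float], burden_pct: Sequence[float]
) -> RegressionFit:
    """OLS of tumour-size change (%) on log10 of the mutation burden (%).

    Burdens must be strictly positive — restrict to samples with at least
    one passing variant before calling. Reports both the overall F-test
    and the slope t-test (equivalent for a single predictor).
    """
    y = np.asarray(ct_change, dtype=float)
    b = np.asarray(burden_pct, dtype=float)
    if y.shape != b.shape or y.ndim != 1:
        raise ValueError("inputs must be 1-D of equal length")
    if y.size < 3:
        raise ValueError("need n >= 3")
    if np.any(b <= 0):
        raise ValueError(
            "non-positive burden: restrict the regression to detected samples"
        )
    x = np.log10(b)
    if np.ptp(x) == 0:
        raise ValueError("constant log-burden: slope undefined")
    if np.ptp(y) == 0:
        # flat response: zero slope, no explained variance
        return RegressionFit(
            intercept=float(y[0]), slope=0.0, slope_se=0.0, slope_t=0.0,
            slope_p=1.0, f_stat=0.0, f_p=1.0, r_squared=0.0, n=y.size,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # linregress warns on perfect fits
        fit = sps.linregress(x, y)
    n = y.size
    if fit.stderr > 0:
        slope_t = fit.slope / fit.stderr
    else:  # residual variance zero: perfect fit (or exactly constant y)
        slope_t = 0.0 if fit.slope == 0 else math.copysign(math.inf, fit.slope)
    f_stat = slope_t**2
    if math.isfinite(f_stat):
        f_p = float(sps.f.sf(f_stat, 1, n - 2))
    else:
        f_p = 0.0
    return RegressionFit(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
        slope_t=float(slope_t),
        slope_p=float(fit.pvalue),
        f_stat=float(f_stat),
        f_p=f_p,
        r_squared=float(fit.rvalue**2),
        n=n,
    )


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> dict:
    """Two-sided two-sample t-test (Welch by default) with group summaries
    (mean and s.d. per group, the error range convention used here)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return {
        "t": float(res.statistic),
        "p_two_sided": float(res.pvalue),
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


# ---------------------------------------------------------------------------
# qPCR delta-delta-Ct copy number


@dataclass(frozen=True)
class CopyNumberResult:
    delta_ct_sample: float
    delta_ct_calibrator: float
    delta_delta_ct: float
    copy_number: float

    @property
    def amplified(self) -> bool:
        """Strictly more than five estimated copies."""
        return self.copy_number > 5.0


def mdm2_copy_number(
    ct_target_triplicate: Sequence[float],
    ct_reference_triplicate: Sequence[float],
    calibrator_delta_ct: float,
) -> CopyNumberResult:
    """Relative copy number by the delta-delta-Ct method.

    delta-Ct = mean(target Ct) - mean(reference Ct); delta-delta-Ct is
    relative to a normal diploid calibrator, so copy number = 2 * 2^(-ddCt).
    Triplicates expected; shorter replicate vectors are tolerated with a
    warning.
    """
    tgt = np.asarray(ct_target_triplicate, dtype=float)
    ref = np.asarray(ct_reference_triplicate, dtype=float)
    if tgt.size == 0 or ref.size == 0:
        raise ValueError("empty Ct replicate vector")
    if tgt.size < 3 or ref.size < 3:
        warnings.warn(
            f"expected Ct triplicates, got {tgt.size}/{ref.size} replicates",
            stacklevel=2,
        )
    delta_ct = float(tgt.mean() - ref.mean())
    ddct = delta_ct - calibrator_delta_ct
    return CopyNumberResult(
        delta_ct_sample=delta_ct,
        delta_ct_calibrator=calibrator_delta_ct,
        delta_delta_ct=ddct,
        copy_number=2.0 * 2.0 ** (-ddct),
    )


# ---------------------------------------------------------------------------
# the emergence summary (posterior + predictives + fold change)


def emergence_test(
    panel_detections: int = 0,
    panel_n: int = 9,
    baseline_detections: int = 0,
    baseline_n: int = 14,
    treatment_detections: int = 12,
    treatment_n: int = 25,
    prior_alpha: float = 1.0,
    prior_beta: float = 1.0,
) -> dict:
    """The full posterior-predictive emergence argument in one call.

    Fits the detection-probability posterior from the normal panel, then
    evaluates the predictive probability of the observed baseline and
    on-treatment detection counts, both as exact-k and as upper tails, and
    the baseline/treatment fold changes for both variants.
    """
    post = beta_posterior(panel_detections, panel_n, prior_alpha, prior_beta)
    p_base_pmf = beta_binomial_pmf(baseline_detections, baseline_n, post)
    p_base_sf = beta_binomial_sf(baseline_detections, baseline_n, post)
    p_treat_pmf = beta_binomial_pmf(treatment_detections, treatment_n, post)
    p_treat_sf = beta_binomial_sf(treatment_detections, treatment_n, post)
    return {
        "posterior_alpha": post.alpha,
        "posterior_beta": post.beta,
        "baseline_pmf": p_base_pmf,
        "baseline_sf": p_base_sf,
        "treatment_pmf": p_treat_pmf,
        "treatment_sf": p_treat_sf,
        "fold_change_pmf": predictive_fold_change(p_base_pmf, p_treat_pmf),
        "fold_change_sf": predictive_fold_change(p_base_sf, p_treat_sf),
    }
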