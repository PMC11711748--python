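"""Statistical analysis of a simulated (or replayed) threshold study.

Implements the full results pipeline on a study table of block-final JNDs:

* descriptive statistics per perturbation type, including the 5th/95th
  percentile ratio that quantifies between-participant spread;
* paired t-tests with Jeffreys-Zellner-Siow (JZS) Bayes factors — a Cauchy
  prior of scale ``r`` on the standardized effect size against a point null,
  evaluated by numerical integration of the noncentral-t likelihood;
* Pearson correlations with Bayes factors under a stretched-beta prior of
  width ``kappa`` on the population correlation (the beta(1/kappa, 1/kappa)
  distribution rescaled to (-1, 1)), again by numerical integration of the
  exact sampling density of r;
* test-retest reliability of the JND per perturbation type, the classical
  attenuation ceiling ``r_max = sqrt(r11 * r22)`` for the cross-type
  correlation, a t-test of the observed cross-type correlation against that
  ceiling, and an interval Bayes factor for the correlation lying inside a
  null interval around the ceiling;
* Deming (errors-in-variables) regression for block-vs-block scatter;
* steps-to-response summaries and their correlation with the JND.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import integrate, stats
from scipy.special import hyp2f1

from .exceptions import (
    DegenerateDataError,
    DomainError,
    NumericError,
    ParameterError,
    StructureError,
)
from .session import StudyResult

__all__ = [
    "TestResult",
    "CorrelationResult",
    "ReliabilityResult",
    "DemingFit",
    "paired_t",
    "jzs_ttest_bf",
    "pearson_with_bf",
    "pearson_bf",
    "r_max",
    "rmax_interval",
    "test_r_vs_rmax",
    "interval_bf",
    "deming_fit",
    "analyze_study",
]

JZS_PRIOR_SCALE = 0.707     # "medium" Cauchy prior width for t-tests
BETA_PRIOR_WIDTH = 0.333    # "medium" stretched-beta prior width for correlations
BF_MAX = 1e12               # overflow guard for degenerate |r| = 1 inputs


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    bf10: float | None = None
    prior_scale: float | None = None

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ParameterError(f"df must be >= 1, got {self.df}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p_value must be in [0, 1], got {self.p_value}")
        if self.bf10 is not None and not self.bf10 > 0:
            raise ParameterError(f"bf10 must be > 0, got {self.bf10}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    test: TestResult

    def to_dict(self) -> dict:
        return {"r": self.r, "n": self.n, **self.test.to_dict()}


@dataclass(frozen=True)
class ReliabilityResult:
    """Reliabilities, attenuation ceiling and the ceiling comparison."""

    r11: float                 # block-1 vs block-2 correlation, increase type
    r22: float                 # same, decrease type
    r12: CorrelationResult     # cross-type correlation of participant means
    r_max: float               # sqrt(r11 * r22)
    comparison: TestResult     # r12 vs r_max
    null_interval: tuple[float, float]
    interval_bf01: float | None   # None when the interval degenerates to a point

    def to_dict(self) -> dict:
        return {
            "r11": self.r11,
            "r22": self.r22,
            "r12": self.r12.to_dict(),
            "r_max": self.r_max,
            "comparison": self.comparison.to_dict(),
            "null_interval": list(self.null_interval),
            "interval_bf01": self.interval_bf01,
        }


@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float
    lam: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ParameterError("Deming fit parameters must be finite")
        if not self.lam > 0:
            raise ParameterError(f"error-variance ratio lam must be > 0, got {self.lam}")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# t-tests and JZS Bayes factors


def paired_t(x, y, prior_scale: float = JZS_PRIOR_SCALE) -> TestResult:
    """Classical paired t-test with a JZS Bayes factor.

    ``t = mean(d) * sqrt(n) / sd(d)`` on the pairwise differences, df = n-1,
    two-sided p.  Identical pairs give t = 0, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("paired samples must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise DegenerateDataError(f"paired t-test needs n >= 3 pairs, got {n}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise DegenerateDataError("paired t-test does not accept missing pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() != 0.0:
            raise DegenerateDataError("constant non-zero differences: t is unbounded")
        t = 0.0
    else:
        t = float(d.mean() * math.sqrt(n) / sd)
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(statistic=t, df=df, p_value=p,
                      bf10=jzs_ttest_bf(t, n, prior_scale), prior_scale=prior_scale)


def jzs_ttest_bf(t: float, n: int, scale: float = JZS_PRIOR_SCALE) -> float:
    """JZS Bayes factor BF10 for a one-sample / paired design.

    Marginal likelihood of ``t`` (df = n-1) under a Cauchy(0, ``scale``) prior
    on the standardized effect size, over the likelihood under the point
    null, by adaptive quadrature of the noncentral-t density:

    ``BF10 = [integral nct(t; n-1, d*sqrt(n)) Cauchy(d; 0, scale) dd] / t(t; n-1)``
    """
    if n < 2:
        raise ParameterError(f"need n >= 2 pairs, got {n}")
    if not math.isfinite(t):
        raise ParameterError(f"t statistic must be finite, got {t}")
    if scale <= 0:
        raise ParameterError(f"prior scale must be > 0, got {scale}")
    df = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(d):
        return stats.nct.pdf(t, df, d * sqrt_n) * stats.cauchy.pdf(d, 0.0, scale)

    center = t / sqrt_n
    left, err1 = integrate.quad(integrand, -np.inf, center, epsabs=0, epsrel=1e-10, limit=200)
    right, err2 = integrate.quad(integrand, center, np.inf, epsabs=0, epsrel=1e-10, limit=200)
    num = left + right
    den = stats.t.pdf(t, df)
    if not (math.isfinite(num) and num > 0) or (err1 + err2) > 1e-6 * num:
        raise NumericError(
            f"JZS quadrature failed for t={t}, n={n}: integral={num}, abserr={err1 + err2}"
        )
    return float(num / den)


# ---------------------------------------------------------------------------
# correlations under the stretched-beta prior


def _stretched_beta_logpdf(rho, a: float):
    """log density of rho on (-1, 1) with (rho+1)/2 ~ Beta(a, a)."""
    rho = np.asarray(rho, dtype=float)
    return stats.beta.logpdf((rho + 1.0) / 2.0, a, a) - math.log(2.0)


def _corr_loglike(r: float, n: int, rho):
    """Log sampling density of a Pearson r given rho (rho-dependent part).

    Uses the exact small-sample density of the sample correlation from a
    bivariate normal (hypergeometric form), dropping factors that do not
    depend on rho (they cancel in every Bayes-factor ratio).
    """
    rho = np.asarray(rho, dtype=float)
    return (
        0.5 * (n - 1) * np.log1p(-rho**2)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0))
    )


def pearson_bf(r: float, n: int, prior_width: float = BETA_PRIOR_WIDTH) -> float:
    """Bayes factor BF10 for a Pearson correlation by numerical integration.

    Alternative: rho ~ stretched beta of width ``prior_width``; null: rho = 0.
    Perfect correlations (|r| = 1) make the likelihood ratio unbounded and are
    returned as the overflow guard ``BF_MAX``.
    """
    if n < 4:
        raise ParameterError(f"need n >= 4 observations, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ParameterError(f"r must be in [-1, 1], got {r}")
    if prior_width <= 0:
        raise ParameterError(f"prior_width must be > 0, got {prior_width}")
    if 1.0 - r * r < 1e-12:
        return BF_MAX
    a = 1.0 / prior_width

    def integrand(rho):
        return np.exp(_corr_loglike(r, n, rho) + _stretched_beta_logpdf(rho, a))

    left, e1 = integrate.quad(integrand, -1.0, r, epsabs=0, epsrel=1e-10, limit=200)
    right, e2 = integrate.quad(integrand, r, 1.0, epsabs=0, epsrel=1e-10, limit=200)
    num = left + right
    den = math.exp(_corr_loglike(r, n, 0.0))
    if not (math.isfinite(num) and num > 0) or (e1 + e2) > 1e-6 * num:
        raise NumericError(f"correlation-BF quadrature failed for r={r}, n={n}")
    return float(min(num / den, BF_MAX))


def pearson_with_bf(x, y, prior_width: float = BETA_PRIOR_WIDTH) -> CorrelationResult:
    """Pearson r with its t-test and stretched-beta Bayes factor."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("samples must be 1-d arrays of equal length")
    n = len(x)
    if n < 4:
        raise ParameterError(f"need n >= 4 observations, got {n}")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DegenerateDataError("zero variance in x or y: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if 1.0 - r * r < 1e-12:
        t = math.copysign(np.inf, r)
        p = 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), df))
    bf = pearson_bf(r, n, prior_width)
    return CorrelationResult(
        r=r, n=n,
        test=TestResult(statistic=float(t), df=df, p_value=p, bf10=bf, prior_scale=prior_width),
    )


# ---------------------------------------------------------------------------
# reliability, attenuation ceiling, interval Bayes factor


def r_max(r11: float, r22: float) -> float:
    """Attenuation ceiling sqrt(r11 * r22) for two imperfect measures."""
    for name, v in (("r11", r11), ("r22", r22)):
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"reliability {name}={v} outside [0, 1]: ceiling undefined")
    return math.sqrt(r11 * r22)


def test_r_vs_rmax(r_obs: float, rmax: float, n: int) -> TestResult:
    """t-test of an observed correlation against the attenuation ceiling.

    ``t = (r_obs - rmax) * sqrt(n - 2) / sqrt(1 - r_obs**2)``, df = n-2,
    two-sided p.  The construction treats the ceiling as a fixed reference
    value for the observed correlation's standard error.
    """
    if n < 4:
        raise ParameterError(f"need n >= 4, got {n}")
    if abs(r_obs) >= 1.0:
        raise DegenerateDataError(f"|r_obs| must be < 1, got {r_obs}")
    df = n - 2
    t = (r_obs - rmax) * math.sqrt(df) / math.sqrt(1.0 - r_obs**2)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(statistic=float(t), df=df, p_value=p)


def rmax_interval(r11: float, r22: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for the attenuation ceiling.

    Propagates Fisher-z intervals of the two reliabilities through the
    product rule: the interval endpoints are sqrt(lo11 * lo22) and
    sqrt(hi11 * hi22), with negative reliability bounds floored at 0.  This
    construction is an explicit interpretation (the ceiling has no standard
    interval), flagged as such here.
    """
    if n < 4:
        raise ParameterError(f"need n >= 4, got {n}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = 1.0 / math.sqrt(n - 3)
    bounds = []
    for r in (r11, r22):
        if abs(r) >= 1.0:
            bounds.append((max(r, 0.0), max(r, 0.0)))
            continue
        zr = math.atanh(r)
        bounds.append((max(math.tanh(zr - z * se), 0.0), max(math.tanh(zr + z * se), 0.0)))
    lo = math.sqrt(bounds[0][0] * bounds[1][0])
    hi = math.sqrt(bounds[0][1] * bounds[1][1])
    return (lo, hi)


def interval_bf(r_obs: float, n: int, interval: tuple[float, float],
                prior_width: float = BETA_PRIOR_WIDTH) -> float:
    """Bayes factor BF01 for the correlation lying inside a null interval.

    Ratio of posterior to prior odds of ``rho in [L, U]`` under the
    stretched-beta prior and the exact correlation likelihood.  With ``n = 0``
    (no data) the likelihood is flat and the factor is 1 identically.
    """
    L, U = float(interval[0]), float(interval[1])
    if not (-1.0 <= L < U <= 1.0):
        raise ParameterError(f"null interval must satisfy -1 <= L < U <= 1, got {interval}")
    if prior_width <= 0:
        raise ParameterError(f"prior_width must be > 0, got {prior_width}")
    a = 1.0 / prior_width
    prior_in = float(stats.beta.cdf((U + 1) / 2, a, a) - stats.beta.cdf((L + 1) / 2, a, a))
    prior_in = min(max(prior_in, 1e-15), 1.0 - 1e-15)
    if n == 0:
        return 1.0
    if n < 4:
        raise ParameterError(f"need n >= 4 (or n = 0 for the prior identity), got {n}")

    def integrand(rho):
        return np.exp(_corr_loglike(r_obs, n, rho) + _stretched_beta_logpdf(rho, a))

    def piece(lo, hi):
        if hi <= lo:
            return 0.0
        v, _ = integrate.quad(integrand, lo, hi, epsabs=0, epsrel=1e-10, limit=200)
        return v

    # split at r_obs so the likelihood peak never straddles a panel edge
    cuts = sorted({-1.0, L, U, 1.0, min(max(r_obs, -1.0), 1.0)})
    masses = {}
    total = 0.0
    inside = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        v = piece(lo, hi)
        total += v
        if lo >= L - 1e-15 and hi <= U + 1e-15:
            inside += v
    if total <= 0:
        raise NumericError(f"interval-BF quadrature failed for r={r_obs}, n={n}")
    post_in = min(max(inside / total, 1e-15), 1.0 - 1e-15)
    return float((post_in / (1.0 - post_in)) / (prior_in / (1.0 - prior_in)))


# ---------------------------------------------------------------------------
# Deming regression


def deming_fit(x, y, lam: float = 1.0) -> DemingFit:
    """Errors-in-variables straight line with error-variance ratio ``lam``.

    ``lam`` is the ratio of the y-error variance to the x-error variance;
    ``lam = 1`` gives the orthogonal fit, ``lam -> inf`` recovers ordinary
    least squares of y on x.  Closed form from the sample moments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ParameterError("Deming fit needs 1-d samples of equal length >= 3")
    if lam <= 0:
        raise ParameterError(f"lam must be > 0, got {lam}")
    sxx = x.var(ddof=1)
    syy = y.var(ddof=1)
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateDataError("zero variance on an axis: line undefined")
    if sxy == 0.0:
        if syy == lam * sxx:
            raise DegenerateDataError("isotropic cloud: Deming slope indeterminate")
        slope = 0.0 if syy < lam * sxx else np.inf
        if not math.isfinite(slope):
            raise DegenerateDataError("vertical Deming line: slope unbounded")
    else:
        slope = (syy - lam * sxx + math.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (2 * sxy)
    intercept = float(y.mean() - slope * x.mean())
    return DemingFit(slope=float(slope), intercept=intercept, lam=float(lam))


# ---------------------------------------------------------------------------
# full study analysis


def analyze_study(study: StudyResult) -> dict:
    """Compute the complete results report from a study.

    Returns a JSON-serializable nested dict: per-type JND descriptives
    (mean, SD, 5th/95th percentiles and their ratio), the increase-vs-
    decrease paired test, block-1-vs-block-2 stability tests, reliabilities
    with the attenuation-ceiling analysis, Deming fits of the block and type
    scatters, steps-to-response summaries, steps-vs-JND correlations (over
    the late-trial window) and the trial-wise mean estimate / credible-width
    trajectories.
    """
    table = study.table
    counts = table.groupby(["participant", "direction"]).size()
    if (counts < 2).any() or set(counts.index.get_level_values(1)) != {"increase", "decrease"}:
        raise StructureError("each participant needs at least two blocks of each perturbation type")

    means = study.participant_means()
    inc = means[means.direction == "increase"].set_index("participant").sort_index()
    dec = means[means.direction == "decrease"].set_index("participant").sort_index()
    n = len(inc)

    def descriptives(m):
        pct = m["jnd_pct"].to_numpy()
        p5, p95 = np.percentile(pct, [5, 95])
        return {
            "mean_mps": float(m["jnd_mps"].mean()),
            "sd_mps": float(m["jnd_mps"].std(ddof=1)),
            "mean_pct": float(pct.mean()),
            "sd_pct": float(pct.std(ddof=1)),
            "p5_pct": float(p5),
            "p95_pct": float(p95),
            "percentile_factor": float(p95 / p5) if p5 > 0 else float("inf"),
        }

    # block-wise vectors per type, ordered by participant
    by_rep = {}
    for direction in ("increase", "decrease"):
        sub = table[table.direction == direction]
        piv = sub.pivot_table(index="participant", columns="block_rep", values="final_jnd_pct")
        by_rep[direction] = piv.sort_index()

    r11 = float(np.corrcoef(by_rep["increase"][1], by_rep["increase"][2])[0, 1])
    r22 = float(np.corrcoef(by_rep["decrease"][1], by_rep["decrease"][2])[0, 1])
    r12 = pearson_with_bf(inc["jnd_pct"], dec["jnd_pct"])
    ceiling = r_max(max(r11, 0.0), max(r22, 0.0))
    interval = rmax_interval(max(r11, 0.0), max(r22, 0.0), n)
    # a point interval (perfect reliabilities) leaves the interval BF undefined
    bf01 = interval_bf(r12.r, n, interval) if interval[1] - interval[0] > 1e-9 else None
    reliability = ReliabilityResult(
        r11=r11,
        r22=r22,
        r12=r12,
        r_max=ceiling,
        comparison=test_r_vs_rmax(r12.r, ceiling, n),
        null_interval=interval,
        interval_bf01=bf01,
    )

    block_stability = {}
    block_means = {}
    deming = {}
    for direction in ("increase", "decrease"):
        b1 = by_rep[direction][1].to_numpy()
        b2 = by_rep[direction][2].to_numpy()
        block_stability[direction] = paired_t(b1, b2).to_dict()
        block_means[direction] = {
            "block1_mean_pct": float(b1.mean()), "block1_sd_pct": float(b1.std(ddof=1)),
            "block2_mean_pct": float(b2.mean()), "block2_sd_pct": float(b2.std(ddof=1)),
        }
        deming[direction] = deming_fit(b1, b2).to_dict()
    deming["cross_type"] = deming_fit(inc["jnd_pct"].to_numpy(), dec["jnd_pct"].to_numpy()).to_dict()

    # steps to response
    all_steps = [t.steps_to_response for b in study.blocks.values() for t in b.trials if t.responded]
    n_trials_total = sum(len(b.trials) for b in study.blocks.values())
    n_nonresp = sum(1 for b in study.blocks.values() for t in b.trials if not t.responded)
    steps_type_test = paired_t(inc["steps"].to_numpy(), dec["steps"].to_numpy())
    pooled_steps = np.concatenate([inc["steps_late"].to_numpy(), dec["steps_late"].to_numpy()])
    pooled_jnd = np.concatenate([inc["jnd_pct"].to_numpy(), dec["jnd_pct"].to_numpy()])
    if np.isnan(pooled_steps).any():
        # blocks shorter than the late-trial window: the windowed steps/JND
        # correlations are undefined
        steps_jnd = {"overall": None, "increase": None, "decrease": None}
    else:
        steps_jnd = {
            "overall": pearson_with_bf(pooled_steps, pooled_jnd).to_dict(),
            "increase": pearson_with_bf(inc["steps_late"], inc["jnd_pct"]).to_dict(),
            "decrease": pearson_with_bf(dec["steps_late"], dec["jnd_pct"]).to_dict(),
        }

    return {
        "n_participants": int(n),
        "nonresponse_fraction": float(n_nonresp / n_trials_total),
        "jnd": {
            "increase": descriptives(inc),
            "decrease": descriptives(dec),
            "type_difference": paired_t(inc["jnd_pct"], dec["jnd_pct"]).to_dict(),
        },
        "stability": {
            "block_means": block_means,
            "block_difference": block_stability,
            "reliability": reliability.to_dict(),
            "deming": deming,
        },
        "timing": {
            "steps_mean": float(np.mean(all_steps)),
            "steps_sd": float(np.std(all_steps, ddof=1)),
            "per_type_mean": {
                "increase": float(inc["steps"].mean()),
                "decrease": float(dec["steps"].mean()),
            },
            "type_difference": steps_type_test.to_dict(),
            "steps_jnd_correlation": steps_jnd,
        },
        "trajectories": _mean_trajectories(study),
    }


def _mean_trajectories(study: StudyResult) -> dict:
    """Trial-wise mean estimate and credible width per type, truncated at the
    shortest block so every trial index averages over all blocks."""
    out = {}
    for direction in ("increase", "decrease"):
        blocks = [b for b in study.blocks.values() if b.direction == direction]
        m = min(len(b.trials) for b in blocks)
        est = np.stack([b.estimate_trajectory[:m] for b in blocks])
        wid = np.stack([b.ci_width_trajectory[:m] for b in blocks])
        out[direction] = {
            "trial": list(range(1, m + 1)),
            "mean_estimate_mps": est.mean(axis=0).tolist(),
            "mean_ci_width_mps": wid.mean(axis=0).tolist(),
        }
    return out
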