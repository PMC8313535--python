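"""Hill-number diversity with rarefaction/extrapolation and bootstrap CIs.

Implements orders q=0 (clone richness) and q=1 (exponential Shannon
entropy), interpolated to sub-sample sizes and extrapolated beyond the
observed size, with coverage-adjusted bootstrap confidence intervals, a
fixed-point two-sample comparison test, and the D50 clonality index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats
from scipy.special import gammaln

log = logging.getLogger(__name__)

#: Work budget (sum of min(X_i, m) terms) below which the exact
#: hypergeometric-expectation entropy is used instead of Monte Carlo.
EXACT_ENTROPY_BUDGET = 5_000_000


class AbundanceVector:
    """Clone-size counts for one sample; substrate of all estimators."""

    __slots__ = ("counts", "n", "s_obs")

    def __init__(self, counts: Iterable[int]):
        arr = np.asarray(list(counts), dtype=np.int64)
        if arr.size == 0:
            raise ValueError("abundance vector is empty")
        if np.any(arr < 1):
            raise ValueError("all clone counts must be >= 1")
        self.counts = arr
        self.n = int(arr.sum())
        self.s_obs = int(arr.size)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AbundanceVector(n={self.n}, s_obs={self.s_obs})"

    @classmethod
    def from_sizes(cls, sizes: Iterable[int]) -> "AbundanceVector":
        return cls([s for s in sizes if s > 0])


@dataclass(frozen=True, slots=True)
class FrequencyCounts:
    f1: int
    f2: int
    f0_hat: float


@dataclass(frozen=True, slots=True)
class RarefactionSpec:
    """Parameters of one rarefaction/bootstrap run."""

    q: int
    m: int
    B: int = 50
    knots: int = 40
    seed: Optional[int] = None
    resampling: str = "assemblage"  # or "subsample" (without replacement)

    def __post_init__(self) -> None:
        if self.q not in (0, 1):
            raise ValueError("q must be 0 or 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.B < 2:
            raise ValueError("B must be >= 2 (SD over replicates)")
        if self.resampling not in ("assemblage", "subsample"):
            raise ValueError(f"unknown resampling mode {self.resampling!r}")


@dataclass(frozen=True, slots=True)
class BootstrapAssemblage:
    """Coverage-adjusted clone probabilities used to generate replicates."""

    p_hat: np.ndarray
    n_unseen: int
    p_unseen: float
    coverage: float
    lam: float

    def probabilities(self) -> np.ndarray:
        if self.n_unseen == 0:
            return self.p_hat
        return np.concatenate([self.p_hat, np.full(self.n_unseen, self.p_unseen)])


@dataclass(frozen=True, slots=True)
class DiversityEstimate:
    q: int
    m: int
    estimate: float
    entropy: Optional[float] = None  # nats, q=1 only
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    replicate_values: Optional[tuple] = None


@dataclass(frozen=True, slots=True)
class D50Result:
    k: int
    normalized: float


@dataclass(frozen=True, slots=True)
class FixedPointComparison:
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float


@dataclass(frozen=True, slots=True)
class RarefactionCurve:
    q: int
    sizes: np.ndarray
    estimates: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None


def hill_number(x: AbundanceVector, q: int) -> float:
    """Plug-in Hill number of order q over the full sample."""
    if q == 0:
        return float(x.s_obs)
    if q == 1:
        p = x.counts / x.n
        return float(np.exp(-np.sum(p * np.log(p))))
    raise ValueError("q must be 0 or 1")


def shannon_entropy(x: AbundanceVector) -> float:
    """Plug-in Shannon entropy (nats)."""
    p = x.counts / x.n
    return float(-np.sum(p * np.log(p)))


def frequency_counts(x: AbundanceVector) -> FrequencyCounts:
    """Singletons, doubletons, and the Chao1 unseen-clone estimate."""
    f1 = int(np.sum(x.counts == 1))
    f2 = int(np.sum(x.counts == 2))
    n = x.n
    if f2 > 0:
        f0 = (n - 1) / n * f1 * f1 / (2.0 * f2)
    else:
        f0 = (n - 1) / n * f1 * (f1 - 1) / 2.0
    return FrequencyCounts(f1=f1, f2=f2, f0_hat=f0)


def rarefied_richness(x: AbundanceVector, m: int) -> float:
    """Expected number of distinct clones in a size-m subsample (no replacement)."""
    if not 1 <= m <= x.n:
        raise ValueError(f"m must satisfy 1 <= m <= n={x.n}; use extrapolate_richness beyond n")
    n, counts = x.n, x.counts
    keep = (n - counts) >= m
    ratio = np.zeros(x.s_obs)
    if np.any(keep):
        a = n - counts[keep]
        ratio[keep] = np.exp(
            gammaln(a + 1) - gammaln(a - m + 1) - gammaln(n + 1) + gammaln(n - m + 1)
        )
    return float(np.sum(1.0 - ratio))


def _rarefied_entropy_exact(x: AbundanceVector, m: int) -> float:
    """Hypergeometric expectation of the plug-in entropy of a size-m subsample."""
    n = x.n
    log_denom = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
    vals, mult = np.unique(x.counts, return_counts=True)
    h = 0.0
    for xi, w in zip(vals, mult):
        j = np.arange(1, min(int(xi), m) + 1, dtype=np.int64)
        rem = n - int(xi)
        mj = m - j
        valid = mj <= rem
        jv, mjv = j[valid], mj[valid]
        logp = (
            gammaln(xi + 1) - gammaln(jv + 1) - gammaln(xi - jv + 1)
            + gammaln(rem + 1) - gammaln(mjv + 1) - gammaln(rem - mjv + 1)
            - log_denom
        )
        term = (jv / m) * np.log(m / jv)
        h += float(w) * float(np.sum(np.exp(logp) * term))
    return h


def _rarefied_entropy_mc(
    x: AbundanceVector, m: int, rng: np.random.Generator, n_draws: int = 1000
) -> float:
    """Monte-Carlo estimate of the expected subsample entropy (without replacement)."""
    total = 0.0
    for _ in range(n_draws):
        sub = rng.multivariate_hypergeometric(x.counts, m)
        p = sub[sub > 0] / m
        total += -np.sum(p * np.log(p))
    return total / n_draws


def rarefied_shannon(
    x: AbundanceVector,
    m: int,
    mode: str = "auto",
    seed: Optional[int] = None,
    n_draws: int = 1000,
) -> float:
    """Expected subsample Shannon entropy H(m), exact or Monte Carlo."""
    if not 1 <= m <= x.n:
        raise ValueError(f"m must satisfy 1 <= m <= n={x.n}")
    if mode not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    work = int(np.minimum(x.counts, m).sum())
    if mode == "exact" or (mode == "auto" and work <= EXACT_ENTROPY_BUDGET):
        return _rarefied_entropy_exact(x, m)
    if n_draws < 1000:
        raise ValueError("monte_carlo mode requires >= 1000 draws")
    return _rarefied_entropy_mc(x, m, np.random.default_rng(seed), n_draws)


def rarefied_shannon_hill(
    x: AbundanceVector,
    m: int,
    mode: str = "auto",
    seed: Optional[int] = None,
    n_draws: int = 1000,
) -> DiversityEstimate:
    """q=1 interpolated Hill number D(m) = exp(H(m))."""
    h = rarefied_shannon(x, m, mode=mode, seed=seed, n_draws=n_draws)
    return DiversityEstimate(q=1, m=m, estimate=float(np.exp(h)), entropy=h)


def extrapolate_richness(x: AbundanceVector, m_star: int) -> float:
    """Chao1-based expected richness at sample size n + m_star."""
    if m_star < 0:
        raise ValueError("m_star must be >= 0")
    fc = frequency_counts(x)
    if m_star == 0 or fc.f1 == 0 or fc.f0_hat <= 0:
        return float(x.s_obs)
    ratio = fc.f1 / (x.n * fc.f0_hat + fc.f1)
    return float(x.s_obs + fc.f0_hat * (1.0 - (1.0 - ratio) ** m_star))


def asymptotic_entropy(x: AbundanceVector) -> float:
    """Asymptotic (bias-corrected) Shannon entropy estimator, in nats."""
    n = x.n
    if n <= 1:
        return 0.0
    counts = x.counts
    inv = 1.0 / np.arange(1, n)
    csum = np.concatenate([[0.0], np.cumsum(inv)])  # csum[t] = sum_{k=1..t} 1/k
    mask = counts <= n - 1
    xm = counts[mask]
    part1 = float(np.sum((xm / n) * (csum[n - 1] - csum[xm - 1])))
    fc = frequency_counts(x)
    f1, f2 = fc.f1, fc.f2
    if f2 > 0:
        a = 2.0 * f2 / ((n - 1) * f1 + 2.0 * f2)
    elif f1 > 1:
        a = 2.0 / ((n - 1) * (f1 - 1) + 2.0)
    else:
        a = 1.0
    part2 = 0.0
    if f1 > 0 and a < 1.0:
        log1ma = math.log1p(-a)
        r = np.arange(1, n)
        with np.errstate(over="ignore"):
            series = float(np.sum(np.exp((r - (n - 1)) * log1ma) / r))
            lead = math.exp((1 - n) * log1ma) * (-math.log(a))
        part2 = (f1 / n) * (lead - series)
        if not math.isfinite(part2):
            log.warning("asymptotic_entropy: correction term overflowed; dropping it")
            part2 = 0.0
    return part1 + part2


def build_bootstrap_assemblage(x: AbundanceVector) -> BootstrapAssemblage:
    """Coverage-adjusted probabilities over observed plus estimated-unseen clones."""
    n, counts = x.n, x.counts
    fc = frequency_counts(x)
    f1, f2 = fc.f1, fc.f2
    denom_c = (n - 1) * f1 + 2.0 * f2

    naive = False
    if f1 == 0:
        coverage = 1.0
    elif denom_c > 0:
        coverage = 1.0 - (f1 / n) * ((n - 1) * f1 / denom_c)
    else:  # n == 1
        naive = True
        coverage = 0.0

    if naive:
        log.warning("bootstrap assemblage degenerate (n=%d); using naive p_i = X_i/n", n)
        return BootstrapAssemblage(
            p_hat=counts / n, n_unseen=0, p_unseen=0.0, coverage=float(counts.max() / n), lam=0.0
        )

    deficit = 1.0 - coverage
    lam_denom = float(np.sum((counts / n) * (1.0 - counts / n) ** n))
    if deficit == 0.0:
        lam = 0.0
        p_hat = counts / n
    elif lam_denom <= 0.0:
        log.warning("bootstrap assemblage lambda denominator is 0; using naive p_i = X_i/n")
        return BootstrapAssemblage(
            p_hat=counts / n, n_unseen=0, p_unseen=0.0, coverage=coverage, lam=0.0
        )
    else:
        lam = deficit / lam_denom
        p_hat = (counts / n) * (1.0 - lam * (1.0 - counts / n) ** n)
        if np.any(p_hat < 0):
            log.warning("bootstrap assemblage produced negative p_i; clipping and renormalizing")
            p_hat = np.clip(p_hat, 0.0, None)
            p_hat *= (1.0 - deficit) / p_hat.sum()

    n_unseen = math.ceil(fc.f0_hat) if fc.f0_hat > 0 else 0
    if n_unseen == 0 and deficit > 0:
        # Chao1 sees no unseen clones yet coverage < 1 (e.g. f1=1, f2=0):
        # fold the deficit back into the observed clones.
        log.warning("coverage deficit %.4g with no estimated unseen clones; renormalizing", deficit)
        p_hat = p_hat / p_hat.sum()
        deficit = 0.0
    p_unseen = deficit / n_unseen if n_unseen else 0.0
    return BootstrapAssemblage(
        p_hat=p_hat, n_unseen=n_unseen, p_unseen=p_unseen, coverage=coverage, lam=lam
    )


def _interpolated_value(x: AbundanceVector, q: int, m: int) -> float:
    if q == 0:
        return rarefied_richness(x, m)
    return float(np.exp(_rarefied_entropy_exact(x, m)))


def bootstrap_diversity(x: AbundanceVector, spec: RarefactionSpec) -> DiversityEstimate:
    """Interpolated diversity at spec.m with a bootstrap normal-theory 95% CI.

    Default resampling draws n chains multinomially from the coverage-adjusted
    assemblage; ``resampling="subsample"`` instead subsamples m chains without
    replacement from the observed sample (sensitivity mode).
    """
    if spec.m > x.n:
        raise ValueError(f"m={spec.m} exceeds sample size n={x.n}")
    point = _interpolated_value(x, spec.q, spec.m)
    rng = np.random.default_rng(spec.seed)
    reps = np.empty(spec.B)
    if spec.resampling == "assemblage":
        probs = build_bootstrap_assemblage(x).probabilities()
        for b in range(spec.B):
            cb = rng.multinomial(x.n, probs)
            xb = AbundanceVector(cb[cb > 0])
            reps[b] = _interpolated_value(xb, spec.q, min(spec.m, xb.n))
    else:
        for b in range(spec.B):
            sub = rng.multivariate_hypergeometric(x.counts, spec.m)
            xb = AbundanceVector(sub[sub > 0])
            reps[b] = hill_number(xb, spec.q)
    sd = float(np.std(reps, ddof=1))
    ci_low, ci_high = point - 1.96 * sd, point + 1.96 * sd
    # the point estimate must sit inside its own interval
    ci_low, ci_high = min(ci_low, point), max(ci_high, point)
    return DiversityEstimate(
        q=spec.q,
        m=spec.m,
        estimate=point,
        entropy=float(np.log(point)) if spec.q == 1 else None,
        ci_low=ci_low,
        ci_high=ci_high,
        replicate_values=tuple(float(v) for v in reps),
    )


def compare_diversity_at_point(
    x_a: AbundanceVector,
    x_b: AbundanceVector,
    spec: RarefactionSpec,
    flavor: str = "welch",
    labels: tuple[str, str] = ("a", "b"),
) -> FixedPointComparison:
    """Two-sample t-test over bootstrap replicate diversities at a common m."""
    for x, label in zip((x_a, x_b), labels):
        if spec.m > x.n:
            raise ValueError(f"m={spec.m} exceeds n={x.n} of sample {label!r}")
    if flavor not in ("welch", "student"):
        raise ValueError(f"unknown t-test flavor {flavor!r}")
    est_a = bootstrap_diversity(x_a, spec)
    est_b = bootstrap_diversity(x_b, spec)
    reps_a = np.asarray(est_a.replicate_values)
    reps_b = np.asarray(est_b.replicate_values)
    mean_a, mean_b = float(reps_a.mean()), float(reps_b.mean())
    t, p = stats.ttest_ind(reps_a, reps_b, equal_var=(flavor == "student"))
    if math.isnan(t):  # zero variance in both replicate sets
        if math.isclose(mean_a, mean_b, rel_tol=1e-12, abs_tol=1e-12):
            t, p = 0.0, 1.0
        else:
            t, p = math.inf if mean_a > mean_b else -math.inf, float(np.finfo(float).tiny)
    return FixedPointComparison(mean_a=mean_a, mean_b=mean_b, t_statistic=float(t), p_value=float(p))


def d50(x: AbundanceVector) -> D50Result:
    """Smallest number of top clones whose cumulative count reaches half of n."""
    ordered = np.sort(x.counts)[::-1]
    cum = np.cumsum(ordered)
    k = int(np.argmax(cum >= x.n / 2.0)) + 1
    return D50Result(k=k, normalized=k / x.s_obs)


def _curve_sizes(n: int, knots: int) -> np.ndarray:
    sizes = np.unique(np.round(np.linspace(1, 2 * n, knots)).astype(np.int64))
    return np.unique(np.concatenate([sizes, [n]]))


def _curve_values(x: AbundanceVector, q: int, sizes: np.ndarray) -> np.ndarray:
    n = x.n
    if q == 0:
        h_inf = None
    else:
        h_n = shannon_entropy(x)
        h_inf = max(asymptotic_entropy(x), h_n)
    out = np.empty(sizes.size)
    for i, m in enumerate(sizes):
        m = int(m)
        if q == 0:
            out[i] = rarefied_richness(x, m) if m <= n else extrapolate_richness(x, m - n)
        else:
            if m <= n:
                out[i] = math.exp(_rarefied_entropy_exact(x, m))
            else:
                h = (n / m) * h_n + ((m - n) / m) * h_inf
                out[i] = math.exp(h)
    return out


def diversity_curve(
    x: AbundanceVector,
    q: int,
    knots: int = 40,
    B: int = 0,
    seed: Optional[int] = None,
) -> RarefactionCurve:
    """Rarefaction/extrapolation curve from size 1 to 2n.

    Interpolation below n, extrapolation beyond; with ``B >= 2`` a bootstrap
    band (point ± 1.96·SD over assemblage replicates) is attached per size.
    """
    if knots < 2:
        raise ValueError("knots must be >= 2")
    if q not in (0, 1):
        raise ValueError("q must be 0 or 1")
    sizes = _curve_sizes(x.n, knots)
    values = _curve_values(x, q, sizes)
    ci_low = ci_high = None
    if B >= 2:
        rng = np.random.default_rng(seed)
        probs = build_bootstrap_assemblage(x).probabilities()
        rep_curves = np.empty((B, sizes.size))
        for b in range(B):
            cb = rng.multinomial(x.n, probs)
            rep_curves[b] = _curve_values(AbundanceVector(cb[cb > 0]), q, sizes)
        sd = np.std(rep_curves, axis=0, ddof=1)
        ci_low = np.minimum(values - 1.96 * sd, values)
        ci_high = np.maximum(values + 1.96 * sd, values)
    return RarefactionCurve(q=q, sizes=sizes, estimates=values, ci_low=ci_low, ci_high=ci_high)
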