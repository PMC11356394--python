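"""Mismatch distributions, sudden-expansion fitting, Fu's Fs, expansion times.

The sudden-expansion model assumes a population at mutation-scaled size
``theta0`` that grew instantaneously to ``theta1`` at ``tau`` units of
mutational time before the present (``tau = 2ut`` with ``u`` the per-sequence
per-generation mutation rate and ``t`` the time in generations).  Under the
infinite-sites assumption the expected distribution of pairwise differences is

    F_i(tau, theta0, theta1) = integral of Poisson(i; x) against the pairwise
    coalescence-time density of the two-epoch demography,

which for ``theta1 = inf`` reduces to the convolution of a Poisson(tau) pulse
with the geometric-like equilibrium distribution
``Fhat_i(theta0) = theta0^i / (1 + theta0)^(i+1)``.

The fit minimizes the sum of squared deviations (SSD) between observed and
expected mismatch frequencies; goodness of fit (SSD, Harpending's raggedness)
is assessed by parametric bootstrap: samples are re-simulated under the fitted
model with an instantaneous-size-change coalescent, refitted, and the observed
statistics compared against the simulated null distributions.

Fu's Fs evaluates ``S' = Pr(K >= k_obs | theta = pi_hat)`` under the Ewens
sampling distribution (exact, via unsigned Stirling numbers of the first kind
in log space) and reports ``Fs = ln(S'/(1 - S'))``; strongly negative values
indicate an excess of rare haplotypes, as expected after expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._coalescent import simulate_sample_differences
from .errors import DomainError, InsufficientDataError
from .haplotypes import HaplotypeTable, pairwise_distance_matrix


# ---------------------------------------------------------------------------
# mismatch distributions


@dataclass(frozen=True)
class MismatchDistribution:
    """Normalized distribution of pairwise differences among sampled sequences."""

    freq: np.ndarray
    n_pairs: int
    n_samples: int
    weighted: bool = False

    def __post_init__(self):
        if self.freq.size and abs(self.freq.sum() - 1.0) > 1e-9:
            raise DomainError("mismatch frequencies must sum to 1")

    @property
    def d_max(self) -> int:
        return len(self.freq) - 1

    @property
    def mean(self) -> float:
        return float(np.arange(len(self.freq)) @ self.freq)


def mismatch_from_difference_matrix(d: np.ndarray,
                                    counts: Sequence[int] | None = None) -> MismatchDistribution:
    """Mismatch distribution over all sample pairs given a difference matrix.

    ``counts`` expands haplotype-level rows to sample multiplicities (pairs of
    samples sharing a haplotype contribute zero differences).
    """
    if counts is None:
        counts = [1] * d.shape[0]
    counts = np.asarray(counts)
    n = int(counts.sum())
    if n < 2:
        raise InsufficientDataError("mismatch distribution needs >= 2 samples")
    dvals = np.rint(d).astype(int)
    d_max = int(dvals.max()) if dvals.size else 0
    iu = np.triu_indices(d.shape[0], k=1)
    weights = (counts[iu[0]] * counts[iu[1]]).astype(float)
    hist = np.bincount(dvals[iu], weights=weights, minlength=d_max + 1)
    # identical-haplotype pairs
    hist[0] += float((counts * (counts - 1) / 2).sum())
    n_pairs = n * (n - 1) // 2
    return MismatchDistribution(hist / n_pairs, n_pairs, n)


def mismatch_distribution(table: HaplotypeTable) -> MismatchDistribution:
    """Observed mismatch distribution of a haplotype table (samples expanded)."""
    dm = pairwise_distance_matrix(table)
    return mismatch_from_difference_matrix(dm.d, table.counts())


def equilibrium_mismatch(theta: float, i: np.ndarray) -> np.ndarray:
    """Equilibrium pairwise-difference pmf Fhat_i = theta^i / (1+theta)^(i+1)."""
    if theta < 0:
        raise DomainError("theta must be >= 0")
    if theta == 0:
        out = np.zeros_like(i, dtype=float)
        out[i == 0] = 1.0
        return out
    logp = i * math.log(theta) - (i + 1) * math.log1p(theta)
    return np.exp(logp)


def expected_mismatch(tau: float, theta0: float, theta1: float = math.inf,
                      d_max: int = 50) -> MismatchDistribution:
    """Model-expected mismatch distribution, tail folded into the last bin.

    For finite ``theta1`` the recent epoch contributes
    ``integral_0^tau Poisson(i; x) e^{-x/theta1}/theta1 dx`` (evaluated with the
    regularized incomplete gamma function) and the pre-expansion epoch the
    Poisson(tau)-shifted equilibrium term damped by ``e^{-tau/theta1}``.
    """
    if tau < 0 or theta0 < 0 or theta1 <= 0:
        raise DomainError("negative model parameters")
    i = np.arange(d_max + 1)
    pois = stats.poisson.pmf(i, tau) if tau > 0 else np.eye(1, d_max + 1, 0).ravel()
    fhat0 = equilibrium_mismatch(theta0, i)
    # convolution: sum_j Pois(j; tau) * Fhat_{i-j}(theta0)
    conv = np.convolve(pois, fhat0)[: d_max + 1]
    if math.isinf(theta1):
        f = conv
    else:
        lam = 1.0 + 1.0 / theta1
        recent = (1.0 / theta1) * lam ** -(i + 1.0) * special.gammainc(i + 1.0, tau * lam)
        f = recent + math.exp(-tau / theta1) * conv
    f = np.clip(f, 0.0, None)
    # fold all tail mass into the last bin
    f[d_max] += max(0.0, 1.0 - f.sum())
    n = f.sum()
    return MismatchDistribution(f / n, n_pairs=0, n_samples=0)


def harpending_raggedness(dist: MismatchDistribution | np.ndarray) -> float:
    """Harpending's raggedness index r = sum of squared successive differences.

    Uses the conventions x_{-1} = 0 and x_{d+1} = 0, so a point mass at zero
    scores r = 2 and smoother (expansion-like) curves score lower.
    """
    x = dist.freq if isinstance(dist, MismatchDistribution) else np.asarray(dist, float)
    padded = np.concatenate([[0.0], x, [0.0]])
    return float(np.sum(np.diff(padded) ** 2))


def ssd(obs: np.ndarray, exp: np.ndarray) -> float:
    """Sum of squared deviations between two aligned frequency vectors."""
    k = max(len(obs), len(exp))
    o = np.zeros(k)
    e = np.zeros(k)
    o[: len(obs)] = obs
    e[: len(exp)] = exp
    return float(np.sum((o - e) ** 2))


# ---------------------------------------------------------------------------
# sudden-expansion model (statsmodels-style Model / Results pair)


@dataclass(frozen=True)
class SuddenExpansionResults:
    """Point estimates, goodness of fit and bootstrap uncertainty for one fit."""

    tau: float
    theta0: float
    theta1: float
    ssd: float
    hri: float
    p_ssd: float
    p_hri: float
    tau_ci: tuple[float, float]
    n_boot: int
    seed: int | None
    model: "SuddenExpansionModel"

    def expected(self) -> MismatchDistribution:
        return expected_mismatch(self.tau, self.theta0, self.theta1,
                                 self.model.observed.d_max)

    def expansion_time(self, mu_site_year: float = 6.13e-8, gen_years: float = 8.0,
                       L: int = 274) -> "TimeEstimate":
        return expansion_time(self.tau, mu_site_year, gen_years, L)

    def summary(self) -> pd.DataFrame:
        rows = [
            ("tau", self.tau), ("theta0", self.theta0), ("theta1", self.theta1),
            ("tau_ci_low", self.tau_ci[0]), ("tau_ci_high", self.tau_ci[1]),
            ("SSD", self.ssd), ("P(SSD)", self.p_ssd),
            ("HRI", self.hri), ("P(HRI)", self.p_hri),
            ("n_boot", self.n_boot),
        ]
        return pd.DataFrame(rows, columns=["parameter", "value"])


class SuddenExpansionModel:
    """Least-squares fit of the sudden-expansion model to a mismatch distribution.

    Parameters
    ----------
    observed:
        The observed (normalized) mismatch distribution.
    finite_theta1:
        Fit theta1 as a third free parameter instead of fixing it at infinity.
    """

    def __init__(self, observed: MismatchDistribution, finite_theta1: bool = False):
        self.observed = observed
        self.finite_theta1 = finite_theta1

    @classmethod
    def from_table(cls, table: HaplotypeTable, **kwargs) -> "SuddenExpansionModel":
        return cls(mismatch_distribution(table), **kwargs)

    def _objective(self, params: np.ndarray) -> float:
        # simplex steps may wander below zero; fold back into the domain
        tau, theta0 = max(params[0], 0.0), max(params[1], 0.0)
        theta1 = max(params[2], 1e-6) if self.finite_theta1 else math.inf
        exp = expected_mismatch(tau, theta0, theta1, self.observed.d_max)
        return ssd(self.observed.freq, exp.freq)

    def _point_fit(self, obs: MismatchDistribution) -> tuple[float, float, float, float]:
        mean = obs.mean
        starts = [
            (max(mean - 0.1, 0.01), 0.1),
            (max(0.9 * mean, 0.01), max(0.1 * mean, 0.01)),
            (max(0.5 * mean, 0.01), max(0.5 * mean, 0.01)),
            (0.01, max(mean, 0.01)),
        ]
        best = None
        saved = self.observed
        self.observed = obs
        try:
            for s in starts:
                x0 = list(s) + ([10.0 * max(mean, 1.0)] if self.finite_theta1 else [])
                res = optimize.minimize(
                    self._objective, x0, method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 4000},
                )
                x = np.clip(res.x, 0.0, None)
                val = self._objective(x)
                if best is None or val < best[-1]:
                    best = (*x, val)
        finally:
            self.observed = saved
        if self.finite_theta1:
            tau, theta0, theta1, val = best
        else:
            tau, theta0, val = best
            theta1 = math.inf
        return float(tau), float(theta0), float(theta1), float(val)

    def fit(self, n_boot: int = 1000, seed: int | None = None) -> SuddenExpansionResults:
        """Fit (tau, theta0[, theta1]) and bootstrap SSD/HRI P-values and tau CI.

        Degenerate observations with all mass at zero yield tau = 0 with a
        warning-free trivial fit.  P-values use the (b + 1)/(B + 1) convention.
        """
        obs = self.observed
        if obs.freq[0] >= 1.0 - 1e-12:
            return SuddenExpansionResults(
                tau=0.0, theta0=0.0, theta1=math.inf, ssd=0.0,
                hri=harpending_raggedness(obs), p_ssd=1.0, p_hri=1.0,
                tau_ci=(0.0, 0.0), n_boot=0, seed=seed, model=self)
        tau, theta0, theta1, fit_ssd = self._point_fit(obs)
        hri_obs = harpending_raggedness(obs)

        p_ssd = p_hri = math.nan
        tau_ci = (tau, tau)
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            n = obs.n_samples
            if n < 2:
                raise InsufficientDataError(
                    "bootstrap requires the sample size of the observed distribution")
            ssd_null, hri_null, tau_null = [], [], []
            for _ in range(n_boot):
                d = simulate_sample_differences(n, theta0, tau, theta1, rng)
                sim = mismatch_from_difference_matrix(d)
                t_b, th0_b, th1_b, ssd_b = self._point_fit(sim)
                ssd_null.append(ssd_b)
                hri_null.append(harpending_raggedness(sim))
                tau_null.append(t_b)
            ssd_null = np.array(ssd_null)
            hri_null = np.array(hri_null)
            p_ssd = (np.sum(ssd_null >= fit_ssd) + 1) / (n_boot + 1)
            p_hri = (np.sum(hri_null >= hri_obs) + 1) / (n_boot + 1)
            lo, hi = np.percentile(tau_null, [2.5, 97.5])
            tau_ci = (min(float(lo), tau), max(float(hi), tau))
        return SuddenExpansionResults(
            tau=tau, theta0=theta0, theta1=theta1, ssd=fit_ssd, hri=hri_obs,
            p_ssd=float(p_ssd), p_hri=float(p_hri), tau_ci=tau_ci,
            n_boot=n_boot, seed=seed, model=self)


def fit_sudden_expansion(obs: MismatchDistribution, n_boot: int = 1000,
                         seed: int | None = None) -> SuddenExpansionResults:
    """Functional wrapper around :class:`SuddenExpansionModel`."""
    return SuddenExpansionModel(obs).fit(n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Fu's Fs


@lru_cache(maxsize=64)
def _log_stirling_first_kind(n: int) -> tuple[float, ...]:
    """log |s(n, k)| for k = 0..n, computed exactly with integer arithmetic."""
    row = [1]
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            prev_k = row[k] if k < len(row) else 0
            new[k] = row[k - 1] + (m - 1) * prev_k
        row = new

    def log_int(x: int) -> float:
        if x == 0:
            return -math.inf
        shift = max(0, x.bit_length() - 53)
        return math.log(x >> shift) + shift * math.log(2.0)

    return tuple(log_int(v) for v in row)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k) for k = 0..n under the Ewens sampling distribution."""
    if theta <= 0:
        raise DomainError("theta must be positive")
    log_s = np.array(_log_stirling_first_kind(n))
    k = np.arange(n + 1)
    log_norm = float(np.sum(np.log(theta + np.arange(n))))
    return log_s + k * math.log(theta) - log_norm


@dataclass(frozen=True)
class FuResult:
    fs: float
    s_prime: float
    p: float
    n_sim: int
    seed: int | None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.fs)


def _fs_statistic(n: int, k_obs: int, theta: float) -> tuple[float, float]:
    """(Fs, S') computed in log space; returns NaNs when undefined."""
    if theta <= 0 or k_obs <= 1:
        return math.nan, math.nan
    logp = ewens_log_pmf(n, theta)
    log_upper = special.logsumexp(logp[k_obs:])
    log_lower = special.logsumexp(logp[:k_obs])
    s_prime = math.exp(log_upper)
    fs = log_upper - log_lower  # = ln(S'/(1-S')) without cancellation
    return fs, s_prime


def fus_fs(N: int, k_obs: int, pi_hat: float, n_sim: int = 1000,
           seed: int | None = None) -> FuResult:
    """Fu's Fs with bootstrap P-value from neutral coalescent simulations.

    ``pi_hat`` is the observed mean number of pairwise differences per
    sequence pair (used as the theta estimate).  The P-value is the fraction
    of constant-size neutral simulations at that theta whose Fs is at most the
    observed value — small P supports expansion.  ``k_obs = 1`` or
    ``pi_hat = 0`` make the statistic undefined (NaN, by convention).
    """
    if N < 2 or not (1 <= k_obs <= N):
        raise DomainError(f"invalid (N, k_obs) = ({N}, {k_obs})")
    if pi_hat < 0:
        raise DomainError("pi_hat must be >= 0")
    fs, s_prime = _fs_statistic(N, k_obs, pi_hat)
    if math.isnan(fs):
        return FuResult(math.nan, math.nan, math.nan, 0, seed)
    p = math.nan
    if n_sim > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_sim):
            d = simulate_sample_differences(N, theta0=pi_hat, tau=0.0, rng=rng)
            # distinct haplotypes = distinct rows of the difference pattern
            k_sim = len({tuple(row) for row in np.rint(d).astype(int)})
            iu = np.triu_indices(N, k=1)
            pi_sim = float(d[iu].mean()) if iu[0].size else 0.0
            fs_sim, _ = _fs_statistic(N, k_sim, pi_sim)
            if not math.isnan(fs_sim) and fs_sim <= fs:
                hits += 1
        p = (hits + 1) / (n_sim + 1)
    return FuResult(fs=fs, s_prime=s_prime, p=p, n_sim=n_sim, seed=seed)


# ---------------------------------------------------------------------------
# expansion-time conversion


@dataclass(frozen=True)
class TimeEstimate:
    """Calendar conversion of tau via t = tau / (2u)."""

    years: float
    generations: float
    mu_site_year: float
    gen_years: float
    L: int


def expansion_time(tau: float, mu_site_year: float = 6.13e-8,
                   gen_years: float = 8.0, L: int = 274) -> TimeEstimate:
    """Convert tau to calendar years: t_years = tau / (2 * mu_site_year * L).

    The per-generation, per-sequence rate is u = mu_site_year * gen_years * L;
    generations = tau / (2u) and years = generations * gen_years, in which
    gen_years cancels — the calendar estimate depends only on the per-year
    rate and the sequence length.
    """
    if tau < 0:
        raise DomainError("tau must be >= 0")
    if mu_site_year <= 0 or gen_years <= 0 or L <= 0:
        raise DomainError("rates, generation time and length must be positive")
    u = mu_site_year * gen_years * L
    generations = tau / (2.0 * u)
    return TimeEstimate(years=generations * gen_years, generations=generations,
                        mu_site_year=mu_site_year, gen_years=gen_years, L=L)
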