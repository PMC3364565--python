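"""Mutation-frequency, fold-elevation, per-site-rate and fluctuation analysis.

Mutation frequency is the fraction of drug-resistant colonies among viable
cells (dilution-corrected); fold elevations compare a treated frequency to
its untreated/empty-vector control and are reported half-up-rounded to
integers. Genome-wide per-site base-substitution rates average per-strain
ratios (mutations / callable sites / generations) with the standard error
of that mean. Forward mutation rates from parallel-culture fluctuation
experiments are estimated either from the zero-mutant fraction (p0 method,
m = -ln p0) or by maximum likelihood under the Luria-Delbrück mutant-count
distribution, whose probabilities follow the Ma-Sandri-Sarkar recursion

    p_0 = exp(-m),    p_k = (m / k) * sum_{i=0}^{k-1} p_i / (k - i + 1).

The per-division rate is mu = m / N_final.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class FrequencyObservation:
    """Colony counts from one selection experiment."""

    resistant_colonies: int
    total_colonies: float  # colonies on the non-selective plate
    dilution_factor: float = 1.0  # non-selective plate dilution vs selective
    condition_label: str = ""

    def __post_init__(self) -> None:
        if self.resistant_colonies < 0 or self.total_colonies < 0:
            raise ValueError("colony counts must be non-negative")
        if self.total_colonies == 0:
            raise ValueError("total_colonies must be positive")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be positive")


def mutation_frequency(obs: FrequencyObservation) -> float:
    """Mutants per viable cell: resistant / (total x dilution factor)."""
    return obs.resistant_colonies / (obs.total_colonies * obs.dilution_factor)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fold_elevation(freq: float, control_freq: float) -> tuple[float, int]:
    """Frequency relative to control: exact ratio and the integer-rounded
    (half-up) report value. Scale-invariant in the common factor."""
    if control_freq <= 0:
        raise ValueError("control frequency must be positive")
    if freq < 0:
        raise ValueError("frequency must be non-negative")
    ratio = freq / control_freq
    return ratio, round_half_up(ratio)


@dataclass(frozen=True)
class RateEstimate:
    """Per-site base-substitution rate averaged over strains."""

    per_site_rate: float
    standard_error: float
    n_strains: int
    generations: float
    per_strain_rates: tuple[float, ...]


def per_site_rate(
    snv_counts: Sequence[float],
    callable_sites: Sequence[float],
    generations: float = 1.0,
) -> RateEstimate:
    """Mean of per-strain rates n_i / (s_i * generations), with SE = sd/sqrt(n).

    ``generations=1`` gives a per-site-per-treatment rate (chemical pulse
    mutagenesis); ``generations≈30`` gives a per-site-per-division rate for
    a mutator grown that many generations.
    """
    n = np.asarray(snv_counts, dtype=float)
    s = np.asarray(callable_sites, dtype=float)
    if n.shape != s.shape or n.ndim != 1 or n.size == 0:
        raise ValueError("snv_counts and callable_sites must be equal-length 1-D")
    if (s <= 0).any():
        raise ValueError("callable_sites must be positive")
    if generations <= 0:
        raise ValueError("generations must be positive")
    rates = n / (s * generations)
    se = (
        float(np.std(rates, ddof=1) / np.sqrt(rates.size))
        if rates.size > 1
        else float("nan")
    )
    return RateEstimate(
        per_site_rate=float(np.mean(rates)),
        standard_error=se,
        n_strains=int(rates.size),
        generations=float(generations),
        per_strain_rates=tuple(float(r) for r in rates),
    )


def luria_delbruck_pmf(m: float, k_max: int) -> np.ndarray:
    """Luria-Delbrück mutant-count probabilities p_0..p_k_max (MSS recursion)."""
    if m < 0:
        raise ValueError("m must be non-negative")
    p = np.zeros(k_max + 1)
    p[0] = math.exp(-m)
    for k in range(1, k_max + 1):
        i = np.arange(k)
        p[k] = (m / k) * np.sum(p[:k] / (k - i + 1.0))
    return p


def _log_likelihood(
    m: float, counts: np.ndarray, ceiling: int = 1000
) -> float:
    """Log likelihood under the MSS distribution, censored at ``ceiling``.

    The mutant-count distribution is heavy-tailed (jackpot cultures), so
    counts at or above the ceiling contribute the tail mass
    P(X >= ceiling) instead of a point probability; below it the recursion
    runs to the largest observed count.
    """
    k_top = int(min(counts.max(), ceiling))
    pmf = luria_delbruck_pmf(m, k_top)
    capped = np.minimum(counts, ceiling)
    with np.errstate(divide="ignore"):
        ll = 0.0
        if (capped < ceiling).any():
            ll += float(np.sum(np.log(pmf[capped[capped < ceiling]])))
        n_cens = int((capped >= ceiling).sum())
        if n_cens:
            tail = max(1.0 - float(pmf[:ceiling].sum()), 1e-300)
            ll += n_cens * math.log(tail)
    return ll


@dataclass(frozen=True)
class FluctuationResult:
    """Fluctuation-analysis estimate of mutations per culture and rate."""

    m: float
    mu: float  # per cell division: m / final_population
    n_cultures: int
    final_population: float
    method: str  # "p0" or "mss_mle"
    confidence_interval: tuple[float, float]  # 95% CI on m


def _mle_confidence_interval(
    m_hat: float, counts: np.ndarray, max_m: float
) -> tuple[float, float]:
    """Profile-likelihood 95% CI: m where log L drops by qchisq(.95,1)/2."""
    ll_hat = _log_likelihood(m_hat, counts)
    drop = stats.chi2.ppf(0.95, df=1) / 2.0

    def g(m: float) -> float:
        return _log_likelihood(m, counts) - (ll_hat - drop)

    lo = 0.0
    if m_hat > 1e-9 and g(1e-9) < 0:
        lo = float(optimize.brentq(g, 1e-9, m_hat, xtol=1e-9))
    hi = max_m
    if g(max_m) < 0:
        hi = float(optimize.brentq(g, m_hat, max_m, xtol=1e-9))
    return (lo, hi)


def fluctuation_rate(
    mutant_counts: Sequence[int],
    final_population: float,
    method: str = "mss_mle",
) -> FluctuationResult:
    """Estimate the expected mutations per culture m and the rate mu.

    ``p0``: m = -ln(fraction of zero-mutant cultures), with a normal-
    approximation CI on m. Requires at least one zero-mutant culture.
    ``mss_mle``: maximizes the Luria-Delbrück likelihood (MSS recursion run
    to the largest observed count, with jackpot cultures above 1000 mutants
    entering as right-censored tail mass) by bounded scalar search, with a
    profile-likelihood 95% CI.
    """
    counts = np.asarray(mutant_counts, dtype=int)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need at least 2 parallel cultures")
    if (counts < 0).any():
        raise ValueError("mutant counts must be non-negative")
    if final_population <= 0:
        raise ValueError("final_population must be positive")
    n = counts.size

    if method == "p0":
        n_zero = int((counts == 0).sum())
        if n_zero == 0:
            raise ValueError(
                "p0 method needs at least one zero-mutant culture; use mss_mle"
            )
        p0 = n_zero / n
        m = -math.log(p0)
        # delta-method SE of -ln(p0_hat) from the binomial zero fraction
        se_m = math.sqrt((1 - p0) / (n * p0))
        ci = (max(0.0, m - 1.96 * se_m), m + 1.96 * se_m)
    elif method == "mss_mle":
        if counts.max() == 0:
            warnings.warn(
                "all cultures have zero mutants: m is estimated as 0 "
                "(degenerate data)",
                stacklevel=2,
            )
            return FluctuationResult(
                m=0.0,
                mu=0.0,
                n_cultures=n,
                final_population=float(final_population),
                method=method,
                confidence_interval=(0.0, 3.0 / n),  # rule-of-three on p0
            )
        max_m = float(min(int(counts.max()), 1000) + 5)
        res = optimize.minimize_scalar(
            lambda m: -_log_likelihood(m, counts),
            bounds=(1e-6, max_m),
            method="bounded",
            options={"xatol": 1e-6},
        )
        m = float(res.x)
        ci = _mle_confidence_interval(m, counts, max_m)
    else:
        raise ValueError(f"unknown method {method!r}")

    return FluctuationResult(
        m=m,
        mu=m / final_population,
        n_cultures=n,
        final_population=float(final_population),
        method=method,
        confidence_interval=ci,
    )


def simulate_luria_delbruck(
    m: float,
    n_cultures: int,
    rng: np.random.Generator,
    *,
    max_clone: int = 10_000_000,
) -> np.ndarray:
    """Generative Luria-Delbrück simulation, independent of the MSS recursion.

    Mutation events per culture are Poisson(m); each event founds a clone
    whose final size J follows the Lea-Coulson distribution
    P(J >= j) = 1/j (j = 1, 2, ...), sampled as floor(1/U). Clone sizes are
    capped at ``max_clone`` (the infinite-mean tail never matters for the
    small counts analysed here).
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    out = np.zeros(n_cultures, dtype=int)
    events = rng.poisson(m, size=n_cultures)
    for i, k in enumerate(events):
        if k:
            u = rng.random(k)
            out[i] = int(np.minimum(np.floor(1.0 / u), max_clone).sum())
    return out
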