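"""Posterior presence/absence probabilities per variant and sample.

Model: given true variant allele fraction f, a read supports the variant with
probability theta(f) = f*(1-e) + (1-f)*e/3 (a sequencing error produces one
specific wrong base out of three; ``error_channel="full"`` uses e instead of
e/3).  The number of supporting reads K out of N is Binomial(N, theta(f)).

The prior on f is a spike-and-slab: mass c0 on {f = 0} and mass 1 - c0 on a
two-segment slab over (0, u] with u = max(gamma/2, f_absent + eps), where
gamma is the sample's neoplastic cell content -- a heterozygous-diploid clonal
variant has expected VAF gamma/2.  The slab places a fixed fraction
w = f_absent / (f_absent + eps) of its mass uniformly on (0, f_absent] and
the rest uniformly on (f_absent, u]; at the minimal support u = f_absent +
eps this is exactly the uniform slab, and holding the sub-threshold mass
fixed makes the absence posterior q provably non-decreasing in gamma for
K = 0 (a plain uniform slab dips just above the support transition).
"Absent" is the event {f = 0} union {0 < f <= f_absent}; its posterior mass
is q, and p = 1 - q.

Because theta is affine in f, the slab integrals have a closed form in the
regularized incomplete beta function; a log-space quadrature fallback handles
the rare regimes where the beta differences underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from phyloseed.datamodel import PatientConfig, VariantCallMatrix

__all__ = ["PresenceTable", "PriorSpec", "posterior_presence", "presence_table"]


@dataclass(frozen=True)
class PriorSpec:
    """Spike-and-slab prior on the VAF of one sample.

    The slab over (0, upper] carries mass ``below_fraction`` uniformly on
    (0, f_absent] and the remainder uniformly on (f_absent, upper].
    """

    c0: float
    upper: float
    f_absent: float
    below_fraction: float

    def slab_density(self, f: float) -> float:
        if f <= self.f_absent:
            return self.below_fraction / self.f_absent
        if f <= self.upper:
            return (1.0 - self.below_fraction) / (self.upper - self.f_absent)
        return 0.0


def prior_spec(gamma: float, config: PatientConfig) -> PriorSpec:
    upper = max(gamma / 2.0, config.f_absent + config.prior_eps)
    w = config.f_absent / (config.f_absent + config.prior_eps)
    return PriorSpec(c0=config.c0, upper=upper, f_absent=config.f_absent, below_fraction=w)


@dataclass
class PresenceTable:
    """Posterior presence (p) and absence (q) probabilities, m x n."""

    p: np.ndarray
    q: np.ndarray
    samples: list[str]
    variants: list[str]

    def __post_init__(self) -> None:
        if self.p.shape != self.q.shape:
            raise ValueError("p and q must share dimensions")
        if not np.allclose(self.p + self.q, 1.0, atol=1e-9):
            raise ValueError("p + q must equal 1 elementwise")

    @property
    def n_samples(self) -> int:
        return self.p.shape[1]

    @property
    def n_variants(self) -> int:
        return self.p.shape[0]

    def to_frame(self) -> "object":
        import pandas as pd

        return pd.DataFrame(self.p, index=self.variants, columns=self.samples)


def _theta_params(e: float, channel: str) -> tuple[float, float]:
    """Intercept theta(0) and slope of theta(f) = theta0 + slope*f."""
    theta0 = e / 3.0 if channel == "third" else e
    slope = 1.0 - e - theta0
    return theta0, slope


def _prior_upper(gamma: float, config: PatientConfig) -> float:
    return max(gamma / 2.0, config.f_absent + config.prior_eps)


def _slab_integral(K: int, N: int, f_lo: float, f_hi: float, theta0: float, slope: float) -> float:
    """integral over [f_lo, f_hi] of Binom(K; N, theta(f)) df, closed form.

    With t = theta(f): integral = (I_t(hi) - I_t(lo)) / ((N+1) * slope), where
    I is the regularized incomplete beta with parameters (K+1, N-K+1).
    """
    t_lo = theta0 + slope * f_lo
    t_hi = theta0 + slope * f_hi
    hi = special.betainc(K + 1, N - K + 1, t_hi)
    lo = special.betainc(K + 1, N - K + 1, t_lo)
    return max(hi - lo, 0.0) / ((N + 1) * slope)


def _log_quadrature(K: int, N: int, f_lo: float, f_hi: float, theta0: float, slope: float, n_grid: int = 20001) -> float:
    """Log of the slab integral by trapezoid quadrature of the log-likelihood."""
    f = np.linspace(f_lo, f_hi, n_grid)
    logs = stats.binom.logpmf(K, N, theta0 + slope * f)
    w = np.full(n_grid, (f_hi - f_lo) / (n_grid - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    return special.logsumexp(logs, b=w)


def posterior_presence(K: int, N: int, gamma: float, config: PatientConfig | None = None) -> tuple[float, float]:
    """Posterior probability (p, q) that a variant is present/absent.

    Parameters
    ----------
    K, N : int
        Variant-supporting reads and total coverage, 0 <= K <= N.
    gamma : float
        Neoplastic cell content of the sample, in (0, 1].

    Returns
    -------
    (p, q) with p + q = 1.
    """
    config = config or PatientConfig()
    if K < 0 or N < 0 or K > N:
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"purity must lie in (0, 1], got {gamma}")
    prior = prior_spec(gamma, config)
    fa, upper, w = prior.f_absent, prior.upper, prior.below_fraction
    if N == 0:
        q = config.c0 + (1.0 - config.c0) * w
        return 1.0 - q, q

    theta0, slope = _theta_params(config.e, config.error_channel)
    c0 = config.c0
    dens_lo = (1.0 - c0) * w / fa
    dens_hi = (1.0 - c0) * (1.0 - w) / (upper - fa)
    spike = c0 * stats.binom.pmf(K, N, theta0)
    int_absent = dens_lo * _slab_integral(K, N, 0.0, fa, theta0, slope)
    int_present = dens_hi * _slab_integral(K, N, fa, upper, theta0, slope)
    numer = spike + int_absent
    denom = numer + int_present
    if denom <= 0.0:
        # underflow regime: redo in log space
        log_spike = np.log(c0) + stats.binom.logpmf(K, N, theta0)
        log_absent = np.logaddexp(log_spike, np.log(dens_lo) + _log_quadrature(K, N, 0.0, fa, theta0, slope))
        log_total = np.logaddexp(log_absent, np.log(dens_hi) + _log_quadrature(K, N, fa, upper, theta0, slope))
        q = float(np.exp(log_absent - log_total))
    else:
        q = float(numer / denom)
    q = min(max(q, 0.0), 1.0)
    return 1.0 - q, q


def presence_table(matrix: VariantCallMatrix, config: PatientConfig | None = None) -> PresenceTable:
    """Elementwise posterior presence probabilities for a whole matrix."""
    config = config or PatientConfig()
    if matrix.purity is None:
        raise ValueError("matrix must carry per-sample purities (run estimate_purity first)")
    m, n = matrix.n_variants, matrix.n_samples
    p = np.empty((m, n))
    q = np.empty((m, n))
    cache: dict[tuple[int, int, float], tuple[float, float]] = {}
    for j in range(n):
        gamma = float(matrix.purity[j])
        for i in range(m):
            key = (int(matrix.mut_reads[i, j]), int(matrix.coverage[i, j]), gamma)
            if key not in cache:
                cache[key] = posterior_presence(key[0], key[1], gamma, config)
            p[i, j], q[i, j] = cache[key]
    return PresenceTable(p=p, q=q, samples=list(matrix.samples), variants=list(matrix.variants))
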