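"""Frequency–fluctuation correlation functions and spectral-diffusion times.

C(t) = ⟨δω(t)δω(0)⟩ is computed per replica after subtracting that
replica's unweighted mean frequency, with the unbiased per-lag pair-count
denominator, then averaged pointwise across replicas with equal weights.
The averaged curve is fitted once with a biexponential
A₁·exp(−t/τ₁) + A₂·exp(−t/τ_c) + y₀ (lag 0 excluded by default, since the
motionally narrowed ultrafast component contaminates it), and the
spectral-diffusion time τ_c is the longest of the two time constants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitConvergenceError
from .observables import ModeSeries

__all__ = [
    "CorrelationSeries",
    "BiexponentialFit",
    "compute_ffcf",
    "fit_biexponential",
    "extract_tau_c",
]

#: initial-guess grid for (τ₁, τ_c), ps
TAU_STARTS = tuple(itertools.product((0.05, 0.1, 0.5), (0.5, 1.0, 2.0)))


@dataclass(frozen=True)
class CorrelationSeries:
    """Replica-averaged FFCF on a uniform lag grid."""

    lag_ps: np.ndarray
    c: np.ndarray  # cm⁻²
    n_pairs: np.ndarray  # contributing origin pairs per lag, summed over replicas
    dt_fs: float

    def __post_init__(self):
        object.__setattr__(self, "lag_ps", np.asarray(self.lag_ps, float))
        object.__setattr__(self, "c", np.asarray(self.c, float))
        object.__setattr__(self, "n_pairs", np.asarray(self.n_pairs, int))
        if self.lag_ps[0] != 0.0:
            raise ValueError("lag grid must start at 0")
        if np.any(np.diff(self.n_pairs) > 0):
            raise ValueError("pairs per lag must decrease with lag")


@dataclass(frozen=True)
class BiexponentialFit:
    """A₁e^{−t/τ₁} + A₂e^{−t/τ_c} + y₀ with τ_c ≥ τ₁ by convention."""

    a1: float
    tau1: float
    a2: float
    tau_c: float
    y0: float
    se: dict[str, float]
    r2: float
    effectively_monoexponential: bool = False

    def __post_init__(self):
        if self.tau1 <= 0 or self.tau_c <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_c < self.tau1:
            raise ValueError("convention requires tau_c >= tau1")


def compute_ffcf(series: ModeSeries, max_lag_ps: float | None = None) -> CorrelationSeries:
    """Replica-averaged frequency autocorrelation of δω.

    δω is each replica's frequency minus that replica's unweighted mean,
    so C is invariant under adding a constant to all frequencies and C(0)
    equals the pooled δω variance. ``max_lag_ps`` defaults to half the
    shortest replica duration and may not exceed it.
    """
    chunks = list(series.usable().replica_slices())
    if not chunks:
        raise ValueError("series has no converged snapshots")
    n_min = min(len(x) for _, x in chunks)
    if n_min < 10:
        raise ValueError(f"each replica needs >= 10 samples (shortest has {n_min})")
    dt_ps = series.dt_fs / 1000.0
    half_dur = (n_min - 1) * dt_ps / 2.0
    if max_lag_ps is None:
        max_lag_ps = half_dur
    k_max = int(np.floor(max_lag_ps / dt_ps + 1e-9))
    if k_max * dt_ps > half_dur + 1e-12:
        raise ValueError(
            f"max_lag {max_lag_ps} ps exceeds half the shortest replica duration "
            f"({half_dur:.4f} ps)"
        )

    acc = np.zeros(k_max + 1)
    pairs = np.zeros(k_max + 1, dtype=int)
    for _, x in chunks:
        d = x - x.mean()
        n = len(d)
        full = np.correlate(d, d, mode="full")[n - 1 : n + k_max]
        cnt = n - np.arange(k_max + 1)
        acc += full / cnt
        pairs += cnt
    c = acc / len(chunks)
    lags = dt_ps * np.arange(k_max + 1)
    return CorrelationSeries(lags, c, pairs, series.dt_fs)


def _biexp(t, a1, tau1, a2, tau2, y0):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + y0


def _biexp_jac(t, a1, tau1, a2, tau2, y0):
    e1 = np.exp(-t / tau1)
    e2 = np.exp(-t / tau2)
    return np.column_stack([e1, a1 * t / tau1**2 * e1, e2, a2 * t / tau2**2 * e2,
                            np.ones_like(t)])


def fit_biexponential(
    corr: CorrelationSeries, include_lag0: bool = False
) -> BiexponentialFit:
    """Multi-start nonlinear least-squares biexponential fit of the FFCF.

    Starts scan (τ₁, τ_c) over a fs×ps grid with amplitudes split evenly
    from the first fitted point; the lowest-residual converged fit wins.
    Parameter standard errors come from the fit covariance. The result is
    flagged effectively monoexponential when one amplitude falls below 2%
    of the first fitted correlation value.
    """
    k0 = 0 if include_lag0 else 1
    t = corr.lag_ps[k0:]
    y = corr.c[k0:]
    if len(t) < 8:
        raise ValueError("need at least 8 lag points to fit")

    c_first = max(abs(y[0]), 1e-12)
    lb = [0.0, 1e-4, 0.0, 1e-4, -np.inf]
    ub = [np.inf, np.inf, np.inf, np.inf, np.inf]
    best = None
    scale = float(np.sum(y**2)) or 1.0
    for tau1_0, tau2_0 in TAU_STARTS:
        p0 = [c_first / 2, tau1_0, c_first / 2, tau2_0, 0.0]
        try:
            popt, pcov = curve_fit(_biexp, t, y, p0=p0, bounds=(lb, ub),
                                   jac=_biexp_jac, maxfev=800)
        except RuntimeError:
            continue
        ss = float(np.sum((y - _biexp(t, *popt)) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt, pcov)
        if ss < 1e-16 * scale:  # essentially exact; later starts cannot improve
            break
    if best is None:
        raise FitConvergenceError("biexponential fit failed from every start")

    ss_res, popt, pcov = best
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(5, np.nan)
    a1, tau1, a2, tau2, y0 = (float(v) for v in popt)
    e_a1, e_t1, e_a2, e_t2, e_y0 = (float(v) for v in perr)
    if tau1 > tau2:  # relabel so tau_c is the longest time
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
        e_a1, e_a2, e_t1, e_t2 = e_a2, e_a1, e_t2, e_t1
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    mono = min(a1, a2) < 0.02 * c_first or abs(tau2 - tau1) < 1e-9
    return BiexponentialFit(
        a1=a1, tau1=tau1, a2=a2, tau_c=tau2, y0=y0,
        se={"a1": e_a1, "tau1": e_t1, "a2": e_a2, "tau_c": e_t2, "y0": e_y0},
        r2=r2, effectively_monoexponential=mono,
    )


def extract_tau_c(fit: BiexponentialFit) -> tuple[float, float]:
    """Spectral-diffusion time: the longest time constant, with 95% half-width."""
    return fit.tau_c, 1.96 * fit.se["tau_c"]
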