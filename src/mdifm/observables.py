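"""Vibrational observables: central frequencies, fluctuation amplitudes,
distributions, coordination-resolved subdistributions and their shapes.

All first/second/third moments are intensity-weighted in population form
(denominator Σw, no Bessel correction): ω₀ = Σwᵢωᵢ/Σwᵢ,
σ = sqrt(Σwᵢ(ωᵢ−ω₀)²/Σwᵢ), and the asymmetry coefficient is the weighted
Fisher third standardized moment. 95% half-width uncertainties are
1.96·SE with SE = s/√N for ω₀ and replica-level dispersion for σ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ModeSeries",
    "VibrationalSummary",
    "FrequencyDistribution",
    "SubdistributionSet",
    "CoordinationSlice",
    "weighted_mean",
    "weighted_std",
    "asymmetry_coefficient",
    "uncertainty_95",
    "summarize",
    "build_distribution",
    "fit_gaussians",
    "decompose_by_coordination",
    "series_from_dataframe",
    "series_to_dataframe",
    "DEFAULT_BIN_WIDTHS",
]

#: Default histogram bin widths per mode, cm⁻¹.
DEFAULT_BIN_WIDTHS = {"bend": 2.0, "OD": 5.0, "OH": 5.0}


@dataclass(frozen=True)
class ModeSeries:
    """Per-snapshot time series of one vibrational mode across replicas."""

    label: str
    replica: np.ndarray
    time_ps: np.ndarray
    freq: np.ndarray
    intensity: np.ndarray
    n_first_shell: np.ndarray
    dt_fs: float
    converged: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "replica", np.asarray(self.replica, int))
        object.__setattr__(self, "time_ps", np.asarray(self.time_ps, float))
        object.__setattr__(self, "freq", np.asarray(self.freq, float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, float))
        object.__setattr__(self, "n_first_shell", np.asarray(self.n_first_shell, int))
        conv = self.converged
        conv = np.ones(len(self.freq), bool) if conv is None else np.asarray(conv, bool)
        object.__setattr__(self, "converged", conv)
        lens = {len(self.replica), len(self.time_ps), len(self.freq),
                len(self.intensity), len(self.n_first_shell), len(conv)}
        if len(lens) != 1:
            raise ValueError("all ModeSeries columns must share one length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.dt_fs <= 0:
            raise ValueError("dt_fs must be positive")

    def __len__(self) -> int:
        return len(self.freq)

    @property
    def replica_ids(self) -> np.ndarray:
        return np.unique(self.replica)

    def usable(self) -> "ModeSeries":
        """Drop non-converged snapshots."""
        if self.converged.all():
            return self
        m = self.converged
        return ModeSeries(self.label, self.replica[m], self.time_ps[m], self.freq[m],
                          self.intensity[m], self.n_first_shell[m], self.dt_fs,
                          self.converged[m])

    def replica_slices(self):
        """Yield (replica_id, time-ordered frequency array) per replica."""
        for r in self.replica_ids:
            m = self.replica == r
            order = np.argsort(self.time_ps[m], kind="stable")
            yield int(r), self.freq[m][order]


@dataclass(frozen=True)
class VibrationalSummary:
    """ω₀ and σ with 95% half-width uncertainties and the sample count."""

    label: str
    omega0: float
    omega0_err: float
    sigma: float
    sigma_err: float
    n: int

    def __post_init__(self):
        if self.sigma < 0 or self.omega0_err < 0:
            raise ValueError("σ and uncertainties must be non-negative")


@dataclass(frozen=True)
class GaussianComponent:
    amplitude: float
    mean: float
    width: float


@dataclass(frozen=True)
class FrequencyDistribution:
    """Intensity-weighted normalized frequency histogram."""

    centers: np.ndarray
    density: np.ndarray
    bin_width: float
    asymmetry: float
    components: tuple[GaussianComponent, ...] | None = None
    r2: float | None = None
    fit_flagged: bool = False

    def __post_init__(self):
        object.__setattr__(self, "centers", np.asarray(self.centers, float))
        object.__setattr__(self, "density", np.asarray(self.density, float))
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        total = self.density.sum() * self.bin_width
        if self.density.any() and not np.isclose(total, 1.0, rtol=1e-8):
            raise ValueError(f"density must integrate to 1 (got {total})")


@dataclass(frozen=True)
class CoordinationSlice:
    """Observables of the snapshots sharing one first-shell count."""

    count: int
    fraction: float  # intensity-weight share of the total
    omega0: float
    sigma: float
    asymmetry: float
    distribution: FrequencyDistribution
    n: int


@dataclass(frozen=True)
class SubdistributionSet:
    """Coordination-resolved decomposition of one mode's distribution."""

    label: str
    slices: dict[int, CoordinationSlice]
    total: FrequencyDistribution

    def fractions(self) -> dict[int, float]:
        return {c: s.fraction for c, s in self.slices.items()}


def _check_weights(values, weights):
    x = np.asarray(values, float)
    w = np.asarray(weights, float)
    if x.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(w > 0):
        raise ValueError("weights must not all be zero")
    return x, w


def weighted_mean(values, weights) -> float:
    """Intensity-weighted average Σwx/Σw."""
    x, w = _check_weights(values, weights)
    return float(np.sum(w * x) / np.sum(w))


def weighted_std(values, weights) -> float:
    """Intensity-weighted population standard deviation."""
    x, w = _check_weights(values, weights)
    mu = np.sum(w * x) / np.sum(w)
    return float(np.sqrt(np.sum(w * (x - mu) ** 2) / np.sum(w)))


def asymmetry_coefficient(values, weights) -> float:
    """Weighted Fisher skewness; negative values mean a low-frequency tail."""
    x, w = _check_weights(values, weights)
    mu = np.sum(w * x) / np.sum(w)
    var = np.sum(w * (x - mu) ** 2) / np.sum(w)
    if var <= 0:
        raise ValueError("asymmetry undefined for zero spread")
    m3 = np.sum(w * (x - mu) ** 3) / np.sum(w)
    return float(m3 / var**1.5)


def uncertainty_95(spread: float, n: int) -> float:
    """95% half-width, 1.96·spread/√n."""
    if n < 2:
        raise ValueError("need at least two samples")
    if spread < 0:
        raise ValueError("spread must be non-negative")
    return 1.96 * spread / np.sqrt(n)


def summarize(series: ModeSeries) -> VibrationalSummary:
    """Pool all replicas into ω₀ ± 1.96σ/√N and σ ± replica-level 95% CI.

    The σ uncertainty uses the dispersion of per-replica σ values (sample
    sd over replicas / √R); it is NaN when only one replica is present.
    """
    s = series.usable()
    if len(s) < 2:
        raise ValueError("need at least two converged samples")
    om = weighted_mean(s.freq, s.intensity)
    sg = weighted_std(s.freq, s.intensity)
    om_err = uncertainty_95(sg, len(s))
    reps = s.replica_ids
    if len(reps) >= 2:
        sig_r = []
        for r in reps:
            m = s.replica == r
            if m.sum() >= 2 and np.any(s.intensity[m] > 0):
                sig_r.append(weighted_std(s.freq[m], s.intensity[m]))
        sig_err = 1.96 * float(np.std(sig_r, ddof=1)) / np.sqrt(len(sig_r))
    else:
        sig_err = float("nan")
    return VibrationalSummary(s.label, om, om_err, sg, sig_err, len(s))


def _histogram(freq, weights, bin_width, edges=None):
    if edges is None:
        lo = np.floor(freq.min() / bin_width) * bin_width - 3 * bin_width
        hi = np.ceil(freq.max() / bin_width) * bin_width + 3 * bin_width
        nbin = max(int(round((hi - lo) / bin_width)), 1)
        edges = lo + bin_width * np.arange(nbin + 1)
    counts, _ = np.histogram(freq, bins=edges, weights=weights)
    density = counts / (weights.sum() * bin_width)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, density, edges


def build_distribution(
    series: ModeSeries,
    bin_width: float | None = None,
    edges: np.ndarray | None = None,
) -> FrequencyDistribution:
    """Intensity-weighted normalized histogram over a padded range.

    ``edges`` overrides the automatic range, letting callers bin several
    subsets of one series on a common grid.
    """
    s = series.usable()
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTHS.get(s.label, 5.0)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    centers, density, _ = _histogram(s.freq, s.intensity, bin_width, edges)
    sg = weighted_std(s.freq, s.intensity)
    ac = asymmetry_coefficient(s.freq, s.intensity) if sg > 0 else 0.0
    return FrequencyDistribution(centers, density, bin_width, ac)


def _gauss_sum(x, *p):
    y = np.zeros_like(x)
    for i in range(0, len(p), 3):
        a, mu, w = p[i : i + 3]
        y = y + a * np.exp(-((x - mu) ** 2) / (2 * w**2))
    return y


def fit_gaussians(dist: FrequencyDistribution, k: int = 1) -> FrequencyDistribution:
    """Least-squares fit of k ∈ {1,2,3} Gaussians to the binned density.

    Initialization is deterministic: means at evenly spaced quantiles of
    the density, common width from the histogram's second moment.
    Non-convergence, or R² < 0.9, flags the result instead of raising.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    x, y = dist.centers, dist.density
    mass = y / y.sum() if y.sum() > 0 else np.full_like(y, 1.0 / len(y))
    mu0 = float(np.sum(mass * x))
    w0 = float(np.sqrt(np.sum(mass * (x - mu0) ** 2))) or dist.bin_width

    cum = np.cumsum(mass)
    qs = [(2 * i + 1) / (2 * k) for i in range(k)]
    means = [float(np.interp(q, cum, x)) for q in qs]
    amp = y.max() / k if y.max() > 0 else 1.0
    p0 = []
    for m in means:
        p0 += [amp, m, w0 / np.sqrt(k)]

    lb = [0.0, x.min() - 10 * w0, dist.bin_width / 10] * k
    ub = [np.inf, x.max() + 10 * w0, np.inf] * k
    try:
        popt, _ = curve_fit(_gauss_sum, x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
        yfit = _gauss_sum(x, *popt)
        ss_res = float(np.sum((y - yfit) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        comps = tuple(
            GaussianComponent(float(popt[i]), float(popt[i + 1]), abs(float(popt[i + 2])))
            for i in range(0, 3 * k, 3)
        )
        flagged = r2 < 0.9
    except RuntimeError:
        comps, r2, flagged = None, None, True
    return replace(dist, components=comps, r2=r2, fit_flagged=flagged)


def decompose_by_coordination(
    series: ModeSeries,
    counts: set[int] | None = None,
    bin_width: float | None = None,
) -> SubdistributionSet:
    """Partition snapshots by first-shell count into subdistributions.

    All subsets are binned on the total distribution's grid, so that
    Σ_counts fraction·density reconstructs the total bin-by-bin when every
    observed count is requested. Fractions are intensity-weight shares.
    Requested counts with no snapshots are omitted with a warning.
    """
    s = series.usable()
    if counts is not None and not counts:
        raise ValueError("counts must be non-empty")
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTHS.get(s.label, 5.0)
    _, _, edges = _histogram(s.freq, s.intensity, bin_width)
    total = build_distribution(s, bin_width, edges=edges)
    wanted = sorted(counts) if counts is not None else sorted(np.unique(s.n_first_shell))

    w_total = s.intensity.sum()
    slices: dict[int, CoordinationSlice] = {}
    for c in wanted:
        m = s.n_first_shell == c
        if not m.any():
            warnings.warn(f"no snapshots with first-shell count {c}; omitted", stacklevel=2)
            continue
        sub = ModeSeries(s.label, s.replica[m], s.time_ps[m], s.freq[m],
                         s.intensity[m], s.n_first_shell[m], s.dt_fs)
        dist = build_distribution(sub, bin_width, edges=edges)
        sg = weighted_std(sub.freq, sub.intensity)
        slices[int(c)] = CoordinationSlice(
            count=int(c),
            fraction=float(sub.intensity.sum() / w_total),
            omega0=weighted_mean(sub.freq, sub.intensity),
            sigma=sg,
            asymmetry=asymmetry_coefficient(sub.freq, sub.intensity) if sg > 0 else 0.0,
            distribution=dist,
            n=int(m.sum()),
        )
    return SubdistributionSet(s.label, slices, total)


# ---------------------------------------------------------------------------
# freqs.csv interchange (one row per snapshot per mode)
# ---------------------------------------------------------------------------

FREQS_COLUMNS = ["replica", "time_ps", "mode", "freq_cm1", "intensity",
                 "n_first_shell", "converged"]


def series_from_dataframe(df: pd.DataFrame, dt_fs: float) -> dict[str, ModeSeries]:
    """Split a freqs table into one :class:`ModeSeries` per mode label."""
    out: dict[str, ModeSeries] = {}
    for label, grp in df.groupby("mode", sort=True):
        grp = grp.sort_values(["replica", "time_ps"], kind="stable")
        out[str(label)] = ModeSeries(
            str(label),
            grp["replica"].to_numpy(),
            grp["time_ps"].to_numpy(),
            grp["freq_cm1"].to_numpy(),
            grp["intensity"].to_numpy(),
            grp["n_first_shell"].to_numpy(),
            dt_fs,
            grp["converged"].to_numpy(bool) if "converged" in grp else None,
        )
    return out


def series_to_dataframe(series_by_mode: dict[str, ModeSeries]) -> pd.DataFrame:
    """Concatenate mode series back into the freqs.csv schema."""
    rows = []
    for label, s in series_by_mode.items():
        rows.append(pd.DataFrame({
            "replica": s.replica, "time_ps": s.time_ps, "mode": label,
            "freq_cm1": s.freq, "intensity": s.intensity,
            "n_first_shell": s.n_first_shell, "converged": s.converged,
        }))
    return pd.concat(rows, ignore_index=True)[FREQS_COLUMNS]
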