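# Methods

This note documents the models, conventions and defaults behind `mdifm`,
the choices made where the design was genuinely open, and what the
synthetic generators do and do not establish.

## Cluster extraction

Water perception assigns every hydrogen to its nearest oxygen under the
minimum-image convention (orthorhombic boxes only); an O–H bond is accepted
below 1.25 Å. Frames containing other elements, stray hydrogens, or
oxygens without exactly two hydrogens are rejected with the offending atom
index — silent repair would hide corrupt inputs.

Shell structure is defined on the O–O radial distribution function, the
standard convention for water structure (an O–H definition would shift the
cutoffs but not the method). The RDF is a pair histogram normalized by
ideal-gas shell counts at each frame's own density; extrema are located on
a centered moving average (default window 5 bins, dr = 0.05 Å). The first
RDF minimum defines the coordination cutoff, the third minimum the cluster
radius.

Clusters are carved around a fixed probe water in two modes:

- **nearest_n** (default): exactly the n nearest environment waters by
  O–O distance, n = 29, giving reproducible fixed-size engine inputs of
  30 molecules / 90 atoms. A fixed radius yields frame-to-frame variable
  counts, which complicates engine-cost budgeting; the fixed-N deck is the
  default for that reason.
- **radius**: every water with O–O distance strictly below the
  third-minimum radius (the literal "first three solvation shells"
  criterion).

Membership comparisons are strict (`<`) at every cutoff. All molecules are
made whole and imaged next to the probe oxygen before export, so a cluster
is contiguous in space and no water is split across the periodic boundary.
The coordination number always counts waters strictly inside the
first-minimum radius (default 3.4 Å), a distance-only criterion —
hydrogen-bond angle tests are deliberately out of scope.

## Frequency engine contract

One engine input per snapshot: probe atoms first (O, H, H), every
environment atom frozen, one probe hydrogen mass-overridden to 2.014 amu
(HDO). The adapter must perform a constrained optimization of the free
atoms followed by harmonic frequencies of the free atoms; only
frequency/intensity pairs cross the boundary, so whether the engine builds
a partial or full Hessian is its own concern. Non-converged snapshots are
flagged, counted and excluded from every observable rather than raised.

Mode assignment uses half-open frequency windows — bend [1100, 1800), OD
[1800, 2900), OH [2900, 4200) cm⁻¹ — chosen to bracket the liquid-phase
HDO fundamentals with wide margins. Frequencies below all windows are the
pseudo-translations/rotations of the constrained probe and are discarded.
If a window holds several candidates the most intense wins and the record
is flagged; an empty window is an error naming the snapshot. A
displacement-projection assignment would be more rigorous but requires
normal-mode vectors, which the engine contract deliberately does not
transport.

## The mock frequency map

Tests and synthetic end-to-end runs use a deterministic map in place of an
external engine:

ω_mode = base_mode − slope_mode · n₁ − c_mode · Σ_j exp(−r_j / λ)

with n₁ the cluster's stored first-shell count, the sum over all
environment oxygens at distances r_j from the probe oxygen, and intensities
affine in n₁. Defaults: base = (1355, 2600, 3530) cm⁻¹, slope = (1, 20,
25) cm⁻¹ per neighbor, c = (600, 8000, 9600) cm⁻¹ and λ = 0.5 Å for
(bend, OD, OH).

The map encodes the two robust qualitative facts about water
solvatochromism: stretches redshift with hydrogen-bond count (tens of cm⁻¹
per neighbor; the bend barely responds), and the response to a single
neighbor is *convex* in distance — a strengthening hydrogen bond redshifts
disproportionately. The short decay length makes the nearest-neighbor term
dominant (≈30 cm⁻¹ at 2.8 Å, tripling by 2.6 Å), which is what produces
the observed negative skew (low-frequency tail) of stretch subdistributions
at low coordination: in sparse shells, occasional close approaches drag
frequencies far down. With these defaults the population asymmetry
coefficient of the count-3 stretch subdistribution on random boxes is
≈ −0.2, weakening toward higher coordination.

A mock run is therefore a test of the *pipeline* — carving, deck building,
assignment, bookkeeping, statistics — and of qualitative solvatochromic
trends. It establishes nothing about any real force field's numbers.

## Observables

All moments are intensity-weighted in population form (denominator Σw, no
Bessel correction): ω₀ = Σwᵢωᵢ/Σwᵢ, σ² = Σwᵢ(ωᵢ−ω₀)²/Σwᵢ, and the
asymmetry coefficient is the weighted Fisher third standardized moment
m₃/σ³ (negative = low-frequency tail). Quantile or Pearson skewness would
be alternatives; the moment definition is used because it composes exactly
with the weighted mean/variance already reported.

Uncertainties are 95% half-widths, 1.96·SE. For ω₀, SE = σ/√N over all
pooled snapshots. For σ, SE is taken from the replica-to-replica dispersion
of per-replica σ values divided by √R: with strongly autocorrelated
snapshots the naive s/√N badly understates the error, while independent
replicas give an honest spread. With a single replica the σ uncertainty is
reported as NaN rather than a false number.

Histograms are intensity-weighted and normalized to unit integral, over a
range padded by three bins; default bin widths 2 cm⁻¹ (bend) and 5 cm⁻¹
(stretches). Coordination-resolved subdistributions are binned on the
total distribution's grid, so fraction-weighted subdensities reconstruct
the total bin-by-bin; population fractions are intensity-weight shares.
Gaussian component fits (k ≤ 3) initialize deterministically from density
quantiles and the histogram's second moment, and are flagged (never
silently accepted) on non-convergence or R² < 0.9.

## FFCF and spectral diffusion

δω is each replica's frequency minus that replica's *unweighted* mean
(intensity weighting enters the distribution observables, not the
correlation function). C(k·Δt) averages δω(t₀)δω(t₀+kΔt) over all valid
origins with the unbiased per-lag pair count, then replicas are averaged
pointwise with equal weight and fitted once — fit-of-average rather than
average-of-fits, because a biexponential on a single 1,000-point replica is
ill-conditioned. C(0) then equals the pooled δω variance exactly.

The fit A₁e^(−t/τ₁) + A₂e^(−t/τ_c) + y₀ excludes lag 0 by default (the
motionally narrowed ultrafast component contaminates it; toggleable),
bounds amplitudes and times positive, and multi-starts from the (τ₁, τ_c)
grid {0.05, 0.1, 0.5} × {0.5, 1, 2} ps with amplitudes split evenly from
the first fitted point; the lowest-residual converged start wins, with an
analytic Jacobian for speed. Time constants are relabeled so τ_c ≥ τ₁;
τ_c is reported with 1.96× its covariance-based standard error. A fit is
flagged "effectively monoexponential" when one amplitude drops below 2% of
the first fitted correlation value. No Kubo constraint ties amplitudes to
σ² — the ratio is a useful diagnostic, not an imposed identity. The FFCF
is fitted unnormalized (the fit carries its own offset y₀).

## Synthetic generators

- **Ornstein–Uhlenbeck**: exact discretization
  δω_{k+1} = δω_k·e^(−Δt/τ) + σ√(1−e^(−2Δt/τ))·ξ_k with a stationary
  start, so σ²e^(−t/τ) holds at any step size and no burn-in is needed.
- **Two-timescale Kubo process**: the sum of two independent OU components,
  C(t) = σ₁²e^(−t/τ₁) + σ₂²e^(−t/τ₂). Defaults (σ₁ = 60 cm⁻¹, τ₁ = 0.1 ps,
  σ₂ = 40 cm⁻¹, τ₂ = 1.0 ps; 50 fs step, 12 replicas × 1,000 points) sit in
  the physical regimes of water spectral diffusion: hydrogen bonds break
  and reform on 50–400 fs, the network reorganizes on 0.7–1.2 ps. Each
  (replica, component) has its own child RNG stream, so zeroing one
  amplitude reproduces the other component's path bitwise.
- **Random water boxes**: random sequential insertion of rigid waters
  (O–H 0.9572 Å, H–O–H 104.52°, random orientation) with a 2.6 Å O–O
  exclusion; defaults (200 waters, 18.2 Å box) match bulk number density
  0.0334 Å⁻³. That density sits near the random-insertion jamming limit,
  so insertion runs through a compiled scan of batched candidates with a
  large retry budget. Deterministic given the seed.
- **Brownian box evolution**: rigid-body Gaussian translations
  (0.12 Å/step) and small rotations per molecule, rejecting moves that
  violate the exclusion distance. This provides *time-correlated* solvation
  environments so FFCF code paths can run end-to-end on synthetic data. It
  is not molecular dynamics: the time scale is set by the step size, not by
  physics, so synthetic τ_c values have no physical meaning.

What a green synthetic test establishes: correct statistics, correct
bookkeeping, correct parameter recovery where ground truth is known, and
the designed-in solvatochromic trends. What it does not establish: real
hydrogen-bond structure (the boxes are exclusion-constrained ideal gases,
not liquid water), real dynamics, or any force field's actual ω₀/σ/τ_c —
those require MD trajectories plus thousands of external frequency
calculations per force field.

## Pipeline conventions

Synthetic datasets choose between `brownian` (time-correlated, FFCF-capable)
and `iid` dynamics (a fresh box per snapshot — ensemble properties only,
maximal statistical efficiency for distribution shapes). Synthetic runs use
fixed shell cutoffs (3.4 / 7.8 Å) because random-insertion boxes have no
RDF shell structure for the extremum finder to locate — it would correctly
raise; RDF-derived cutoffs are available for real trajectories
(`cutoffs = "rdf"`). Every output CSV carries a provenance header (package
version, config hash excluding the output directory, master seed); reruns
of an identical config on synthetic/mock inputs are byte-identical. If the
FFCF fit fails for some mode (e.g. white-noise iid data), the τ_c cell is
NaN, a warning is emitted, and the benchmark stage drops that metric
rather than aborting.

Percent differences are 100·(value − reference)/reference (positive ⇒ the
reference is lower), reported to one decimal; uncertainty propagation is
first-order with the two measurements treated as independent (they come
from separate simulations), and a difference is flagged significant when
the propagated 95% interval excludes zero — the numerical counterpart of
"error bars crossing the axis".

## Known limitations

- Orthorhombic boxes and pure-water frames only; no triclinic cells, ions
  or cosolutes.
- Mode assignment by frequency windows can mislabel pathological spectra
  where a stretch wanders out of its window; such snapshots surface as
  assignment errors rather than wrong labels.
- The σ uncertainty needs ≥ 2 replicas; the replica-dispersion estimator is
  itself noisy for few replicas.
- Biexponential fits on short series (< 8 usable lags) are refused; on
  nearly monoexponential data the (A₁, τ₁) component is weakly identified
  (flagged, and τ_c remains the meaningful number).
- The external-engine adapter shells out per snapshot; batching and
  parallel dispatch are left to the caller (snapshots are independent).
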