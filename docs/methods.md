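# Methods

`oligoflux` implements the quantitative analysis chain of an antibody-scanning
study of α-synuclein aggregation: kinetic curve fitting of thioflavin-T (ThT)
traces, the analytical oligomer-flux framework, saturation-binding analysis,
single-molecule pull-down (SiMPull) spot counting, and super-resolved
aggregate morphometrics, together with synthetic-data generators that emulate
each raw-data source. This note records the models, the parameter choices and
their rationale, the numerical decisions, and the known limitations.

## Kinetic model

Aggregation is treated in the linear polymerisation picture

    dM/dt = 2 k₊ P(t) m(t),

with M the fibril mass fraction (normalized to plateau = 1), m = 1 − M the
monomer fraction, P the fibril number concentration and k₊ the elongation
rate constant. Two experimental regimes select different reductions:

**High seed (~15% preformed fibrils).** Nucleation is negligible, P ≈ P(0),
and the early reaction is linear with slope 2·k₊·P(0)·m(0). `fit_elongation`
takes the ordinary least-squares slope of the first `n_points` samples
(default 6; the assay samples once per minute). Because P(0) and m(0) are
common to all conditions of a plate, only slopes *relative to the
antibody-free control* are interpreted (`relative_elongation`).

**Low seed (~0.06%), mildly acidic.** Secondary nucleation dominates and the
normalized mass is described by a generalized logistic (Richards) curve

    M(t) = 1 − [1 + (c/a)·e^{κt}]^{−1/c},

with amplitude parameter a (M(0) ≈ 1/a), effective growth rate κ (a
combination of elongation and secondary-nucleation rate constants,
κ² ∝ 2 k₊ k₂ m_tot^{n₂+1}) and shape parameter c, held fixed at 0.3
(corresponding to a secondary-nucleation reaction order n₂ = 4; the c↔n₂
mapping is carried as documentation metadata, not computed). The early-time
limit M ≈ e^{κt}/a matches the secondary-nucleation solution
(λ²/2κ²)·e^{κt}, which defines the primary-nucleation combination
λ = κ·√(2/a) reported as `lambda_`.

Fitting uses bounded trust-region nonlinear least squares (a ∈ (0, 10⁶],
κ ∈ (0, 10] min⁻¹), with κ initialized from the maximum coarse-grained
finite-difference slope divided by 0.25 (the analytic maximum of dM/dt is
≈ 0.3κ for c = 0.3) and a initialized from 1/M(0). Replicates are fitted
jointly by pooling residuals; per-replicate fits remain available for spread
estimates. Optimizer failure, or an estimated half-time beyond the observed
time window (a sigmoid not identifiable from the data, e.g. a trace stuck
below 20% of plateau), is reported as a `converged = False` result carrying a
diagnostic message — not an exception.

Derived quantities: the half-time t_½ solves M(t) = 0.5 by bracketed
root-finding (closed form ln[(a/c)(2^c − 1)]/κ serves as the oracle in
tests); the fibril number is P = M′/(r₊ m) with r₊ = 2 k₊ m_tot, and its
derivative dP/dt evaluated at t_½ is the effective fibril amplification rate,
reported relative to the control mean.

## Oligomer flux

Every new fibril arises from an oligomer generated on fibril surfaces
(secondary nucleation — the source) and consumed by elongation into mature
fibrils (the sink), so the net flux toward oligomers is φ(t) = dP/dt.
Substituting the fitted logistic gives, with u = (c/a)·e^{κt}:

    φ(t)    = κ² u / (r₊ c (1+u)²)         (bell-shaped profile)
    φ_Area  = κ a / (r₊ c (a+c))           (= P(∞) − P(0))
    φ_Time  = ln(a/c)/κ                    (u = 1 at the peak)
    φ_Peak  = κ² / (4 r₊ c)

φ_Peak, φ_Area and φ_Time summarize the maximal oligomer-generation rate, the
total oligomers formed, and when generation is fastest. Each is normalized to
the control-replicate mean (ratios; the control means are exactly 1 by
construction). An inhibitor of secondary nucleation (κ below control, all
else equal) lowers φ_Peak and φ_Area and delays φ_Time — this monotone
ordering is asserted over parameter sweeps in the tests.

Numerical choices: profiles are evaluated on t ∈ [0, 5·t_½] at a pitch of
t_½/1000, which captures >99.9% of the flux area in the normalized regime
(M(0) ≤ 5%, i.e. a ≥ 20); the peak is root-solved from dφ/dt = 0 on the
bracket [t_½/100, 5·t_½] (a `NoPeakError` when there is no interior maximum,
e.g. a ≤ c); all exponentials are evaluated in log space so late-time
underflow cannot corrupt the closed forms. Every closed form is guarded by an
independent numerical oracle (finite-difference differentiation of M,
trapezoidal quadrature, grid argmax/max) in the test suite, so a
transcription error in the algebra would be caught. The randomized-draw
domain used for those oracle sweeps (a ∈ [20, 1000] log-uniform,
κ ∈ [0.002, 0.05] min⁻¹) is the regime of normalized low-seed traces —
curves starting within 5% of baseline with half-times of ~1–60 hours.

## Binding analysis

MST titrations follow the one-site saturation equation
Y = B_Max·x/(K_D + x). The default pipeline mirrors the conventional
preprocessing: the lowest signal is shifted to zero (`zero_floor`, an
idempotent operation) and the two-parameter equation is fitted; a
three-parameter variant with a free additive offset exists for robustness
checks. The two routes agree on K_D (to ~2% at 1% response noise) provided
the titration's bottom concentration lies far below K_D, so that flooring
removes offset rather than signal — the synthetic design uses a 16-point
1:1.75 serial dilution from top = 20–100 × K_D. R² is 1 − RSS/TSS on the
fitted points; non-convergence is a flagged value, not an exception. The fit
is invariant under concentration-unit rescaling (p0 is built from the
geometric mean of x).

BLI sensorgrams are corrected by interpolating the reference sensor onto the
sample's time grid, subtracting, and then removing the mean of the corrected
trace over its own baseline window (by default the samples labelled
`baseline`), so the association phase starts near zero. Kinetic (k_on/k_off)
fitting is out of scope.

## SiMPull spot counting

Stacks (default 50 frames, 50 ms exposure) contain immobilized spots, so
pixel-wise frame averaging raises SNR by √n_frames. Detection on the averaged
image: robust background = image median, robust s.d. = 1.4826 × MAD; local
maxima above median + k·(robust s.d.) (default k = 5) are spots, with maxima
closer than `min_separation_px` (default 3) merged to the brighter one;
plateau ties resolve to the smallest (row, col), so detection is
deterministic and translation-equivariant. At k = 5 a blank 512×512 field
yields ≤ 2 (typically 0) false positives. Coordinates are 0-based (row, col)
pixel indices; physical positions are (index + 0.5)·pixel_nm with
pixel_nm = 105.4 by default. Per-condition spots-per-field-of-view summaries
report mean, s.d., n and fold differences against a reference condition.

The synthetic TIRF generator places spots uniformly with a 5 px minimum
mutual separation — single-molecule pull-down fields are sparse by design,
with resolvable spots — and renders a Gaussian PSF (σ = 1.4 px) on a constant
camera offset plus i.i.d. Gaussian read noise.

## Super-resolved morphometrics

Localization tables (Thunderstorm-style, nm units) are segmented into
aggregates by single-linkage clustering: points closer than `link_radius_nm`
(default 50) are linked and connected components smaller than `min_size`
(default 20) are discarded. Each aggregate is summarized by:

* **length** — the 1st–99th percentile extent of the projection onto the
  principal axis. A raw maximum-Feret diameter is inflated by localization
  error (≈ 2σ·√(2 ln n); ~35% for a 200 nm rod sampled with 20 nm precision
  at n = 500), while the trimmed extent recovers noiseless rods to within
  ~4% and 20 nm-blurred rods to within ~20%.
* **area and circularity** — convex-hull area and perimeter;
  circularity = 4π·area/perimeter² (clipped to ≤ 1).
* **eccentricity** — from the second-moment (covariance) ellipse, with the
  sampling variance of the moment anisotropy subtracted before taking the
  eigen-gap. The raw anisotropy of a finite point sample is χ²-distributed
  around zero even for perfectly round shapes, putting a noise floor of
  ≈ (5.3/n)^¼ (~0.3 at n = 500) on the naive eccentricity; the
  bias-corrected estimator reports a median of 0 for isotropic clouds while
  leaving elongated clusters essentially unchanged.

All three are exactly rotation-invariant (the estimators are built from
rotation-equivariant quantities), and eccentricity estimates for
near-isotropic aggregates remain heavy-tailed, so round-trip validation uses
medians over independent aggregates. Perfectly collinear clusters are flagged
`degenerate` with area 0 and undefined (NaN) circularity. A rendered-mask
fallback (`method="raster"`, default pitch 10 nm) rasterizes localizations
and measures `skimage` region properties instead; it is pixelation-limited
and therefore only approximately rotation-invariant.

The localization generator samples rods as uniform points along a segment and
discs as uniform points over the disc, each jittered by isotropic Gaussian
localization error (default 20 nm), with random orientation per seed.

## Statistics and reporting

Group comparisons follow the study's convention: an omnibus one-way ANOVA,
then per-condition two-sided Welch t-tests against the antibody-free control
without multiplicity correction (flagged in the result metadata); a
Dunnett-style many-to-one option is available. Null calibration (uniform
omnibus p-values under H₀) is verified by simulation in the tests. Star
labels use the four-tier map * p<0.1, ** p<0.01, *** p<0.001, **** p<0.0001
by default (a three-tier variant without the p<0.1 level is selectable);
boundary values fall to the weaker category and labelling is monotone in p.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume:
sigmoidal replicate traces with i.i.d. Gaussian plate-reader noise (default
s.d. 0.02 normalized units — a calibration choice, as real plate-reader noise
magnitudes vary), geometric dilution series with Gaussian response noise,
immobile Gaussian-PSF spots over Gaussian read noise, and uniform-support
localization clouds with Gaussian localization error. They do **not** emulate
correlated drift or evaporation in plate readers, MST thermophoresis physics,
EMCCD gain/photon statistics, fluorophore blinking or photobleaching
kinetics, localization-density inhomogeneity, or structured biological
backgrounds. Passing round trips therefore demonstrate correctness of the
estimators under the stated noise models, not robustness to every instrument
artifact.

All generators take one explicit integer seed; replicate r (or sub-draw i)
uses the sub-stream seed + r, so outputs are byte-identical for equal seeds.

## Problem sizes in the validation suite

The validation protocols (`oligoflux.validation`, used by both
`tests/test_acceptance.py` and `scripts/acceptance.py`) use: 100 random
parameter draws for the closed-form-vs-oracle sweeps; 50 simulated
experiments (3 replicates each) for kinetic and binding recovery; 3 planted
512×512 fields (100 spots each) plus 50 blank fields for detection fidelity;
31 independent aggregates per shape class (discs at 2000 localizations, the
dense-labelling regime of long dSTORM acquisitions) with medians reported;
and 200 null simulations for the ANOVA calibration. With 6 points × 3
replicates per experiment, the median elongation slope over 50 experiments
retains a ~6% relative sampling s.d. — the least-determined quantity in the
suite, which is why its recovery is quoted as a median.

## Known limitations

* Absolute rate constants (k₊, k₂, k_n) are not resolved — only effective and
  control-relative rates, as the normalized-data framework permits.
* c is fixed, not selected; no multi-mechanism model competition is
  performed.
* Weak or partial titrations can return converged fits with poor R²;
  interpretation is left to the caller (R² is always reported).
* dSTORM reconstruction (drift correction, rendering) is consumed, not
  performed; localization tables must already carry nm units.
* Eccentricity near zero is intrinsically hard to estimate from finite
  localization samples (noise ∝ n^(−1/4)); single-aggregate eccentricities
  below ~0.3 should not be over-interpreted at a few hundred localizations.
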