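# Methods

`gqion` analyzes the quantitative readouts used to characterize artificial
ionophores built from a DNA G-quadruplex and a lipophilic guanosine ligand:
vesicle flux kinetics, a ligand-binding panel, single-channel
electrophysiology, and a reduced Brownian-dynamics (BD) model of
electro-diffusive permeation. This note records the models, their
assumptions, the defaults, and the choices made where the design was open.

## Flux kinetics (`fluxkin`)

The HPTS assay reports intravesicular pH as a fluorescence signal. After a
base pulse at `t_base` imposes a one-unit transmembrane pH gradient, H+/M+
exchange through the ionophore relaxes the internal pH toward a plateau:

    y(t) = plateau · (1 − exp(−k_obs (t − t_base))),  t_base ≤ t ≤ t_lysis.

Detergent lysis at `t_lysis` defines the 100% level used for normalization:
`(I_t − I₀)/(I_∞ − I₀)` with I₀ the pre-base mean and I_∞ the post-lysis
mean (≥3 samples each). Values are not clipped, so noise may leave them
slightly outside [0, 1].

Fitting choices:

* `fit_first_order` uses damped nonlinear least squares over the
  `[t_base, t_lysis]` window by default (overridable). The window between
  the two protocol events is the natural choice when no other is stated.
  The rate start value comes from a log-linear regression of `1 − y/plateau₀`
  and the plateau start from the last pre-lysis value; robust starts are the
  dominant failure mode for exponential fits. The plateau is fitted, not
  pinned at 1 — incomplete gradient collapse is common at low transporter
  loadings.
* Fractional activity Y at a fixed readout time (default 300 s) is
  normalized between the blank (0 μM) trace and the maximal response;
  without a blank, raw readouts are returned with a `no-blank` flag.
* `fit_hill` bounds EC50 to (0, 10·max c] and n to (0, 10]: an unbounded
  Hill exponent is unidentifiable on sparse 7-point dose designs. Data that
  never reach half-maximal activity are fit anyway and flagged
  `no-saturation` (the behaviour of poorly transported cations).
* Replicates aggregate as mean ± SD.

## Binding panel (`bindfit`)

* **Melting.** Thermal melts are treated as generic normalized two-state
  transitions and fit with a four-parameter Boltzmann sigmoid
  `low + (high − low)/(1 + exp((Tm − T)/w))`. The fitted midpoint is
  cross-checked against the maximum of a smoothed (Savitzky–Golay) first
  derivative; disagreement beyond w/2 flags the fit. Donor/acceptor
  photophysics of the underlying FRET measurement are out of scope; only the
  melt fraction is modelled. ΔTm is a plain difference of fitted midpoints
  and is therefore exactly additive over chains of fits.
* **Titration.** The fluorimetric Kd uses the exact 1:1 quadratic
  (depletion-aware) bound-fraction solution scaled by a fitted amplitude.
  Because the model is linear in the amplitude, the optimizer is started
  from a coarse log-spaced Kd scan with the amplitude profiled analytically.
  Where the ligand binds its receptor at m:1 stoichiometry, the 1:1 model is
  applied **per site** (site concentration = m × receptor); the single
  published Kd is interpreted as a per-site constant. At partial-saturation
  designs the Kd likelihood is flat upward — the fit carries a
  `saturation-not-approached` flag when max titrant < Kd, and recovery
  precision should be judged from the replicate spread, not one fit.
* **Continuous variation (Job).** The generator solves the full single-step
  m:1 equilibrium `mL + Q ⇌ LmQ` by bracketed root finding per mole
  fraction; the analyzer deliberately uses only the peak position
  (quadratic interpolation through the top three points, m = round of
  x*/(1−x*)), with the un-rounded ratio reported so non-integer evidence is
  preserved. Peak location, not equilibrium refitting, is the standard
  treatment; the forward model is the harder of the two and lives in the
  generator. For strong binding the peak is triangular rather than
  parabolic, which biases the interpolated vertex by a few percent — small
  against the gaps between integer stoichiometries at noise ≤3% of range,
  but exact recovery degrades to ~90% by 5% noise.
* **ITC.** Heats are per mole of injectant (instrument convention) from the
  single-set-of-identical-sites (Wiseman) isotherm with the standard
  displacement bookkeeping: each injection of volume v dilutes the cell
  contents by (1 − v/V₀) and adds titrant at syringe concentration. The fit
  has four parameters (n sites, Kd, ΔH, constant dilution offset). A
  Wiseman c-value (n·[cell]/Kd) above 1000 means the titration ran
  stoichiometrically and Kd is flagged unidentifiable. At c ≈ 10 with 2%
  noise the intrinsic Kd precision of a 20-injection design is ~15%
  (1 SD, single fit); the recovery suite therefore uses a 50-injection
  design at c ≈ 20 where the median error is below 5%.

## Electrophysiology (`patchan`)

* All-points histograms default to 0.2 pA bins (configurable; no standard
  rule exists).
* Gating idealization is the simple half-amplitude threshold: the closed
  level is the histogram mode nearest 0 pA, open levels the remaining
  modes, and states switch where the current crosses the midpoint to the
  nearest open level. Dwells shorter than 2 samples are excluded from dwell
  statistics. A unimodal histogram returns a `no-gating` result with
  p_open 0 (level near zero) or 1 (level clearly away from zero).
  Multi-level Markov/HMM idealization is out of scope.
* Conductance is the OLS slope of the I–V relation (pA/mV = nS); an
  intercept exceeding its SE flags the relation non-ohmic.
* Reversal potentials: the default estimator interpolates the zero crossing
  linearly between the bracketing pair, falling back to the OLS-line root
  when no bracket exists (accepted only within 1.5× the sampled range,
  flagged extrapolated). For globally linear (ohmic) tail-current families
  `method="line"` uses the OLS root directly — with 16 points at 2% noise
  its SD is ~0.9 mV versus ~2.9 mV for the bracketing pair, and the two
  coincide exactly on noise-free linear data. Replicated experiments are
  summarized by the mean of per-experiment reversals.
* The bi-ionic GHK relation `E_rev = (RT/F) ln(P_cis[cis]/(P_trans[trans]))`
  uses T = 298.15 K by default (RT/F = 25.693 mV); the potential is that of
  the cis side relative to the grounded trans side, and every result record
  states this convention. Note that a measured +11 mV reversal corresponds
  to a permeability ratio of exp(11/25.69) ≈ 1.5 at 298 K under this
  relation; published ratio/reversal pairs computed with other temperature
  or activity conventions will differ, so the module always reports the
  relation it used.

## Brownian-dynamics permeation (`permbd`)

The applied-field permeation problem is reduced to one dimension along the
membrane normal z: each ion diffuses in a periodic box of length L_z under
a species-specific potential of mean force W(z) plus the uniform force of a
transmembrane voltage, with the overdamped Euler–Maruyama step

    z ← z + (D/kT)·F(z)·dt + sqrt(2 D dt)·ξ,   F(z) = −dW/dz + q V/L_z.

Assumptions and consequences:

* **Independent ions.** No ion–ion or ion–DNA explicit interactions;
  concentration enters only through the ion count N. Currents scale
  linearly in N and saturation/blocking effects are absent. This keeps all
  estimators exact against closed forms (flat-PMF conductance
  g = N q² D/(kT L_z²)) and is the main limitation relative to atomistic
  simulation — the surrogate is not expected to reproduce any absolute
  conductance, only mechanistic structure (ohmic linearity, bias
  antisymmetry, selectivity by barrier height).
* **Units.** nm, ns, elementary charge, mV; energies in e·mV with
  kT = 25.693 e·mV at 298.15 K; current conversion 1 e/ns = 160.218 pA.
  All constants stay order-1 and conversions are exact.
* **Force field.** W(z) lives on a uniform grid spanning [0, L_z] with
  W(0) = W(L_z) (periodicity is validated); forces are centered finite
  differences at the nodes, linearly interpolated between them. The
  integrator refuses a time step whose maximum drift exceeds one grid
  spacing.
* **Total-intensity current.** I(t+Δt/2) = (1/(Δt L_z)) Σᵢ qᵢ Δzᵢ with
  displacements from unwrapped coordinates (identical to nearest-image
  differences; both coordinate sets are stored for cross-checks). The
  estimator telescopes, so frame thinning changes no mean. Per-species
  currents sum to the total exactly and cumulative charge is the exact
  discrete time integral.
* **Stationarity.** The first 25% of frames are discarded before averaging
  (configurable), and means carry block-averaged SEs (default 10 blocks).
* **Boltzmann inversion.** W_est(z) = −kT ln(ρ(z)/ρ_bulk) with the bulk
  reference taken from the outer 10% of the box at each end, anchored so
  the bulk minimum is zero; empty bins are masked and reported. With
  20 ions × 4 μs of equilibrium sampling a 2 kT barrier is recovered to
  RMSE < 0.2 kT (typically ~0.05 kT).
* **Defaults.** L_z = 10 nm, D_K ≈ 1.96 and D_Cl ≈ 2.03 nm²/ns (bulk
  water values), dt = 0.02 ns for barriers up to ~2 kT on a 0.1 nm grid
  (smaller for steeper profiles), 10–30 ions per species. Box length and
  counts are stated reference conditions of this reduced model, not claims
  about any atomistic system.

## Synthetic data (`synthgen`)

Generators produce exactly the statistical structure the analyzers assume:
single-exponential flux traces with base-pulse/lysis events (protocol
defaults: base pulse at 50 s, lysis at 350 s, 1 s sampling), Hill
dose-responses, Boltzmann melts, depletion-aware titrations, full m:1
equilibrium Job series, Wiseman thermograms, two-state Markov gating
traces, and ohmic tail-current families. Noise is additive Gaussian with
sigma given as a fraction of the signal's dynamic range — the simplest
model sufficient for recovery testing; real assays add photobleaching,
drift, dye pKa nonlinearity, vesicle polydispersity, filter ringing and
capacitance transients, none of which are emulated. Passing recovery tests
therefore demonstrates estimator correctness and precision at stated noise,
not robustness to structured artifacts.

All randomness flows from one integer seed through a counter-based
per-replicate scheme (`default_rng([seed, replicate])`), so replicate k is
bit-reproducible regardless of generation order. Flux traces are generated
pre-normalized to the lysis level (matching how such data are reported); a
raw mode (`baseline`, `scale`) exercises the normalization path. The raw
fluorescence-to-pH transform of the underlying dye is not modelled — the
generator emits the normalized signal directly.

## Verification strategy

Every fitter is checked three ways: exact recovery on noise-free
self-generated data; agreement with an independent brute-force oracle
(grid/profile scans for the exponential, Hill and titration fits; a dense
root scan for the m:1 equilibrium; finite differences of an independently
root-solved equilibrium for ITC heats); and seeded-replicate recovery
suites with bias tests. The BD engine is checked against closed forms
(Einstein MSD, drift velocity, flat-PMF conductance), exact conservation
identities, and equilibrium round trips (density → Boltzmann inversion →
input PMF). Study-condition tests generate fixtures at the characterized
system's fitted values with its stated replication (n = 3 fluorescence and
binding panels, n = 4 tail-current families) and assert recovery at the
corresponding tolerances. Reported problem sizes (trace lengths, replicate
counts, BD step counts) are the package's reference conditions chosen for
tight statistics at interactive runtimes.
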