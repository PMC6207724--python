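# Methods

This note describes the models implemented in `shp2kin`, the assumptions
behind them, the numerical choices made where the design was open, and the
known limits of what the synthetic-data tests demonstrate.

## The system

SHP2 is a tandem-SH2 protein tyrosine phosphatase that auto-inhibits by
docking its N-SH2 domain into the catalytic (PTP) cleft.  The protein
exchanges between this **closed, inactive** conformation and an **open,
active** one; activating disease mutations (E76D, E76K) shift the
equilibrium toward open, and the allosteric inhibitor SHP099 binds only the
closed conformer.  The package quantifies this landscape along four
connected axes: NMR-derived populations, drug-binding kinetics,
steady-state enzymology, and a coupled model predicting activity and
inhibitor potency.

## Populations from chemical shifts (`nmr_populations`)

For residues in fast exchange, the observed amide cross peak is the
population-weighted average of the pure-state positions.  With the PTP
domain as the fully open reference and the drug-bound complex as the fully
closed reference, each residue is projected onto the open-to-closed axis in
the weighted plane (d1H, 0.15 * d15N):

    A = d(query) - d(open),   B = d(closed) - d(open),
    F = |A| cos(theta) / |B|         (fraction closed)

**Sign convention.**  The literature form of these equations measures both
vectors from the *closed* reference, which makes F equal to minus the open
fraction and puts collinear peaks at theta ~ 180 deg — inconsistent with
the retention window 0 <= F <= 1 used alongside it.  We therefore measure A
from the open reference by default (F = fraction closed, collinear peaks at
theta ~ 0) and expose `convention="literature"` for the literal form; both
yield identical retained sets and estimates.

**Filters** (checked in fixed order, one recorded reason per residue):
a-priori exclusion list (residues within 15 A of the drug pocket, supplied
by the user — computing it from coordinates is deliberately out of the
numeric core), axis length |B| >= 0.03 ppm, collinearity within +/-10 deg,
and 0 <= F <= 1.  Thresholds are arguments with these defaults.

**Estimator.**  Retained residues share one global F with residual
|B|F - |A|cos(theta) ~ N(0, sigma) in ppm.  The likelihood maximiser is
closed-form (a weighted regression through the origin); variances come from
the observed information at the optimum, whose cross-term vanishes exactly
there (asserted numerically), giving var(F) = sigma^2 / sum|B|^2 and
var(sigma) = sigma^2 / (2n).  F is reported unclipped with a warning
outside [0, 1]; per-residue filtering alone enforces the physical range.
sigma is fitted per data set (per protein), as the likelihood is written
per spectrum.  Monte-Carlo calibration (500 replicates, n = 28, F = 0.90,
0.003 ppm peak noise) shows the Hessian SE tracks the empirical SD within
~2%.

## Conformational-selection binding (`binding_kinetics`)

Scheme: open <-> closed (rates k_open, k_close), closed + L <-> closed.L
(k_on, k_off).  Key derived quantities:

    K_open/close = k_open / k_close = p_open / p_closed
    K_D          = k_off / k_on                  (intrinsic, closed state)
    K_D_obs      = (K_open/close + 1) * K_D      (apparent)

The forward model integrates the full mass-action ODE (ligand depletion
included; LSODA, rtol 1e-10) and checks protein/ligand conservation to
1e-9.  Under pseudo-first-order conditions the relaxation rates are the two
non-zero eigenvalues of the linearised scheme, computed in closed form from
their sum `k_open + k_close + k_on L + k_off` and product
`k_close k_on L + (k_close + k_open) k_off`.

**The two field-standard approximations** are implemented in their literature form and
validated against the exact eigenvalues:

* fast/binding phase: `k_obs = k_on/(K_open/close + 1) * L + k_off`.
  This population-scaled slope is exact in the *fast-exchange* limit
  (k_on L << k_open + k_close).  It is **not** the asymptote of the fast
  eigenvalue at large L, whose slope is the unscaled k_on; the residual
  error equals the open fraction.  The two eigenvalue branches undergo an
  avoided crossing near k_on L = k_open + k_close, and the experimentally
  tracked "binding" phase follows the slow branch below it and the fast
  branch above it.
* slow/conformational phase: a hyperbola in L with plateau k_close and
  half-saturation (k_close + k_open)/k_on.  Its error relative to the exact
  slow eigenvalue decays roughly as 1/(separation ratio) and, for the WT
  constants, retains a +3-5% excess even at ratios of 10-100 because the
  physical parameter family cannot match the exact 1/L approach to the
  plateau.

Consequently `recovery_experiment` (used by the round-trip validation)
applies each expression in its own regime: a low-concentration series
(k_on L <= 8% of the exchange rate) for the on-rate, a strong-dilution
chase (post-dilution ligand << K_D_obs, where rebinding bias is < ~2%) for
the off-rate, and a high-concentration series (separation ratio 8-136 — at
ratio >= 10 everywhere the slow branch has under 1% curvature left and the
closing rate becomes unidentifiable) for k_close.  On noiseless data this
chain returns k_close within ~4%, k_on within ~2%, K_D_obs within ~3%;
these floors are properties of the approximate literature expressions, not of the fits.

Exponential fits use multi-start bounded least squares (rates seeded
log-spaced between 0.5/span and 0.5/dt), optional linear drift, covariance
and AIC reporting; phase-count selection requires AIC improvement plus a
resolvability guard (threefold rate separation or minor amplitude above
three times the residual noise).  Replicates may be averaged before
fitting (the default, matching five-replicate averaging practice) or
fitted individually.  `apparent_kd` propagates uncertainty both to first
order and by seeded Monte-Carlo resampling; the two agree within 25% for
input CVs up to ~10%.

## Steady-state enzymology (`enzyme_kinetics`)

The fully open engine shows *partial substrate inhibition*: turnover rises,
peaks, and levels off at a second non-zero rate.  The two-site sequential
(Adair-Pauling) law

    k_obs = (kcat1 S/KD1 + kcat2 S^2/(KD1 KD2)) / (1 + S/KD1 + S^2/(KD1 KD2))

treats KD1/KD2 as macroscopic sequential dissociation constants (no
statistical-factor correction).  The fitter compares the full model with
the nested Michaelis-Menten case by AIC and falls back to the reduced model
(with a warning) when the data never descend from their maximum.  Replicate
SDs supply inverse-variance weights; with n = 3 replicates such weights are
themselves noisy, which the tests accommodate by using the canonical seeded
fixture.

Dose-response curves use a four-parameter logistic in log10 dose (midpoint
= IC50, free asymptotes by default; a 0/100%-constrained mode mirrors the
common two-parameter variant).  `restoration_concentration` inverts any
monotone inhibition model by bracketed bisection and returns infinity when
the target activity lies below the curve's floor — the quantity that
matters for activating mutants, where restoring basal wild-type activity
requires far more drug than the IC50 (e.g. 73.5 uM for a 50-fold activity
excess at K_D_obs = 1.5 uM).

## Coupled exchange + catalysis + sequestration (`coupled_model`)

States: closed, closed.drug, open, ES, ESS; substrate binds only the open
manifold, catalysis proceeds from ES (kcat1) and ESS (kcat2) with product
release returning open enzyme, and the drug sequesters the closed
conformer with its intrinsic K_D.  The steady state is solved two
independent ways — direct null-space solve and ODE relaxation (Radau) —
which agree to better than 1e-6 on randomised draws.

Numerical/structural choices:

* substrate association defaults to 1000 uM^-1 s^-1 so binding is
  effectively at equilibrium, matching the rapid-equilibrium engine law;
  lowering it probes binding-limited regimes where the Michaelis constant
  exceeds K_D.
* `k_open_close` is the canonical equilibrium field (open over closed);
  the reciprocal `K_close_open` is a derived property, avoiding the
  direction ambiguity between the two conventions in circulation.
* the closing rate defaults to 5.8 s^-1 at 35 C (about twofold above the
  25 C stopped-flow value), as a configurable default, with the NMR
  equilibrium fixing k_open.
* drug binding is resolved inside the steady state with free-drug
  depletion handled when the enzyme concentration is non-negligible; IC50s
  are extracted by bracketed bisection on the dose axis.
* the engine fixture (kcat1 370, kcat2 185, KD1 110, KD2 800; ~261 s^-1 at
  500 uM substrate) is **illustrative**: the true engine constants of the
  isolated catalytic domain are not published in a reusable form, so absolute full-length activities are not reproduced,
  only structural relationships.

**A structural property worth stating plainly:** because the closed state
exchanges only with free open enzyme, steady-state flux balance pins
[closed]/[open] = k_close/k_open regardless of how slow exchange is.
Activity suppression relative to the open engine is therefore bounded by
1/p_open, approached at low substrate occupancy, and the steady state is
independent of the exchange *rate* (only the equilibrium constant enters) —
both facts are asserted by tests.  Reported basal activities of the
full-length proteins imply suppression beyond this bound, so this scheme
topology cannot by itself reproduce them quantitatively; the package
reports what the model structure actually predicts.  Predicted potency
shifts are robust to this limitation because they depend on the landscape
ratio, not the absolute engine: with the WT and E76K landscapes the
half-inhibition concentration rises ~20-fold in the pure sequestration
limit and ~100-fold at 500 uM competing substrate.

An open-state-binding activator (e.g. a bisphosphorylated peptide) enters
through thermodynamic linkage, multiplying K_open/close by
(1 + [activator]/K_A); the predicted IC50 rises monotonically with
activator, as it must for a closed-state binder.

## Synthetic data (`synthetic_data`)

Generators are bit-reproducible functions of (scenario, seed) and emit
ground-truth sidecars.

* **Peak lists** place query peaks at the linear two-state average plus
  isotropic Gaussian noise in the weighted plane (default 0.003 ppm,
  a typical peak-position precision), with axis lengths log-uniform on
  0.05-0.5 ppm and planted violations for every filter class.  Presets
  carry the published landscapes (10.4 / 23.0 / 95.8% open; n = 28/13/22).
* **Stopped-flow traces** come from the full ODE with additive Gaussian
  noise (2% of amplitude by default) and optional drift; five replicates
  per condition; the dissociation chase pre-equilibrates the complex and
  dilutes it (preset: the bench design of 0.6/0.6 uM and 11-fold dilution,
  which the model shows to carry substantial rebinding bias — recovery
  experiments use a dilution satisfying the negligible-rebinding
  condition instead).
* **Activity/dose tables** are direct forward models with multiplicative
  (CV) and additive noise respectively.

What passing tests do *not* show about real data: peak assignment errors,
exchange-regime lineshape effects, instrument dead time, photophysics
(bleaching, inner-filter), buffer/temperature mismatches between assays,
and any deviation of the true engine from the two-site law are all outside
the generators; recovery results certify the analysis chain, not the
experiments.

## Degenerate inputs and tie-breaks

Coincident open/closed references raise a degenerate-axis error; a query
exactly at the measured-from reference takes the collinear angle of its
convention with F at the endpoint.  Noise-free likelihoods (sigma -> 0)
report infinite log-likelihood with zero variances rather than failing.
Empty post-filter sets, too-few residues/concentrations, flat slow-phase
data, negative fast-phase slopes, and targets below a dose-response floor
all raise typed errors rather than returning numbers.
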