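# Methods

## Model

The core is a deterministic mass-action model of BCL-2 family interactions.
All species are well-mixed concentrations in μM; time is in hours; every
reaction is elementary with order ≤ 2. The shipped network
(`src/momp/data/drmomp_network.yaml`, 71 species / 126 reactions) encodes:

- **Free proteins.** BIM, PUMA, NOXA (BH3-only initiators), BCL2, BCL(X)L,
  MCL1 (anti-apoptotic), BAX and BAK in inactive and activated forms.
- **Mode-2 sequestration.** Anti-apoptotic proteins reversibly bind BH3-only
  proteins. BIM and PUMA bind all three (K_D 2 nM); NOXA binds only MCL1
  (K_D 20 nM), encoding its restricted binding spectrum. The model file
  expresses every binding pair explicitly, so per-pair presence/absence is
  editable data.
- **Mode-0 sequestration.** Anti-apoptotic proteins bind *activated* BAX/BAK
  (K_D 10 nM), the dominant protective reaction once activation has begun.
- **Mode-1 sequestration.** Anti-apoptotic proteins also hold *inactive*
  BAX/BAK in weaker complexes (K_D 100 nM), a retro-translocation-style
  buffer.
- **Direct activation.** BIM and PUMA activate BAX and BAK catalytically via
  a transient encounter complex (K_D 0.5 μM, k_cat 50 h⁻¹); NOXA is a pure
  sensitiser and activates nothing.
- **Oligomerisation.** Activated BAX/BAK grow by monomer addition into
  assemblies of up to 20 subunits (association 360 μM⁻¹h⁻¹, dissociation
  0.36 h⁻¹ per step); assemblies of ≥ 12 subunits are designated pore
  species, consistent with the large ring assemblies effector pores form.

A generic protein–protein association constant k_on = 360 μM⁻¹h⁻¹
(10⁵ M⁻¹s⁻¹) is used throughout; affinities enter through
k_off = K_D · k_on, so detailed balance holds exactly per pair.

The network file is a reconstruction of this model class from its stated
structure and standard BCL-2 biochemistry, not a transcription of any
published parameter table; its header says so, and the loader accepts any
file following the same schema, so a revised transcription drops in without
code changes. Absolute η values therefore depend on this parameterisation;
the package's checked claims are the structural counts, conservation,
oracle agreement and the monotone/ordering behaviour documented by the test
suite, not specific η magnitudes.

## Stress dose η

Genotoxic stress is modelled as step-function production of BIM, PUMA and
NOXA at equal constant rates for 12 h (the production window equals the
simulated horizon by default; a post-production margin is configurable).
Production is an *external input schedule*, not part of the reaction list,
so the 126-reaction count and all conservation groups are independent of the
applied stress. η is the **total** BH3-only production over the window
(rate summed across the three proteins × 12 h); the per-protein rate is
η/(3 · 12 h).

MOMP is declared when the pore read-out (summed concentration of ≥ 12-mer
assemblies) crosses a threshold within the horizon. The threshold
(0.01 μM) is recorded in the model file; it was fixed once, when the model
file was built, such that an unstressed simulation of any profile in the
shipped panel produces zero pores while the stress transition is switch-like
and reachable for every effector-expressing profile. η is located by
bisection on [0, η_max] (default η_max = 10 × total anti-apoptotic
concentration, floor 1 μM — mass-action buffering cannot exceed the buffer
capacity by a large factor), to a relative tolerance of 10⁻³, at most 40
iterations. Degenerate cases are reported as status markers rather than
numbers: threshold ≤ 0 → η = 0; MOMP with zero stress → η = 0 (flagged);
no MOMP at η_max (e.g. BAX = BAK = 0) → `resistant_beyond_bound`.

The returned `StressDose` carries the final bisection bracket. Comparisons
between η values (e.g. monotonicity along a dose scan) should use the
bracket widths as the resolution of the estimate; the test suite does.

## Antagonists

A selective inhibitor is a descriptor (target ∈ {BCL2, BCLXL, MCL1}, K_D in
nM, bioavailability factor). With nominal dose d, the network gains one drug
species at concentration 0.5 · d (the default factor models drug degradation
and active extrusion) plus reversible binding against the free target only.
Shipped defaults use the published discovery-paper affinities — ABT-199
0.01 nM, WEHI-539 1.1 nM, A-1210477 0.45 nM — marked non-authoritative in
the config; they are inputs, not fitted quantities. A drug whose target is
absent from a profile provably changes nothing (its binding flux is zero),
and the implementation preserves this exactly.

## Numerical choices

- LSODA (stiff-capable) with analytic Jacobian assembled from the
  stoichiometry; rtol = atol = 10⁻⁶ μM. nM-scale affinities against μM
  concentrations make the system stiff.
- Concentrations are never clamped inside the right-hand side: mass-action
  kinetics self-correct small negative excursions, and a consistent
  rhs/Jacobian pair is what keeps the implicit solver convergent. A
  trajectory more negative than 100 × atol aborts with a diagnostic naming
  the interval; smaller excursions are clipped to zero on output.
- Integration is split at every production-schedule breakpoint so the solver
  never straddles the 12-h step discontinuity.
- Conservation groups (one per core protein, oligomers weighted by subunit
  count) are verified symbolically against the stoichiometry matrix at
  network construction, and numerically along trajectories by
  `check_conservation`; groups coupled to production/degradation reactions
  are flagged open rather than failing.
- At saturating stress doses the *peak* pore amount can decline by a few
  percent even though the MOMP indicator stays monotone: large BH3-only
  excess holds a standing fraction of effectors inside activation
  (Michaelis-type) encounter complexes. Dose–response monotonicity is
  therefore asserted below this saturation regime, and the bisection relies
  only on the threshold indicator, which is monotone over the bracket (the
  grid-search oracle in the tests confirms this).

## Synergy analytics

Fraction affected is 1 − viability. Webb CI is oriented as
fu_observed/(fu_A · fu_B), so CI < 1 means synergy, matching the
classification thresholds (CI < 0.3 strong synergy, CI = 1 additive,
CI > 1 antagonistic; thresholds applied exactly). Single-agent curves are
variable-slope four-parameter logistics fitted by trust-region least squares
with tight convergence tolerances; data non-monotone beyond 0.05 fall back
to isotonic regression plus interpolation (flagged). Loewe predictions solve
the additivity identity by bracketed Brent root finding over the jointly
achievable effect range; combinations outside that range clamp to the range
boundary with a saturation flag (the exact behaviour of proprietary
implementations at saturation is undocumented, so the clamp is this
package's own convention). Isobologram contours are linear interpolations of
the iso-effect crossing along each matrix row; on a 6-point logarithmic dose
grid this interpolation carries ~10–15 % error, which is the tolerance the
sham-contour test uses. In-silico pore synergy grids normalise peak pore
amounts by the grid maximum to form effect fractions before applying Webb
CI; that normalisation is a convention of this package, documented here
because pore amounts have no natural [0, 1] scale.

Dose-matrix aggregation: per-pair CI is reported together with mean ± SD
over nonzero pairs; any scalar summary of a CI matrix is an assumption, so
the per-pair values are always retained.

## Synthetic data

`sample_profiles` draws concentrations log-uniformly within per-protein
ranges spanning the observed panel (0.001–4.581 μM overall); the panel
spans > 3 orders of magnitude, which a Gaussian would misrepresent.
`survival_from_eta` maps η to surviving fraction through a logistic in
ln η (floor 0.05, ceiling 0.95, slope 1.0) plus truncated Gaussian noise
(default sd 0.05); the slope was calibrated once so that rank recovery at
the default noise level is strong but not trivially saturated, and then
frozen. `synth_dose_matrix` builds 6 × 6 grids from two Hill curves under an
exact ground truth: Bliss independence (fu product), sham dose additivity
(one drug at two potencies, which is exactly Loewe-additive for parallel
Hill curves), or Bliss with the interior unaffected fraction scaled by
(1 ∓ boost) for synergy/antagonism. Zero-dose margins are left noise-free so
marginal consistency is exact at zero noise.

What the generators deliberately do not emulate: plate/edge effects,
heteroscedastic assay noise, correlated replicate structure, protein
measurement error, and any coupling between a profile and its dose-response
shape beyond the monotone η link. Tests passing on synthetic data therefore
demonstrate correctness of the computations under the stated statistical
model, not robustness to real assay artefacts.

## Problem sizes

Default test and acceptance runs use the shipped eight-line panel, 6 × 6
synthetic matrices, 3–5-point antagonist scans, 200-replicate survival
recovery, and a 1000-point grid-search oracle on a reduced two-protein
network — sizes chosen so each check isolates one property at full numerical
fidelity.

## Known limitations

- Rate constants are literature-scale class values, not a fitted or
  transcribed parameter set; η is meaningful as an ordering/sensitivity
  score, and absolute μM values shift with the parameterisation.
- No pharmacokinetics: antagonist exposure is a constant effective
  concentration over the window.
- Nothing downstream of MOMP (caspase activation, clearance) is modelled.
- Drugs bind only their nominal target; polypharmacology would need extra
  binding entries in the antagonist expansion.
- Deterministic and well-mixed: no cell-to-cell variability, no membrane
  compartmentalisation.
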