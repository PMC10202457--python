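# Methods

## Model structure

The model describes an over-expressed EGFR-class receptor carrying a
C-terminal tyrosine activation motif, together with a cytosolic fluorescent
tandem-SH2 reporter that binds the motif once the receptor is activated.
Each receptor carries three binary states — ligand-bound, dimerized,
reporter-bound — and every combination is a species: free ligand and free
reporter, four monomer states, and the ten unordered pairs of per-receptor
states as dimers, 16 species in total.  Dynamics are pure mass action.

Binding rules:

- **Ligand exchange.** Ligand associates at k₁ with any unliganded receptor
  (monomeric or within a dimer) and dissociates at β·k₇.  Free ligand is a
  clamped constant, not an integrated state: the bath contains vastly more
  ligand than the cell carries receptors, so depletion is negligible.
- **Dimerization.** Any two monomers dimerize at k₅; dimerization and
  autophosphorylation are lumped into one event, so a dimer carrying at
  least one ligand is the active, phosphorylated complex.  Ligand-free
  dimers are inactive but real (pre-formed dimers) and dissociate at k₆;
  active dimers dissociate at γ·k₃.  The homodimerization flux of a
  monomer species A is written k₅·[A]² (and 2k₅·[A][B] for unlike pairs),
  the convention under which the pre-stimulus equilibrium below is exact.
- **Reporter exchange.** The reporter associates at k₂ with either tail of
  an active (ligand-bearing) dimer — trans-autophosphorylation exposes both
  tails — and dissociates at k₄ from any reporter-bound receptor.  Species
  carrying reporter but no ligand (reporter-bound monomers, reporter-bound
  ligand-free dimers) are therefore never produced by association; they
  appear only transiently when an active complex loses its ligand or falls
  apart before the reporter unbinds.  An alternative reading of the rate
  roles (k₇ as the active-dimer off-rate) exists in prose descriptions of
  such models; it is incompatible with β being a *binding*-affinity scale
  and γ a *dimerization*-affinity scale, so the assignment above is used
  (see the note in `parameters.py`).

The right-hand side is generated from a declarative reaction list
(reactants, products, rate slot, statistical multiplier) rather than
hand-coded.  This makes the two linear conservation laws — total receptor
(weight = receptors per complex) and total reporter (free + bound) —
mechanical: the stoichiometry matrix is exactly orthogonal to both weight
vectors in integer arithmetic, which the tests assert.

Out of scope by design: receptor trafficking, internalization and
degradation (the simulated horizon is ~30 min in cells whose membrane
receptor pool is approximately constant on that timescale), receptor
heterodimers, and spatial effects.

## Parameters and units

Internal units are molar and seconds; doses in ng/mL and receptor copy
numbers are converted at the boundary (dose × 10⁻⁶ / MW; copies /
(N_A · 4/3·π·r³)).  Default ligand molecular weight is 6222 g/mol (human
EGF); low-affinity ligands use the same default, so dose comparisons are on
the ng/mL scale throughout.

Two parameter groups have literature-range defaults: ligand binding
k₁ = 10⁷ M⁻¹s⁻¹, k₇ = 2×10⁻² s⁻¹ (K_d = 2 nM, EGF–EGFR range) and
reporter binding k₂ = 10⁷ M⁻¹s⁻¹, k₄ = 0.1 s⁻¹ (K_d = 10 nM, the
avidity-enhanced tandem-SH2/ITAM range).  The lumped dimerization constants
were calibrated by matching the qualitative shape of high-dose EGF
responses — a fast phase complete within ~1 minute followed by a slow
further rise over ~20–30 minutes, switching to a transient peak with
plateau when γ is raised to 100: k₅ = 10⁴ M⁻¹s⁻¹ sets the slow-phase
timescale 1/(k₅·N_E,o) ≈ 17 min, k₆ = 5×10⁻³ s⁻¹ (the one externally
pinned value) puts ~23 % of receptor in pre-formed dimers at the default
expression level, and k₃ = 10⁻⁴ s⁻¹ makes EGF-bound dimers more stable
than ligand-free ones (the paper-described hierarchy) while γ = 100
inverts it.  Receptor total: 250,000 copies in a 10 µm sphere
(9.91×10⁻⁸ M); reporter equals receptor by default (1:1 molar ratio).

Ligand identity enters only through β (multiplies k₇) and γ (multiplies
k₃).  The standard low-affinity-ligand setting is β = 50, γ = 100.  The
GBM-mutant scenario compares wild-type receptor + EREG (β = 50, γ = 100)
with the mutant receptor + EREG.  Published characterization of the R84K /
A265V mutations reports a ~650-fold *increase* in dimerization affinity of
low-affinity-ligand-bound receptors and a ~6-fold change in ligand
binding; the default scenario therefore uses β = 6, γ = 100/650 (dimers
650-fold more stable than WT+EREG).  A literal alternative reading —
multiplying the WT-EREG scalings by 6 and 650, i.e. *weakening*
dimerization — contradicts the reported affinity change and the predicted
"stronger, more gradual" mutant response; it is available behind
`interpretation="literal"` for comparison.

## Pre-stimulus equilibrium

With no ligand and no reporter bound, receptor partitions between monomer
N₃ and inactive dimer N₅:

    N_E,o = N₃,ₒ + 2·N₅,ₒ,    k₅·N₃,ₒ² = k₆·N₅,ₒ

giving 4N₅² − (4N_E,o + K)·N₅ + N_E,o² = 0 with K = k₆/k₅.  The physical
(smaller) root is evaluated as 2·N_E,o² / (b + √(b² − 16·N_E,o²)),
b = 4N_E,o + K, which avoids the catastrophic cancellation of the
"b − √(…)" form when dimerization is weak (K ≫ N_E,o); a bracketing root
finder serves as the independent oracle in tests.  The resulting state is
an exact fixed point of the zero-ligand dynamics (numerical residual at
machine-precision level, asserted to ≤ 10⁻¹⁰·N_E,o/s across a wide
parameter grid).

## Numerics

Two integration kernels share one compiled mass-action RHS:

- an **embedded adaptive Dormand–Prince RK5(4)** (rtol 10⁻⁸, atol 10⁻¹⁴ M)
  that steps exactly onto the output grid (default 5 s over 30 min).  The
  step is additionally capped at the fast-mode stability limit estimated
  from the rate constants.  No mid-integration clipping is performed:
  Runge–Kutta steps preserve linear conservation laws exactly, and clipping
  would break them (conservation drift over 30-min runs is ≲ 10⁻⁶ relative,
  dominated by roundoff).  Tiny negative undershoots are clipped only at
  output; undershoots beyond ~10³× the local error tolerance abort.
- a **fixed-step classical RK4** at 1 ms, the brute-force reference; the
  production solver agrees with it to ≲ 10⁻⁶ relative on clearance
  (asserted at 10⁻⁴).

A stiff-capable route (scipy's LSODA) is wrapped as well.  After the fast
binding transient the system is effectively stiff — explicit steps remain
stability-limited — so LSODA is 10–100× faster at loose tolerances and is
selected automatically for the fitting loop and for strongly scaled
parameter corners (β, γ up to 10⁴, where off-rates reach ~10² s⁻¹).  It
also serves as the independent cross-check of the compiled kernel in the
unit tests.  At fixed solver settings all routes are bit-deterministic.

## Kinetic-regime classification

The qualitative regime vocabulary is operationalized with deterministic,
config-exposed rules (all on the 30-min clearance trace): *flat* if the
30-min clearance is below 1 %; *peak-plateau* if the maximum inside the
first 5 min is ≥ 1.02× the 30-min value and ≥ 90 % of the 30-min value is
reached by 5 min; *biphasic-rising* if the trace is monotone within 0.5
percentage points, the mean slope on [0, 2 min] is ≥ 5× the (positive)
mean slope on [10, 30 min], and the 30-min value is ≥ 1.10× the 5-min
value; otherwise *gradual-rising*.  Kinetics claims about dose panels are
evaluated over "responding" doses only — those whose 30-min clearance
exceeds 10 % of the panel maximum.  Under a pure binding-affinity change
(β = 1000) the response at dose d mirrors the base case at roughly d/β, so
that panel shows the base-case class sequence truncated from below;
"kinetics unchanged" is therefore checked as: no class outside the
base-panel vocabulary appears, and in particular no peak-plateau.

## Trace quantification

Per-cell cytosolic intensity tables are converted to percent clearance via
activity(t) = −100·(I_cyt(t)/I_cyt,o − 1), with I_cyt,o the mean of the
pre-stimulus frames (configurable count; 1 if unspecified).  Frame-wide
microscope artifacts are detected per experiment: a frame is flagged when
the median across cells of the signed relative change from the previous
(already repaired) frame exceeds 30 % in magnitude and ≥ 80 % of cells
move in the same direction; flagged frames take each cell's previous-frame
value (placeholder rule).  Both thresholds are config-exposed; the 30 %
bound sits well above per-frame physiological change (≲ 15 % per 30 s
frame even at saturating dose) and well below the ~3-fold artifacts
observed, so on the synthetic benchmark the rule operates with perfect
recall and no false positives.  A corrupted *first* frame has no
predecessor and is reported as an error rather than repaired.  Replicate
aggregation is hierarchical: cell means per experiment first, then mean ±
sample SD across experiment means — never pooled-cell SD.  Time to
half-max is the first, linearly interpolated crossing of 50 % of the
trace's own maximum; min–max normalization maps a trace to [0, 1] by its
own extrema.  KTR (kinase translocation reporter) activity is the
cytosolic:nuclear intensity ratio.  Membrane enrichment is the maximum of
a line-scan profile.

## Synthetic data

The generator emulates the statistical structure of the imaging tables:
per-cell receptor and reporter expression as independent log-normal
multipliers (geometric SD 1.8 by default — a fixture choice spanning the
expression-ratio range over which biosensor amplitude visibly varies, not
an estimate from data); per-cell dynamics simulated at that cell's own
totals; cytosolic intensity proportional to the free-reporter fraction
with multiplicative log-normal per-frame noise (CV 5 % default); optional
frame-wide fold-change artifacts (never frame 0, which could not be
repaired); optional linear photobleaching (off by default).  A JSON-able
ground-truth sidecar records true clearance, artifact frames and folds,
expression multipliers and the generating (β, γ), sufficient to score
every quantifier output.  All randomness flows from the spec's seed.

KTR traces are driven by a clearance signal through a **transport delay**
(default 240 s) plus an affine map to the cytosolic:nuclear ratio.  A
transport delay (rather than first-order smoothing) is used because it
shifts time-to-half-max by exactly the lag, making the ground-truth lag
identifiable to within one frame; an optional first-order smoothing
constant is available on top.

What passing tests on these fixtures do *not* show: robustness to
segmentation errors, photobleaching-correlated noise, cell movement or
focus drift, or receptor internalization — none of which the generator
emulates.

## Parameter fitting

Ligand scalings (β, γ) are fit to mean clearance traces at one or more
doses by least squares in (log₁₀β, log₁₀γ) over [−2, 4]², all other
parameters fixed — mirroring the separation between one-time base-model
calibration and ligand-specific scaling.  The optimizer is derivative-free
(Nelder–Mead with box bounds): 10 restarts by default (first at the
origin, the rest uniform in the box, seeded), each run briefly, with the
best endpoint polished to convergence; every restart's loss is recorded.
Fit-loop simulations use rtol 10⁻⁶ through the automatic solver route.
Non-identifiability is reported, not hidden: after the fit, the loss is
probed ±0.15 decades along the axes and diagonals, and any direction whose
loss rise is below 1 % of the residual floor is flagged (a single weak
dose constrains only a combination of β and γ and trips this flag).  An
optional amplitude scale factor can be co-fit for data whose absolute
amplitude is not trusted.

Recovery under the reference conditions (3 doses at 2/20/200 ng/mL, 50
cells per dose, 5 % noise, homogeneous expression so the population mean
estimates the model trace) lands both parameters within ~10–15 % of
(β, γ) = (50, 100) in a typical replicate; the seeded 20-replicate report
is part of the acceptance run.

## Problem sizes

Default experiment sizes used throughout tests and the acceptance script:
30-min horizons at 5 s output (solver) and 30 s frames (imaging-side);
dose panels of 4 (β, γ) combinations × 7 doses; 32-point ratio sweeps;
populations of 20–50 cells; 20 replicate fits in the recovery report.
These sizes make the full chain reproducible in minutes on a single CPU
while keeping every statistical check comfortably powered.

## Known limitations

- The reaction catalogue treats both tails of any ligand-bearing dimer as
  phosphorylated; singly-ligand-bound dimers therefore recruit reporter on
  both tails.  If only the liganded tail were competent, reporter capacity
  per singly-bound dimer would halve; amplitudes would shift but the
  regime structure would not.
- Free-ligand clamping ignores depletion; at sub-ng/mL doses in small
  volumes this would overestimate occupancy.
- The fitted (β, γ) absorb any mismatch in the fixed base constants; they
  are fold-changes relative to the calibrated base model, not absolute
  biophysical constants.
- The regime classifier is threshold-based; traces near a boundary (e.g.
  an early/late slope ratio near 5) can switch label under small parameter
  changes.  Thresholds are exposed precisely so sensitivity can be probed.
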