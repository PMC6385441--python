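# Methods

## The model

`yeastiron` implements a compartmental kinetic model of iron import,
trafficking and regulation in exponentially growing *Saccharomyces
cerevisiae*.  The cell is three nested regions — cytosol (plus all organelles
other than the two modelled ones), mitochondria, and vacuoles — with fixed
volume fractions f_cyt = 0.8, f_mit = 0.1, f_vac = 0.1 (respiring W303
cells).  Because the culture volume grows exponentially at rate α while
fractional volumes stay constant, every concentration [X] obeys an ODE of the
form

    d[X]/dt = (formation) − (consumption) − α·[X]

and the *expanding steady state* is the condition in which production of each
species exactly balances growth dilution, rate = α·[X].  Only volume ratios
enter the equations: flux from cytosol into an organelle is multiplied by
f_cyt/f_organelle so that moles are conserved when material changes reference
volume.  Absolute volumes are therefore never stored.

Four tiers of resolution share one parameter vocabulary:

* **C1** — all cell iron as one pool, `Fe_cell`; import follows a Hill law in
  nutrient iron N, `R_cell = R_cell_max·N^sens/(K_N^sens + N^sens)`.
* **C3** — one pool per compartment (`Fe_cyt`, `Fe_mit`, `Fe_vac`);
  mitochondrial import is mass-action in the labile cytosolic pool,
  vacuolar import a Hill law.
* **C4** — the cytosolic pool splits into labile Fe(II) (`C`) and the
  cytosolic/nuclear ISC + low-spin-heme pool (`CIA`).
* **C9** — full speciation: `C, CIA` (cytosol), `FM, FS, MP` (mitochondrial
  labile Fe(II), ISC/heme centers, nanoparticles), `F2, F3, VP` (vacuolar
  Fe(II), Fe(III), nanoparticles) and matrix oxygen `O2`.

The C3 tier deliberately uses the labile pool (identical to the whole
cytosolic pool at that tier) as the substrate of the organelle import laws so
that `k_mit` and `R_vac_max` keep their meaning when the tier is refined —
iron flows into mitochondria in proportion to the labile pool only, not to
the ISC-bound pool.

Growth follows a Michaelis–Menten law α(N) = α_max·N/(K_α + N).  The source
tables print K_α with 1/hr units; it is the half-saturation *concentration*
of the growth law, so the package carries it in μM.

### Oxygen and the vicious cycle

Matrix oxygen obeys

    d[O2]/dt = k_O2·(O2_cyt − [O2]) − k_mp·[FM]·[O2] − k_res·[FS]·[O2] − α·[O2]

with cytosolic oxygen fixed at 100 μM.  Respiratory complexes (proxied by the
ISC pool FS) consume oxygen; whatever oxygen reaches the matrix converts
labile Fe(II) into nanoparticles (MP) instead of letting it feed ISC
assembly.  Low FS → high O2 → more MP → even less FS: a self-reinforcing
loop.  Conversely, healthy mitochondria exclude oxygen (micro-aerobic
matrix) and keep assembling ISCs.  At steady state the balance closes to

    [O2] = O2_cyt·k_O2 / (k_O2 + k_mp·[FM] + k_res·[FS] + α),

which the solver verifies against the integrated value.

The vacuolar Fe(II)→Fe(III) conversion is gated by a phenomenological
iron-regulon valve, Reg = 1/(1 + ([FS]_sp/[FS])^n23): nearly closed when ISCs
are scarce (keeping vacuolar iron as Fe(II)), half-open at the set point
(370 μM), open under iron sufficiency.  Reg(0) is defined as 0 by continuous
limit, and the power is computed in a guarded form so that astronomically
small FS underflows to a closed valve instead of overflowing.

### Strains

Wild type (`WT`) and the Mrs3/4 double deletion (`DD`), which lacks the
high-affinity mitochondrial iron importers, differ in exactly four parameter
families: the import Vmax pair (R_cell_max/R_cyt_max: 180/230 WT vs 390/480
DD), the mitochondrial import constant (k_mit 5.5 vs 1.2, with
three-compartment-tier values 2.8 vs 1.6), the vacuolar nanoparticle
constant (k_vp 1.10e-7 vs 2.37e-7) and the growth half-saturation
(K_α 0.13 vs 3.9 μM).  All other constants are shared.  The bundled values
live in `src/yeastiron/data/canonical_parameters.yaml`.  R_cyt_max is the
printed optimized value (230/480) rather than R_cell_max/f_cyt (225/487.5);
the ≤3% difference between the two is a rounding artefact of the source
tables and is preserved as printed.

## Steady-state solving

`solve_steady` integrates from the canonical initial conditions (10 μM for
every iron component, 0 μM oxygen) with LSODA (rtol 1e-8, atol 1e-10) over
geometrically expanding horizons until max|d[X]/dt| / max(|[X]|, 1 μM) falls
below tol (default 1e-9), up to t_max = 1e4 hr; non-convergence is flagged,
never raised.  The system is stiff — dilution acts at ~0.05/hr while the
respiration term k_res·[FS] can exceed 1e4/hr.  After convergence the
algebraic system is root-polished (hybrid Powell), and the polished root is
kept only if it is non-negative and within 1e-3 relative of the integrated
point, so polishing can tighten residuals (to ~1e-12 relative) but never
switch branches.  Integrator tolerances are package choices; the source
describes only "solve to steady state".

### Bistability

The mitochondrial subsystem is genuinely bistable in iron-poor conditions:
a nanoparticle-dominated branch (high O2, low FS) coexists with a healthy
branch (micro-aerobic, high FS).  From the canonical initial conditions the
model selects the nanoparticle branch for the starved mutant (DD at N = 1
and 2 μM) *and* for WT at N = 1 μM; the healthy branch at those conditions is
reached from ≥3× larger initial iron.  Published simulated values for WT N=1
and DD N=2 correspond to the healthy branch; the bundled tables flag those
cells (`status=branch`) and the attractor probe in `steady_state` exposes
both branches.  Because branch selection is trajectory business, steady
states are always obtained by integrate-then-polish, never by blind root
finding.

## Observation tables and Mössbauer bookkeeping

Mössbauer spectroscopy resolves sample iron into four groups (NHHS Fe(II),
central doublet, nanoparticles, NHHS Fe(III)) on whole-cell and mitochondrial
bases.  Given an assumed labile cytosolic concentration [C] (taken from
chelator-based estimates; it is below spectroscopic detection), the group
map is linear and square, and `mb_data` inverts it exactly; the forward and
inverse maps round-trip to machine precision.  Data-based fluxes follow from
the steady-state algebra alone (R = α·pool, organelle imports carrying the
volume ratio).

The published tables are shipped as a canonicalized CSV
(`observations.csv`, one row per table × strain × N × basis × quantity).
The printed originals are typographically run together, so every cell was
validated against the internal algebra before being trusted; cells that
could not be validated are flagged `unparsed` or `discrepant` (e.g. the
starved-WT vacuolar iron that two tables disagree about, and the
starved-mutant simulated row) and all programmatic consumers skip them.  The
loader checks a SHA-256 of the file.  Printed cells are 2-significant-figure
roundings of quantities computed from already-rounded inputs, so consistency
checks use a 10% band and comparisons of recomputed single quantities a 5%
band (half an ulp in the second significant digit).

## Fitting

The objective is ERR = mean over datapoints of 2·|sim − dat|/(sim + dat),
which weighs each point evenly although pools span four orders of magnitude.
Optimization is multiplicative coordinate descent: each parameter in turn is
tried at ±step, a candidate is accepted only if it strictly lowers ERR (ties
reject, for determinism), the step schedule is ±10%, ±5%, ±1%, sweeps at one
step repeat until a sweep accepts nothing, and the whole coarse-to-fine
schedule is re-run until a full pass accepts nothing.  The repetition is
this package's choice: a single pass stalls in shallow valleys of correlated
parameters.

The tiers are fitted in order, each transferring its optimized parameters to
the next: (1) growth and whole-cell import laws against α and R_cell;
(2) organelle import laws against the compartment fluxes, with R_cyt_max
initialized to R_cell_max/f_cyt and then re-freed; (3) the cytosolic ISC law
against R_cia; (4) the full model against all pools and formation rates,
after rescaling the mitochondrial constant (×2 WT, ÷1.3 DD) — the adjustment
required so that WT mitochondria exclude oxygen at every N while
ISC-deficient mitochondria still fill with nanoparticles.  A final joint
pass may re-free everything.  Exactly which datapoints enter each stage's
ERR is not uniquely determined by the source material; the composition used
here is recorded per fit in `FitResult.datapoints_used`, and absolute ERR
values are therefore not comparable across compositions.

Stage 1 offers a data-driven initialization (double-reciprocal regression
for the growth law; logit regression for the import law) used by the
recovery harness; the descent schedule does all refinement.

Sensitivity uses the one-at-a-time index S = (ERR(+1%) + ERR(−1%)) /
(2·ERR(opt)): S = 1 for a parameter the objective ignores, larger S for
parameters the fit depends on.

## Synthetic data and what passing tests show

`synthetic` generates observation tables with the structure the analysis
assumes: solve a chosen tier to steady state per strain × N, map pools to
the Mössbauer observables, apply independent unit-mean lognormal noise of a
given CV to every *observable* (groups, α, whole-cell iron, the assumed [C])
— not to derived pools — then run the same inversion and flux algebra used
on real data.  Multiplicative noise is the natural error model for positive
observables spanning four decades; the 2-significant-figure printing of the
source tables corresponds to an implicit CV of roughly 5–10%.  Ground truth
is recorded alongside, including the observable-level import Vmax
(f_cyt·R_cyt_max when the source tier is compartmental).

The generator reproduces the *statistical* structure of the measurements,
not their systematic errors: real spectral decompositions have correlated
group errors, baseline ambiguity, and the assumed-[C] convention; none of
that is simulated.  Recovery results therefore demonstrate that the pipeline
is correct and well-conditioned under its own assumptions, not that the
published parameter values carry 5% uncertainty.

The recovery study uses 8 log-spaced nutrient levels on [0.25, 41] μM.  The
lower end is below what real minimal medium allows (~1 μM endogenous iron);
it is chosen so the design brackets the smallest half-saturation constant
being recovered (WT K_α = 0.13 μM).  With conditions floored at 1 μM that
constant is statistically unidentifiable at 5% noise — the exact lognormal
MLE has ~31% median error (CRLB σ_logK ≈ 0.34) — which is itself an
informative design-of-experiment finding: the growth of WT cells is already
nearly iron-saturated at the lowest achievable medium concentration.

## Numerical conventions and degenerate inputs

* Non-integer exponents (nisu 2.3, nvp 2.4, n23 1.6) are real powers of
  non-negative arguments; ODE right-hand sides clip transient solver
  undershoot to zero before exponentiation (the oxygen influx term uses the
  raw value so overshoot relaxes back).
* Zero-substrate rates are exactly 0; `reg_fs(0)` = 0 by limit.
* ERR skips (with a warning) pairs whose sim+dat sum is zero.
* `pools_from_groups` forgives inferred-pool negativity within 1e-9 of the
  total (float cancellation) and otherwise raises naming the offending pool.
* N is constant during a run (boundless-medium assumption); sweeps outside
  the calibrated [1, 41] μM range warn but proceed.
* All randomness flows through a single integer seed per synthetic config.

## Problem sizes used by the shipped analyses

Nutrient sweeps use 33 log2-spaced points on [1, 41] μM; the
frataxin-deficiency scan 13 points on [0, R_isu_max]; perturbation traces a
6-point N grid; the recovery study 8 N values × 2 strains, noise-free plus
20 noisy replicates at CV = 5%.  A full eight-condition C9 steady-state
table solves in under a second on one core.

## Known limitations

* The supplementary ODE listings of the source work were not available; the
  systems are reconstructed from the printed equations.  The bistable branch
  mismatches at WT N=1 / DD N=2 (see Bistability) are consistent with a
  small difference between that file and the reconstruction, or with
  different effective initial conditions in the published runs.
* The model under-predicts the iron hoarded by the mutant at N = 41 (the
  source analysis accepts the same misfit to keep the model simple).
* ROS is not an explicit species (it tracks MP one-to-one), the iron regulon
  is a single phenomenological valve rather than a transcriptional model,
  and Mössbauer spectral fitting itself is out of scope — only printed group
  concentrations are consumed.
* ERR values printed in the source for the tiered fits are not reproducible
  without their exact datapoint composition, which is unrecorded; they are
  deliberately not test surfaces.
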