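# Methods

## Model

The model tracks six representative MADS-box proteins of the Arabidopsis
floral meristem — AP1 (A function), AP3 and PI (B), AG (C), SHP (D), SEP
(E) — in each of the four whorls, over days 0–5 of meristem development.
Concentrations are in nM, time in days. Assumptions:

- no spatial coupling between whorls (no diffusion); whorls differ only
  through two timed trigger inputs;
- transcription is regulated by protein **dimers** (the DNA-binding
  species): production of gene *i* is a sum of Michaelis–Menten terms
  over its activating dimers, multiplied by an unoccupied-site factor
  `Km/(Km+R)` for each repressing dimer — transcription requires at least
  one occupied activation site and all repression sites empty;
- translation delay is neglected (transcription is protein production);
- dimers decay only by dissociation into functional monomers;
- the triggers (AP3: whorls 2–3; AG: whorls 3–4) are constant inputs on
  the half-open window [day 1, day 2) and zero otherwise; their biology
  (LFY/UFO, WUS/LFY) is not modeled.

The full model per whorl has 13 states (6 monomers + 7 dimers) and 51
parameters (13 β, 16 Km, 6 decay rates, 2 trigger magnitudes, 7 pairs of
Kon/Koff). The seven dimer species are [AP1 SEP], [AG AG], [AG SEP],
[AP3 PI], [AP1 AP1], [SEP SEP] and [SHP SEP]; [SHP SEP] is formed but
regulates nothing (its loss is a pure D-function phenotype).

The wiring encodes the floral logic: AP1 and AG mutually repress through
their homodimers ([AG AG] ⊣ AP1, [AP1 AP1] ⊣ AG) — a bistable A–C toggle
that the AG trigger flips in whorls 3–4; AP3/PI autoactivate through the
obligate [AP3 PI] heterodimer — a latch that the AP3 trigger ignites in
whorls 2–3; SEP self-maintains through [SEP SEP] and supports every other
function through its heterodimers.

## Quasi-steady-state reduction

With Koff ≈ 1 min⁻¹ (= 1440 day⁻¹) and day-scale transcription/decay,
dimerization equilibrates essentially instantaneously. Setting the dimer
derivatives to zero gives [xᵢxⱼ] = γᵢⱼ xᵢ xⱼ with γ = Kon/Koff, and
substituting into the monomer balance yields six implicit ODEs that the
package writes in mass-matrix form **M(x) ẋ = g(x,t)**, where g collects
production + trigger − decay and

    M_ii = 1 + Σ_het γ_ij x_j + 4 γ_ii x_i,   M_ij = γ_ij x_i.

M is exactly the Jacobian of the monomer→total mass balance. It is
strictly diagonally dominant **by columns** for x ≥ 0 (each column's
off-diagonal entries γᵢⱼxⱼ are dominated by the diagonal of that column),
hence always invertible; note row dominance does *not* hold in general
(a large xᵢ puts γᵢⱼxᵢ off-diagonal in row i). Every right-hand-side
evaluation is a dense 6×6 linear solve — no general DAE machinery.

The reduction is validated against the full coupled model as the oracle:
at Koff = 1440 day⁻¹ the monomer trajectories agree within 2% sup-norm
(relative to each gene's trajectory maximum, after a 0.1-day transient)
in all whorls, and the error decreases along the ladder Koff ∈ {144,
1440, 14400} day⁻¹.

Homodimer stoichiometry: forming one homodimer consumes two monomers; the
factor 2 appears in the monomer balance, the totals (total = x + Σ_het
[dimer] + 2·[homodimer]), and the 4γx term of M.

## Total ↔ monomer conversion

Measured concentrations are totals (monomer + dimer-bound). The forward
map total(x) is polynomial; the inverse uses damped Newton iteration with
the exact Jacobian M(x), initial guess x = totals (exact at γ = 0),
step-halving on residual increase, positivity projection, tolerance
1e-10·(1+‖totals‖), max 100 iterations. Uniqueness of the non-negative
root follows from monotonicity of the forward map; the round trip is
reproduced to better than 1e-8 relative over [1, 10⁴]⁶ nM.

## Data transformation

Microarray-style meristem averages are converted to whorl-resolved
concentrations in five steps: (1) one joint multiplicative scaling so the
grand mean over genes and days is 10³ nM (typical eukaryotic TF
concentration; the single joint factor — rather than per-gene factors —
is recorded in the output sidecar); (2) off-state = 1% of an expressed
gene's level; (3) the on/off pattern per gene/whorl/day from the
developmental expression table (days 0–1: uniform expression across the
meristem); (4) constant whorl volumes (1.1, 2.7, 2.9, 1.1)·10⁴ μm³;
(5) the volume-weighted mass balance fixes the per-gene scaling factor
α_i(t) = ĉ_i(t)·ΣV_w / Σe_i^w V_w and c_i^w = e_i^w α_i(t). The
transformation preserves the meristem average exactly by construction.

## Parameter identification

Literature bounds, converted from per-minute: β ∈ [1.44e3, 7.2e4] nM/day
per equation, Km ∈ [10, 10³] nM, dc ∈ [1.44, 144] day⁻¹; triggers
positive and unbounded above. γ and Koff are fixed, not fitted. The
packaged reference set itself sits outside these ranges at a few entries
(β of SHP a factor 3.5 below the lower bound; dc of AG above; two Km just
above) — exactly the exceptions the identification literature range
analysis flags — so recovery fits use `ParameterBounds.widen_to_include`,
which expands a class range minimally to contain the reference values and
flags the widened classes.

Decoupling: since no parameter appears in two equations, each gene is fit
separately. The other five genes (values and derivatives — derivatives
enter through the mass-matrix coupling row) are piecewise-linear
interpolations of the daily data with forward-difference slopes,
right-continuous at the knots. The target equation is integrated per
whorl from the day-0 data point; residuals are model − data over days
1–5 × 4 whorls in linear concentration space, unweighted (day-0 points
serve as initial conditions and are excluded; off-state points enter
unweighted). All four whorls are integrated as one 4-component system per
evaluation. Optimizer: scipy `least_squares` (trust-region reflective)
with box bounds and `x_scale='jac'`.

Initialization (the package's own design): Km slots start at the typical
concentration of their governing dimer signal — at A = Km the MM fraction
has its maximal parameter sensitivity 1/(4Km) — computed from the day-2+
data on-levels via the QSS product; decay at the geometric mid-range; β
on the steady-state balance β ≈ dc·x_on split over activator slots. On
top of that, blind fits use a derivative-collocation ("gradient
matching") pre-fit — matching the decoupled right-hand side to the data's
forward-difference slopes at interval midpoints, an ODE-free regression —
plus a deterministic sweep over log-spaced decay rates and optional
seeded ×/÷-factor multistarts, keeping the best objective.

Identifiability, measured on noiseless synthetic data from the reference
set (daily sampling, 4 whorls): the decoupled objective is multimodal,
with distinct basins corresponding to latching vs non-latching solutions
of the positive-feedback equations. From the identified minimum, a single
deterministic refinement run recouples to the data within |ε| ≤ 0.104 on
every expressed gene/whorl (9 of 13 pairs ≤ 0.05) and preserves all four
organ calls; the residual ~10% bias on AP1/AG traces to the forward-Euler
interpolation of the trigger-day transient at daily sampling. Adding
multistarts lowers the *decoupled* objective further but can degrade the
*recoupled* fidelity — the surrogate is biased, and its global minimum is
not the best recoupled model — so multistart results should be read with
that caveat. Fully blind identification recovers the organ calls
reliably, and the trajectories of the non-latching genes well, but does
not reliably find the AP3/PI latching basin. ε here is the signed mean
relative error (sim − data)/data averaged over days 1–5, per gene and
whorl — deliberately not squared, so systematic over/underestimation
keeps its sign.

## Calibrated choices

Four quantities are not fixed by the available sources and are packaged
as explicit, documented calibrations:

1. **γ→dimer assignment.** The affinity-ratio *values* {1, 0.1, 0.1,
   0.01, 0.01, 5e-3, 5e-3} nM⁻¹ are literature-derived, but their
   assignment to the seven dimers is not recoverable. The package fixes
   it by exhaustive search (630 distinct assignments) against the
   reference kinetics: exactly three reproduce the wild-type day-5
   pattern, and one also reproduces all five literature mutants and all
   seven dimer-removal phenotypes — γ([AG AG]) = 1,
   γ([AG SEP]) = γ([SEP SEP]) = 0.1, γ([AP3 PI]) = γ([SHP SEP]) = 0.01,
   γ([AP1 SEP]) = γ([AP1 AP1]) = 5e-3. Mechanistically the ranking is
   forced: only a strong [AG AG] can repress AP1 in whorls 3–4 given its
   repression constant, and a strong [AP3 PI] would self-ignite the B
   latch in whorl 1 from basal [AP1 SEP] activation. The assignment is
   explicit in every run manifest.
2. **β/Km slot order for AP3 and PI.** The identified (β, Km) pairs
   attach to activator slots; for AP3/PI the large-β slot must be the
   autoregulatory [AP3 PI] (the latch), not [AP1 SEP] — otherwise AP3
   switches on in whorl 1 for every admissible γ. Other genes keep the
   wiring-table order.
3. **Organ-call threshold.** A gene is "on" in a whorl if its day-5
   total concentration exceeds max(100 nM, 0.1 × its wild-type
   cross-whorl day-5 maximum). The per-gene relative form reflects how
   expression states are read off fitted trajectories (AP1's off-state in
   stamens/carpels sits only a factor ~10 below its own on-level, far
   above any absolute floor); the floor handles genes that never come
   on. B function requires both AP3 and PI on (obligate heterodimer);
   labels come from the exact (A, B, C, E) pattern — sepal A·E, petal
   A·B·E, stamen B·C·E, carpel C·E — with D only annotating ovule
   competence inside the carpel programme; any other pattern, including
   any E-less state, is "no floral organ".
4. **Ectopic level.** Ectopic expression pins a gene at 10⁴ nM in all
   whorls — at the autoactivated plateau of the B genes, which a 10³ nM
   pin would fail to engage (the [AP3 PI] latch would not hold and the
   known ectopic-AP3 phenotype would not be reproduced).

## Mutant experiments

Knockout: zero initial concentration and structurally zero production
(trigger included). Ectopic: the gene's row of the mass-matrix system is
replaced by ẋ = 0 with the concentration pinned. Dimer removal: one γ set
to zero. All experiments run on the reduced model, all four whorls, days
0–5, and are classified against wild-type-referenced thresholds. A
"double organ conversion" is exactly two whorls changing to another organ
label (not "none"). [SHP SEP] removal cannot change a four-label call
(SHP regulates nothing); the screen reports D-function loss when the
carpel call persists while SHP's dimer-bound day-5 level falls below
threshold — a surrogate for "carpels without ovules" in a model without
ovule-level resolution.

## Affinity robustness

Two readings are computed. (a) *Frozen parameters*: each γ is scaled by
2 and by 1/2 and the wild type re-simulated; 9 of 14 perturbations
preserve all four organ calls, and the five failures ([AG AG] and
[AP1 AP1] both directions, [AP1 SEP] halved) are genuine attractor
changes of the A–C toggle, which sits within a factor two of its
bifurcation under the reference kinetics — no assignment of the affinity
multiset does better. (b) *Re-identification* (local tracking): the γ is
scaled, the six equations are re-fitted from the reference minimum on the
synthetic data, and the re-fitted model is re-simulated; deterministic
tracking preserves 10 of 14, failing where the re-fitted data (inverted
under the perturbed γ) are inconsistent with any parameterization of the
perturbed model near the toggle margin. A continuation initializer that
rescales the perturbed dimer's Km slots by the same factor (exactly
preserving every MM fraction) is available but not deterministically
better.

## Synthetic data

The generator emulates the documented shape of the original expression
series: daily samples over days 0–5, four whorls, six genes, totals with
on-levels near 10³ nM and off-levels at 1%, volume-weighted meristem
averages with weights (1.1, 2.7, 2.9, 1.1)/7.8. Day-0 convention: AP1
(induced at time 0) and the ever-present SEP at the on-level, the rest at
the 1% off-level, uniform across whorls. Noise is multiplicative
log-normal (default σ = 0.05; concentrations are positive and span two
decades, so additive noise would be ill-posed), fully seeded. What
passing tests show: the pipeline's algebra and dynamics are
self-consistent and the qualitative biology is reproduced from known
ground truth. What they do not show: robustness to real microarray noise
structure (probe effects, normalization artifacts), to mis-specified
wiring, or to the 1%-off-level convention being wrong — the generator
shares those conventions with the transformation it tests.

## Numerical choices

- Integrator: LSODA (automatic stiff/non-stiff switching), rtol 1e-6,
  atol 1e-3 nM, integration restarted at the trigger-window edges so the
  discontinuity never sits inside a step. The full model at Koff = 1440
  day⁻¹ (rate coefficients up to ~10⁷/day at γ = 1) is integrated the
  same way; an explicit RK pair would need ~10⁷ steps there.
- Outputs are clipped at zero for reporting; internal rate evaluations
  clamp small solver-induced negatives.
- Simulation horizon: days 0–5 (the data window); persistence is checked
  by advancing the day-5 state to day 8 — drifts stay below 30% (the
  dimer buffering in M stretches the slowest relaxation, the SEP loop, to
  M₆₆/dc₆ ≈ 7 days) and the organ calls are unchanged.
- Decoupled-fit integration: LSODA at rtol 1e-7, piecewise over the day
  knots (which include the trigger edges).

## Known limitations

- The A–C toggle's factor-two fragility (above) is a property of the
  reference kinetics, not of the implementation; conclusions about dimer
  perturbations between a factor ~2 and the full knockout are not
  supported.
- Off-state trajectories (the 1% regime) carry large relative errors
  through the whole pipeline, as expected for values set by convention
  rather than measurement; analyses should not lean on them.
- Whorl volumes are time-constant and day-0/1 concentrations are a
  convention; both are stamped into generated datasets but are not
  estimates.
- No quartet (tetramer) complexes, no AG-dependent meristem termination,
  no spatial resolution below the whorl.
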