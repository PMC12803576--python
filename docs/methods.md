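# Methods

## Scope and model structure

`myokin` implements a desk-scale kinetic model of cardiomyocyte energy
metabolism intended for proteomics-based personalization and
substrate-preference analysis. Whole-heart kinetic models of this kind
resolve hundreds of reactions; this package deliberately reduces each
canonical step group to one lumped reaction so the network stays small
enough to analyse, while keeping every mechanism the analyses depend on:
substrate competition between fatty acids (FA), glucose, lactate/pyruvate,
ketone bodies and branched-chain amino acids (BCAA); insulin-dependent
glucose uptake; the carnitine shuttle; and mitochondrial electrophysiology.

The network has 32 reactions over 29 states in four compartments
(extracellular, cytosol, mitochondrial matrix, intermembrane space; the
intermembrane space carries no state pools — its proton concentration is
clamped and it exists to define the inner-membrane potential ΔΨ).
Concentrations are mmol per litre of compartment water; fluxes are mmol per
litre cell per hour, so the ODE right-hand side is `dC_i/dt = (N v)_i /
vol_i` with volume fractions cytosol 0.70, matrix 0.28, intermembrane 0.02.
`dΔΨ/dt` is the net charge flux across the inner membrane divided by a
capacitance parameter (10⁻³ mmol charge L⁻¹ mV⁻¹).

Nine conserved moieties are declared (adenine nucleotides per compartment,
NAD(H) per compartment, FAD(H₂), CoA per compartment, carnitine per
compartment). Every moiety lives in a single compartment — the
ANT and the carnitine translocase are antiporters, so each side's total is
separately conserved — which makes the totals exact invariants of the ODE in
concentration units and lets "total mitochondrial carnitine" be a clean,
physically meaningful knob (default 3.0 mmol/L of matrix volume, the
physiological value). Model validation checks that every declared moiety
vector lies in the left null space of the stoichiometric matrix and that
each reaction balances substrate-skeleton carbon (CO₂ is an explicit
boundary product) and transferable phosphate (against a clamped inorganic
phosphate pool, recorded per reaction as `pi_release`).

### Rate laws

* `reversible_mm` — generalised reversible Michaelis–Menten,
  `v = vmax (Πa − Πb/K̂) / (Π(1+a) + Π(1+b) − 1)` with `a=S/Km`, `b=P/Km`
  and `K̂` chosen so the net rate is zero exactly at mass-action ratio =
  Keq (Haldane consistency). Used for transporters, LDH and adenylate
  kinase. The law is first-order in each listed species irrespective of its
  stoichiometric multiplicity (a deliberate simplification for the lumps;
  the adenylate-kinase equilibrium is therefore AMP ∝ ADP/ATP rather than
  ADP²/ATP — monotone in the same direction, which is what the AMP signal
  is for).
* `hill_allosteric` — irreversible multiplicative saturation kinetics with
  optional Hill exponents, allosteric activator/inhibitor factors, and for
  the respiratory complexes and ATP synthase a sigmoid membrane-potential
  gate (complexes inhibited above ~185 mV, synthase activated above ~150
  mV). These gates stand in for thermodynamic back-pressure; they keep every
  rate proportional to its capacity parameter, which gives the model exact
  scaling equivariance (all capacities ×λ ⇒ same steady concentrations,
  fluxes ×λ).
* `ghk_ion_flux` — Goldman–Hodgkin–Katz electrodiffusion for K⁺ and the
  proton leak; the permeability plays the role of vmax. Below
  |zFV/RT| < 10⁻⁴ the flux switches to its first-order expansion
  `P[(c_in − c_out) + u(c_in + c_out)/2]`, continuous and differentiable at
  V = 0.
* `atp_load` — the generic hyperbolic ATP demand
  `v = k_load·ATP/(ATP + Km)`, Km 0.5 mmol/L.
* `antiporter` — 1:1 exchange with saturable sites on both faces; the
  ADP/ATP carrier (ANT) is electrogenic (one net charge per exchange), so
  its equilibrium constant carries a factor `exp(FΔΨ/RT)`, which is what
  pushes ATP out of the matrix against the cytosolic phosphorylation
  potential.

### Oxidative phosphorylation stoichiometry

Charge stoichiometry encodes a P/O ratio of 2.5 ATP/NADH and 1.5 ATP/FADH₂:
NADH oxidation pumps 10 charges, FADH₂ 6; the synthase consumes 3 per ATP
and the ANT 1 per exported ATP. The proton leak and the K⁺
uniporter/K⁺–H⁺-exchanger cycle dissipate a few percent of the pumped
charge, so realised ATP/O₂ at maximal workload is ≈4.5, below the
stoichiometric ceiling of 5 mol ATP per mol O₂.

### Regulation

Insulin multiplies the GLUT4 capacity by `ins/(ins + K)` (K = 50 arbitrary
units; ~0.44 at fasting insulin, ~0.8 postprandially). Catecholamines
multiply a configured reaction subset (default: the glycolytic lump) by a
saturating phosphorylation factor. Two metabolite signals couple the fat
and glucose limbs (the glucose–fatty acid cycle): cytosolic long-chain
acyl-CoA inhibits hexokinase, and the ATP/AMP state controls the
phosphofructokinase step (Hill-4 ATP inhibition, AMP activation). These are
the channels through which raising FA availability or the cytosolic ATP
level (e.g. by enhancing ANT) suppresses glucose uptake.

### Design choices worth recording

* **Fatty-acid entry.** Uptake is split between CD36-facilitated transport
  and a passive flip-flop diffusion term with no mapped protein. A
  substantial passive component is physiologically documented, and it is
  also what distributes control correctly at this network size: a reduced
  model has one reaction where the full-scale model has dozens, so any
  single protein-mapped reaction that rigidly set FA supply would dominate
  the ±10% control screen in a way no individual enzyme does at full scale.
  For the same reason hexokinase ships as its two isoforms (HK1/HK2) and
  acyl-CoA synthetase as two isoform reactions (ACSL1/ACSL3).
* **Free cytosolic ADP** rests near 0.9 mmol/L, higher than
  creatine-kinase-buffered estimates; the model has no creatine system (out
  of scope), and the elevated free ADP is what lets adenine-pool signals
  propagate. Interpret absolute cytosolic ADP/AMP with that in mind.
* **Ion scope.** Only mitochondrial electrophysiology is dynamic;
  sarcolemmal Na⁺/K⁺/Ca²⁺ handling is clamped (plasma Na⁺/Ca²⁺ fields exist
  for completeness but have no mechanistic effect). Plasma acetoacetate is
  lumped into the β-hydroxybutyrate pool at uptake.

## Calibration of the reference heart

The paper-style workflow fits reference capacities to non-failing-heart
data; no such dataset ships here, so the reference vmax vector was
calibrated against physiologic targets declared in the model file: resting
ATP turnover ~1.9 mol L⁻¹ h⁻¹ (≈30 mmol/L/min, textbook resting human
myocardium), ΔΨ within 150–200 mV, an overnight-fasting resting partition
with FA dominant (~75%), glucose ~20%, marginal lactate/ketones, BCAA < 1%,
and ATP/O₂ ≤ 5. Calibration was structured manual fitting (balance each
lump's capacity against its target flux and saturation regime, then adjust
the competition couplings); with ~30 capacities and strong mechanistic
constraints this converges quickly and transparently, and a black-box
optimiser was not needed. The fitted vector ships in
`src/myokin/data/reference_model.yaml`; the fasting steady state is frozen
there as the initial state, so cold solves start already converged.

## Simulation protocols

* **Resting state** — stiff BDF integration (rtol 10⁻⁸, atol 10⁻¹⁰) in
  chunks until `max |dC/dt|/(|C|+atol) < 10⁻⁶`, then a Newton polish in
  reduced coordinates: one dependent pool per moiety is eliminated, so the
  root problem is non-singular and the solution cannot drift off the moiety
  manifold. Negative excursions are clamped to zero when evaluating rates.
  A warm start that already satisfies the tolerance is returned unchanged
  (this also makes the control coefficient of a disconnected reaction
  exactly zero). Non-convergence raises an error carrying the residual
  trace; a rising residual is flagged as oscillatory divergence.
* **Workload ramp** — `k_load` is multiplied by 1.25 per step from the
  resting demand (2000 mmol ATP L⁻¹ h⁻¹), each steady state warm-started
  from the previous; the ramp stops when the relative production increase
  falls below 10⁻³ (or a step fails, in which case the last stable step is
  taken and flagged). Demand beyond capacity slightly *reduces* production
  (the load saturates while cytosolic ATP falls), so a declining step is
  recorded in the diagnostics as overdrive and excluded from the ramp
  trace; capacity is the converged maximum.
* **Readouts** — ATP production is the summed flux of net-ATP-producing
  reactions; O₂ consumption follows the O₂ stoichiometry of the respiratory
  complexes (½ O₂ per NADH/FADH₂). Substrate partition weights each class's
  *uptake* flux by its full-oxidation ATP-equivalent yield; yields are
  derived from the model's own stoichiometry along configured routes
  (glucose 32, palmitate 106, lactate 15, β-hydroxybutyrate 22.5, BCAA 26.5
  ATP per mole at P/O 2.5/1.5 — e.g. palmitate: −2 activation + 7×(2.5+1.5)
  β-oxidation + 8×10 acetyl-CoA = 106). Net-released substrates contribute
  zero. Partition levels below the resting workload are reported as the
  resting partition (the heart cannot run below resting demand). FA/Glc is
  the ratio of FA to glucose ATP equivalents; a zero glucose share returns
  +∞ with the ratio flagged.

## Control analysis

Coefficients are log-log finite differences:
`c = ln(ratio_perturbed/ratio_base)/|ln(1 ± δ)|`, δ = 0.10 by default, both
directions, warm-started from the baseline resting state. The sign
convention is "positive = this perturbation raises FA/Glc", so in the `+`
direction `c` is the classical scaled control coefficient (the toy-chain
summation theorem, Σc = 1 ± 0.02, is tested in that form). Non-convergent
perturbations are recorded as missing, never zero; a reaction needs finite
coefficients in ≥70% of patients to be ranked. Ranking is by absolute mean
over patients per direction, ties broken by reaction id, and covers
protein-mapped reactions only by default — the screen looks for protein
targets, and the ATP load or a passive leak is not one (pass
`include_unmapped=True` to screen them too).

Sweeps re-solve the resting state over a grid: plasma FA 0.3–1.0 mmol/L
(monotone non-decreasing FA/Glc expected and soft-checked), and total
mitochondrial carnitine (the moiety total is reset and member pools rescaled
proportionally; the saturation point is the first grid value whose forward
relative difference drops below 1% per mmol/L).

## Synthetic cohorts

The generator emulates exactly the statistical structure the pipeline
consumes, not any real dataset: log-normal intensities with
protein-specific log-means (log-sd 0.25), cell-wise missingness (8%),
planted haemoglobin/collagen QC violations (10% of samples), and
multiplicative heart-failure effects drawn per patient and protein
(β-oxidation-pathway proteins ×0.6, glycolysis-pathway ×1.3 on the log
scale with sd 0.1/0.08 — fixture conventions chosen once to reproduce the
reported direction of the failing-heart shift, FA→Glc, not its magnitude).
Outcome tables couple ΔLVEF linearly to resting FA/Glc (slope 10 percentage
points per ratio unit, noise sd 2) and the relative LVEDd reduction
analogously (slope 0.09, noise 0.025), clipped to physiologic bounds; all
draws are seeded and unseeded generation is refused.

What passing tests on these cohorts shows: that the pipeline recovers
planted effects through QC, imputation, personalization and simulation, and
that its statistics behave (null cohorts give chance-level AUCs). What it
does not show: anything about real LC-MS artefacts (batch effects,
peptide-level noise, match-between-runs), real effect sizes, or real
outcome distributions.

## Personalization details

Sample QC keeps samples with **strictly** <5% haemoglobin and <5% collagen
fraction; the valid-value filter keeps protein groups with **strictly**
more than 70% valid values over all samples (both filters idempotent).
`E_subject` sums intensities over a reaction's mapped protein groups —
summation, not averaged ratios, because summed intensity approximates total
catalytic capacity across isoforms/subunits. Missing values fall through a
two-tier imputation: the sample's cohort-group mean for that protein, else
(protein absent in the whole cohort) the control-reference value, i.e.
assumed unchanged from controls; the tier is logged per reaction
(`measured` / `group_average` / `control_default`) so either path can be
audited. Reactions with no mapped protein keep scale exactly 1. A zero
control reference for a mapped protein is a configuration error (the
valid-value filter should have removed it).

## Outcome pipeline

Endpoints use the printed inclusive thresholds: functional response
ΔLVEF ≥ 10 percentage points, optimal unloading relative LVEDd reduction
≥ 15%. Published three-tier reverse-remodelling staging criteria are not
reproduced here; staging is a configurable rule object whose shipped
default is a documented LVEF-change rule (responder ≥ 10, partial ≥ 5),
and swapping rules changes labels only. Statistics are standard library
calls behind thin wrappers: Pearson r with Fisher-z CI, AUC by the
tie-averaged rank method with a seeded percentile bootstrap (2000
replicates), Kolmogorov–Smirnov-gated t / Mann–Whitney group comparison,
standardized-beta multiple regression (reported as absolute values), and
PCA with explained-variance output.

## Numerical notes and limitations

* The steady-state problem is solved to residual 10⁻⁶ h⁻¹ relative; the
  Newton polish typically lands near machine precision. Everything is
  deterministic: identical inputs give bit-identical profiles.
* Problem sizes in the shipped tests (cohorts of 20+20 over three seeds for
  parameter recovery, 100+100 for the outcome chain, ±10% screens over ~26
  mapped reactions) were chosen as the smallest sizes at which the
  qualitative claims are stable across seeds.
* The model is a reduction: absolute fluxes and pool sizes are calibrated,
  not measured; per-patient numbers should be read comparatively (patient
  vs. control, scenario vs. scenario), which is how the analyses use them.
* Ketone and lactate shares at rest are small and their workload trends are
  only qualitatively right (lactate's share grows with workload; the ketone
  share shrinks slightly, where a finer model shows a mild rise).
* Transient (non-steady-state) physiology — ischaemia/reperfusion,
  beat-to-beat dynamics, the creatine-kinase shuttle, calcium signalling —
  is out of scope.
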