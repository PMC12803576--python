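# myokin

Personalised kinetic modelling of myocardial energy metabolism from cardiac
proteomics.

Advanced heart failure reshapes how the heart fuels itself: ATP production
capacity falls and substrate preference shifts from fatty acids (FA) toward
glucose (Glc). `myokin` is for researchers who want to turn a label-free
proteomics profile of a left-ventricular biopsy into a patient-specific,
simulatable model of cardiomyocyte energy production — and to ask what that
model predicts about bioenergetic phenotype, clinical response to mechanical
unloading (LVAD), and candidate metabolic drug targets.

## The model

The core is a reduced kinetic network of cardiac energy metabolism: 32
lumped reactions over 29 state variables in four compartments
(extracellular, cytosol, mitochondrial matrix, intermembrane space). It
covers glucose uptake (GLUT1/insulin-dependent GLUT4), glycolysis with an
ATP-inhibited / AMP-activated phosphofructokinase step, lactate/pyruvate
exchange and oxidation, fatty-acid uptake (CD36 + passive flip-flop),
activation and the explicit carnitine shuttle (CPT1, translocase, CPT2),
β-oxidation, ketolysis, branched-chain amino-acid (BCAA) oxidation, the TCA
cycle, and oxidative phosphorylation with the mitochondrial membrane
potential ΔΨ as a state variable (respiratory complexes pump charge; the
ATP synthase, adenine-nucleotide translocator, K⁺ uniporter and proton leak
consume it; ion fluxes follow the Goldman–Hodgkin–Katz equation). Conserved
moieties — adenine nucleotides, NAD(H), FAD(H₂), CoA and carnitine pools per
compartment — are declared and validated against the stoichiometry.

Personalization scales each reaction's capacity by proteomics:

    Vmax_subject = Vmax_reference · E_subject / E_control

with `E` the summed intensity of the protein groups mapped to the reaction
and `E_control` the mean over non-failing control samples. ATP demand is a
hyperbolic load `v_ATP = k_load · ATP/(ATP + Km)`; raising `k_load` stepwise
until ATP production converges yields the maximal ATP production capacity,
the reserve (capacity − resting rate), peak O₂ consumption, ATP/O₂, the
substrate partition in ATP equivalents, and the FA/Glc utilisation ratio —
the substrate-preference statistic used for outcome association and for the
±10% perturbation screen (metabolic control analysis) over all
protein-mapped reactions.

## Worked example

```python
from myokin import MyocardialEnergetics

model = MyocardialEnergetics.reference("fasting")   # control-average heart
res = model.fit()
print(res.summary())
```

```
      Myocardial Energetics Results
==============================================
patient:             reference
scenario:            fasting
converged:           True
----------------------------------------------
resting ATP rate         1890.9 mmol/L/h
max ATP capacity         2523.2 mmol/L/h
ATP reserve               632.3 mmol/L/h
peak O2 rate              554.9 mmol/L/h
ATP per O2                 4.55 mol/mol
membrane potential        196.6 mV
FA/Glc (rest)              3.53
FA/Glc (max)               2.86
----------------------------------------------
substrate partition at rest:
  fatty_acids         74.68 %
  glucose             21.17 %
  lactate_pyruvate     0.00 %
  ketones              3.52 %
  bcaa                 0.63 %
```

Reading this: at overnight-fasting substrate levels (free fatty acids
0.5 mmol/L) the control-calibrated heart turns over ~1.9 mol ATP per litre
cell per hour at rest and can raise production ~33% before supply saturates;
fat provides three quarters of resting ATP, amino acids less than 1%, and
the membrane potential sits in the physiologic 150–200 mV band. A
personalized model (`MyocardialEnergetics.from_proteomics(matrix, "H012")`)
prints the same table for one patient; failing hearts typically show a lower
capacity and a lower resting FA/Glc ratio.

Follow-up analyses hang off the results object: `res.control_screen()`
ranks reactions by the absolute mean control coefficient of resting FA/Glc
(in the shipped calibration, inhibiting insulin-dependent glucose uptake and
enhancing the ADP/ATP carrier are the top two ways to raise it);
`res.sweep_fa()` and `res.sweep_carnitine()` trace FA/Glc against plasma FA
concentration and total mitochondrial carnitine (saturating above the
3.0 mmol/L physiological default).

The same pipeline is scriptable from the shell:

```bash
myokin synth --seed 7 --out cohort/          # synthetic proteomics cohort
myokin cohort --proteomics cohort/           # QC -> personalize -> features
myokin rank-targets --proteomics cohort/     # +-10% control screen
myokin sweep fa                              # FA availability sweep
myokin associate --proteomics cohort/ --seed 7   # LVAD outcome association
```

Synthetic cohorts (`myokin.cohort`) emulate log-normal label-free
intensities with missing values, pathway-structured heart-failure effects,
planted QC contamination, and LVAD outcome tables (ΔLVEF, ΔLVEDd) coupled to
the resting FA/Glc ratio, so the full analysis is testable without any
patient data.

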