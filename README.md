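# ventriflow

Functional flow-component separation and kinetic energy of intracardiac
4D flow MRI.

Time-resolved three-directional phase-contrast MRI ("4D flow") measures the
velocity of blood everywhere in the left ventricle (LV) over the cardiac
cycle. By seeding one pathline in every voxel of the end-diastolic (ED)
segmentation and integrating it forward to end-systole (ES) and backward to
the previous ES, the ED blood volume (LVEDV) separates into four functional
components according to each parcel's transit through the chamber:

| component | definition over one cycle |
|---|---|
| direct flow (DF) | enters the LV **and** is ejected |
| retained inflow (RI) | enters but is not ejected |
| delayed ejection flow (DEF) | already in the LV at cycle start, ejected |
| residual volume (RV) | neither enters nor leaves |

The non-ejecting volume is NE = RI + RV. "Entering" and "being ejected" are
decided by trajectory crossings of the basal plane through its mitral
(inlet) and aortic (outlet) regions. Component volumes are expressed as
proportions of the LVEDV (DF/LVEDV, NE/LVEDV volume ratios). Each pathline
represents one voxel of blood, so its kinetic energy is

    KE(t) = 1/2 · ρ_blood · V_pathline · |v_pathline(t)|²,   ρ_blood = 1060 kg/m³

and the ED snapshot yields DF/LVEDV and NE/LVEDV **KE ratios** (component KE
at ED over total LVEDV KE at ED). Conservation quality control compares
pathline-derived inflow (DF + RI) with outflow (DF + DEF) and fails a dataset
when the symmetric relative difference exceeds 10 %.

A cohort statistics stage indexes LV volumes to body surface area
(Mosteller, BSA = √(height·weight/3600)), correlates the 4D-flow ratios with
LVEDVI/LVESVI/LVEF (Pearson), compares groups (t-test or Mann–Whitney U via
a Shapiro–Wilk gate, paired t-test for inflow vs outflow), and stratifies
patients by LVEDVI (cutoff 74 ml/m²) or LGE status for one-way ANOVA with
Tukey HSD post-hoc tests.

The package targets researchers quantifying early or subtle LV dysfunction:
falling DF volume/KE ratios and rising NE ratios with increasing LV volume
indices are the markers of interest.

## Worked example

Generate a straight-channel phantom whose component fractions are known in
closed form, then analyze it:

```bash
$ ventriflow phantom --kind plug --out plug_study
wrote plug-flow study to plug_study (truth.json included)

$ ventriflow analyze plug_study --out plug_results
LVEDV 5.6 ml | DF 0.600 RI 0.200 DEF 0.200 RV 0.000 NE 0.200 | inflow 4.5 ml outflow 4.5 ml
QC pass (discrepancy 0.000)
```

The default channel (100 mm long, plug speed 80 mm/s, 1 s horizons in each
direction) lets blood advance 80 mm per half-cycle: the 60 mm overlap of the
entered and ejected intervals is direct flow (DF ratio 0.600), the 20 mm
nearest the inlet entered without being ejected (RI 0.200), the 20 mm nearest
the outlet is ejected old blood (DEF 0.200), and nothing is stagnant.
`plug_study/truth.json` holds the same fractions from the closed form.

The same pipeline runs on the smooth ellipsoidal-chamber phantom (diastolic
inflow jet, systolic outflow jet, intraventricular swirl) or on any study
directory in the documented NIfTI + JSON layout:

```python
from ventriflow import phantom, analyze_study

study = phantom.make_chamber_phantom()
a = analyze_study(study)
print(a.result.df_ratio, a.result.ne_ratio, a.ke_ratios["df_ke_ratio"])
# 0.284 0.610 0.565
print(a.result.inflow_ml, a.result.outflow_ml, a.qc.passed)
# 57.7 55.5 True
```

Cohort tables (CSV/XLSX, with an optional schema map binding file columns to
the canonical names) feed the statistics stage:

```bash
ventriflow phantom --kind cohort --seed 1 --out cohort.csv
ventriflow cohort cohort.csv --out report
```

which writes the correlation table, both subgroup analyses and the paired
inflow/outflow test as CSV/JSON.

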