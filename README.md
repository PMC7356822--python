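# synthmri

Simulation and validation tools for **synthetic MRI relaxometry**.

Synthetic MRI estimates quantitative proton density (PD), T1 and T2 at
every voxel from a single multi-echo/multi-delay scan and then
*resynthesizes* any weighted contrast (T1w, T2w, FLAIR) by plugging a
chosen TR/TE/TI into the spin-echo signal equations

    S_IR(TI)  = PD · |1 − 2·e^(−TI/T1) + e^(−TR/T1)| · e^(−TE/T2)
    S_SE(TE)  = PD · (1 − e^(−TR/T1)) · e^(−TE/T2)

The accuracy of those synthesized contrasts stands or falls with the
accuracy of the fitted relaxation times. This package implements the
phantom-based validation of that chain for researchers in quantitative
MRI: CuSO₄ tube phantoms whose T1/T2 follow a relaxivity law
(1/T = 1/T_solvent + r·C), brain-like digital phantoms
(WM/GM/CSF/thalamus/stroke lesion), simulated magnitude acquisitions
with Rician noise, inversion-recovery T1 and multi-echo T2 fitting by
nonlinear least squares, and the comparison statistics: percent
difference against conventional spin-echo references, Friedman tests of
interday/intersession repeatability with Bonferroni correction, and the
thalamus-standardized contrast-to-noise ratio

    CNR = (mean(region) − mean(thalamus)) / sd(thalamus).

A reference table of per-concentration conventional and synthetic-scan
relaxation values (two days × seven sessions) ships with the package
and drives both the table-level validation and the empirical bias model
that makes simulated "synthetic scans" misestimate long relaxation
times the way real ones do.

## Worked example

Validate the synthetic-scan relaxation values in the packaged reference
table against their conventional references:

```python
from synthmri import build_validation_report, load_phantom_reference_table

report = build_validation_report(load_phantom_reference_table())
row = report.table.set_index(["quantity", "concentration_mM"])
print(row.loc[("T1", 0.2), ["reference_ms", "synthetic_ms", "percent_difference"]])
```

```
reference_ms          2117.200000
synthetic_ms          2642.214286
percent_difference      24.797576
Name: (T1, 0.2), dtype: float64
```

At the lowest CuSO₄ concentration (longest T1, the CSF-like regime) the
synthetic scan overestimates T1 by ~25%, while `report.summary` shows
every T2 row between 11 and 20 mM (short, tissue-like T2) within 10% —
synthetic relaxometry is accurate in the parenchymal range and drifts
in the fluid range. `report.table["interday_p_bonferroni"].min()` is
0.114: no concentration shows a significant day-1 vs day-2 difference
after Bonferroni correction, i.e. the synthetic values are repeatable
even where they are biased.

The same asymmetry appears in image contrast. An 18-subject simulated
cohort, imaged with true tissue values ("clinical" mode) and with the
phantom-calibrated bias applied to CSF ("synthetic" mode):

```python
from synthmri.cnr_analysis import compare_modes, simulate_cnr_cohort

report = compare_modes(simulate_cnr_cohort(n_subjects=18, seed=1))
print(report.tests[report.tests.significant][["region", "contrast", "p_bonferroni"]])
```

```
  region  contrast  p_bonferroni
1    CSF  T2-FLAIR      0.000265
2    CSF       T2w      0.000265
```

Only CSF on T2-weighted and FLAIR images differs significantly between
modes; WM, GM and the stroke lesion do not — the CSF relaxometry error
does not disturb lesion contrast.

## Command line

```sh
synthmri simulate-phantom --out phantom      # quantitative maps, NIfTI
synthmri simulate-brain --out brain
synthmri synthesize --maps brain --tr 4545 --te 110 --out t2w.nii
synthmri validate --seed 1 --out results/phantom
synthmri cnr --seed 1 --out results/brain --subjects 18
synthmri run-all --seed 1 --out results
```

Each run writes CSV/JSON reports plus a provenance record (config hash,
seed, version) sufficient to reproduce it byte-identically.

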