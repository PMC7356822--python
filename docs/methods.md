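# Methods

## Scope and model

`synthmri` re-creates, in simulation, the workflow used to validate
synthetic MRI relaxometry against conventional spin-echo references:
quantitative PD/T1/T2 maps of known phantoms, acquisition series
simulated from closed-form signal equations, nonlinear least-squares
T1/T2 estimation, resynthesis of weighted contrasts, and the comparison
statistics (percent difference, Friedman repeatability, standardized
CNR).

All signal physics is mono-exponential spin-echo theory:

* Inversion-recovery spin echo, perfect inversion:
  `S(TI) = A (1 - 2 e^{-TI/T1} + e^{-TR/T1})`, returned as magnitude.
  Inversion efficiency, B1/B0 inhomogeneity, slice profiles and
  stimulated echoes are not modelled; each contrast is characterized by
  effective TR/TE/TI only.
* Transverse decay `S(TE) = S0 e^{-TE/T2}` (single compartment).
* Weighted-contrast synthesis composes the two per voxel; sequences
  without an inversion pulse use the saturation-recovery form
  `PD (1 - e^{-TR/T1}) e^{-TE/T2}`.

The vendor reconstruction that produces real synthetic scans is not
public; these standard forms are a documented stand-in, and the
*systematic* error of synthetic relaxometry is modelled separately (see
bias model below) rather than mechanistically.

## Reference protocols

The conventional quantification protocols are the 16-point TI series
(100–4000 ms) and the 20-echo TE series (9.9–198.4 ms), both at
TR = 10 s; they are shipped as defaults (`TI_SERIES_MS`,
`TE_SERIES_MS`). The three weighted contrasts used throughout are
T1w (TR 1800 / TE 23 / TI 750 ms), T2w (TR 4545 / TE 110 ms) and
T2-FLAIR (TR 9000 / TE 92 / TI 2472 ms).

## Phantoms

**Tube phantom.** Cylindrical tubes (7.1 cm² cross-section, 6 cm
height) in a saline tank on a 160 mm field of view; default grid
128×128×20 with 6 mm slice spacing (5 mm thickness + 1 mm gap), RAS+
affine, 0-based voxel indices. Tube relaxation times follow the
fast-exchange relaxivity law `1/T(C) = 1/T_solvent + r·C`. No
relaxivity constants are published for the reference data, so the
defaults are calibrated by ordinary least squares of `1/T` on
concentration over the packaged reference table (slope = r, intercept
= solvent rate). Within the calibrated range (0.2–1.0 mM for T1,
5–20 mM for T2) predictions sit within ~10% of the tabulated
references. The T2 intercept corresponds to an unphysically long
solvent T2 (~50 s); it is a calibration intercept of a line fitted over
5–20 mM, not a water property, and is never used outside the tank-fill
placeholder. Both parameters are overridable.

**Brain phantom.** Schematic, not anatomical: nested ellipsoids (CSF
shell > GM shell > WM core), two ellipsoidal ventricles and thalami,
and one spherical stroke lesion inside the WM, on a shared 192 mm FOV
grid. Default tissue values (PD a.u. / T1 ms / T2 ms): WM 0.70/830/80,
GM 0.85/1330/110, CSF 1.00/4300/2000, thalamus 0.82/1100/90, lesion
0.90/1700/160 — nominal 3T literature values. CSF T1 is deliberately
near the FLAIR null point (the null T1 for TI 2472 / TR 9000 computes
to ≈4276 ms), so CSF is suppressed on FLAIR as on a scanner. Because
geometry is schematic, passing tests demonstrate correctness of the
computation chain, not realism of anatomy, partial-volume behaviour, or
flow effects.

## Noise

Magnitude images carry Rician noise: `sqrt((S+n1)^2 + n2^2)` with iid
zero-mean Gaussians of standard deviation σ (default 0.02 a.u. against
a CSF PD of 1). Background is then Rayleigh (mean σ√(π/2), sd
σ√(2−π/2)), which the tests verify at 10⁶ voxels. Every stochastic
call takes a seed; independent volumes use child streams spawned from a
`SeedSequence`, so runs are bit-reproducible.

## Fitting

T1 and T2 fits minimize the least-squares objective by variable
projection: for a trial relaxation time the amplitude is closed-form,
so the search is one-dimensional — a 400-point logarithmic grid over
the bounds (T1 ∈ [1, 20000] ms, T2 ∈ [1, 5000] ms) followed by bounded
Brent refinement (xatol 1e-9 ms). This is deterministic, needs no
starting values, and minimizes exactly the objective a dense
grid-search oracle evaluates, which the tests exploit. Estimates at a
bound are flagged not-converged; constant or all-nonpositive series
return a not-converged result instead of raising.

Magnitude IR data are polarity-restored before fitting by default: the
flip point is the minimum-magnitude sample, and the two candidate flip
sets (excluding/including that sample) are ranked by their refined
fit residuals, ties going to the earlier index. A pure-magnitude
fitting path exists for comparison. Voxelwise fitting memoizes
identical time courses, which collapses piecewise-constant noiseless
phantoms to one fit per region.

## Bias model for synthetic scans

The reference table shows synthetic-scan relaxation values drifting
from conventional references as relaxation times grow. This is encoded
as multiplicative per-concentration factors, mean(14 synthetic
sessions)/reference, linearly interpolated against concentration (or
against reference relaxation time when applied to tissue), with
nearest-neighbour extrapolation outside the tabulated range. In the
brain experiment the bias is applied only to tissues whose T1 exceeds
2300 ms or T2 exceeds 240 ms — beyond the calibrated phantom range,
where the discrepancies are documented — which in practice selects CSF
and leaves WM/GM/thalamus/lesion untouched.

## Statistics

* Percent difference: `100 (T_syn − T_ref)/T_ref`. The
  synthetic-vs-reference comparison aggregates the 14 sessions by their
  mean (median available); this aggregation reproduces the tabulated
  bound pattern (>20% for T1 at 0.2 mM; <10% for T2 at 11–20 mM; >20%
  for T2 at 7–9 mM). The recomputed T1 differences at 0.7–1.0 mM span
  1.2–8.2% and are flagged in the report as inconsistent with the
  claimed 5–8% band.
* Friedman test: own implementation with mid-ranks and the standard tie
  correction, chi-square approximation with k−1 df (needed because the
  interday layout has k = 2, which `scipy.stats.friedmanchisquare`
  refuses); an exact permutation null is available for n ≤ 8. Fully
  tied data return statistic 0, p = 1. Interday repeatability is tested
  per concentration (k = 2 days × n = 7 sessions, Bonferroni over the
  14 rows); intersession per (quantity, day) (k = 7 sessions × n = 7
  concentration blocks). On the packaged table the interday family is
  non-significant after correction; the intersession layout *does*
  reach significance because tiny session effects are consistent across
  concentration blocks — the blocking of the original analysis is not
  specified, so both layouts are reported as-is.
* Bonferroni: `p_adj = min(1, m p)`, reject at p_adj < 0.05.
* Standardized CNR: `(mean(region) − mean(thalamus)) / sd(thalamus)`
  with sample (n−1) standard deviations; exactly invariant under
  positive affine intensity rescaling, and an error (not ±inf) on
  noiseless input.

## Simulated experiments

**Phantom validation** (`run_phantom_validation`): two 7-tube phantoms
(T1 set 0.2–1.0 mM, T2 set 5–20 mM), one reference scan plus 2 days ×
7 sessions of synthetic scans (bias applied to the maps, independent
noise per session), per-tube ROI-mean time courses fitted, and the
validation report built from the resulting table. Simulations default
to a 64×64×10 grid, which keeps the full run in seconds while leaving
dozens of voxels per tube slice; `table_only` mode skips simulation and
analyses the packaged table directly. With σ = 0 and bias off, percent
differences close to < 0.1% (pipeline self-consistency).

**Brain contrast comparison** (`run_brain_experiment`): a matched
cohort (default 18 subjects) with per-subject multiplicative tissue
jitter (sd 2%, clipped to ±20%) on shared geometry, imaged in a
clinical mode (true values) and a synthetic mode (CSF biased), three
contrasts each with independent noise. Per (region, contrast) a
Friedman test across subjects compares modes, Bonferroni-corrected over
the 12-comparison family. Under the defaults CSF is flagged on T2w and
FLAIR while WM, GM and lesion are not — the direction of the clinical
finding; magnitudes of patient-data CNRs are not reproducible from a
schematic phantom and are out of scope.

## Numerical and degenerate-input choices

* FLAIR null-T1 search: Brent root finding on [1, 10·TR]; a missing
  sign change (TR < 2·TI) raises rather than returning a bound.
* Physically implausible tissue (T2 > T1) warns but is accepted, so
  degenerate test configurations remain constructible.
* Empty protocols, empty masks, overlapping tubes, oversized lesions,
  unmatched subject sets and missing table cells raise `ValueError`
  with the offending item named.
* Report CSVs are written with fixed float formatting; identical inputs
  give byte-identical files.

## Known limitations

Single-compartment relaxometry only; no B1/inversion-efficiency
correction; schematic geometry without partial volume or flow; the
synthetic-scan bias is an empirical multiplicative model calibrated on
14 table rows, not a reconstruction simulation; the chi-square Friedman
approximation is anti-conservative for very small n (use the exact
method there).
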