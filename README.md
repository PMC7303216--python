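# eeg-microstates

Resting-state EEG microstate analysis for case–control research: the scalp
potential field of awake, resting EEG alternates between a handful of
quasi-stable topographies ("microstates", conventionally four classes
A–D), each persisting ~60–120 ms. Deviations in the temporal dynamics of
these classes — notably more of class C and less of class D — are a
candidate endophenotype in the schizophrenia spectrum. This package
implements the full analysis chain used in such studies, plus the
statistical machinery around it, for methodologists and clinical
neurophysiology groups who want a tested, scriptable reference
implementation:

1. **Preprocessing & GFP** — band-pass, downsampling, average reference;
   global field power GFP_t (per-sample population SD across electrodes)
   and its local maxima, where topographies are cleanest.
2. **Polarity-invariant modified k-means** — clustering of GFP-peak maps
   by squared spatial correlation, with the template update as the
   dominant spatial pattern (leading eigenvector) of each cluster;
   individual→group two-level aggregation; quality scored by the global
   explained variance GEV = Σ(GFP_t·corr_t)²/ΣGFP_t².
3. **Backfitting** — competitive per-sample labelling by maximal
   |spatial correlation|, Besag-style temporal smoothing
   (argmax_c corr²(t,c) + λ·N_b(t,c), defaults b = 5, λ = 10) with
   single-frame rejection, and the per-class temporal parameters: mean
   duration (ms), time coverage (%), occurrence (1/s).
4. **Group statistics** — 2×2 chi-squares, summary t-tests, Cohen's
   d / Hedges' g, η²↔d conversion, Bonferroni–Holm step-down, Pearson
   correlations, BIC Bayes factors, and a split-plot (mixed-design) Type
   III ANOVA with between-subject covariates.
5. **Random-effects meta-analysis** — REML estimation of τ², inverse
   variance pooling g* = Σw_i g_i/Σw_i with w_i = 1/(v_i + τ²), z-tests,
   joint Holm correction across parameter × class cells.
6. **Synthetic data** — a semi-Markov surrogate-EEG generator with planted
   templates, dwell times, GFP modulation and controlled SNR, so the whole
   chain is testable end to end without patient data.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from microstates import (SimulationSpec, make_templates, simulate_microstate_eeg,
    two_level_clustering, align_templates, competitive_fit, microstate_parameters,
    chi_square_2x2, gender_table)
from microstates.pipeline import extract_peak_maps

# a 5-subject synthetic cohort: 64 channels, 128 Hz, planted durations
planted = make_templates(64, 4, min_separation=0.5, seed=1)
cohort = [simulate_microstate_eeg(SimulationSpec(
    n_electrodes=64, duration=60.0, templates=planted,
    mean_durations=(60.0, 80.0, 100.0, 120.0), snr=2.0, seed=100 + s))
    for s in range(5)]

# individual -> group clustering on GFP-peak topographies
peak_maps = [extract_peak_maps(rec) for rec, _ in cohort]
group_fit, _ = two_level_clustering(peak_maps, k=4, seed=0)
templates, _, corrs = align_templates(group_fit.templates, planted)
print(f"group GEV = {group_fit.gev:.3f}; template recovery |corr| = {corrs.mean():.4f}")

# backfit one subject and compute temporal parameters
rec, truth = cohort[0]
seg = competitive_fit(rec, templates)
print(microstate_parameters(seg).round(2))

# the demographics layer
x2, df, p = chi_square_2x2(gender_table("patients", "controls"))
print(f"gender chi-square: X2({df}) = {x2:.3f}, p = {p:.3e}")
```

prints

```
group GEV = 0.999; template recovery |corr| = 0.9999
       mean_duration  coverage  occurrence  n_segments
class
0              58.43     16.26        2.78       167.0
1              75.13     21.54        2.87       172.0
2              98.37     26.89        2.73       164.0
3             121.07     35.31        2.92       175.0
gender chi-square: X2(1) = 35.762, p = 2.229e-09
```

The group templates recover the planted maps almost exactly (mean
|spatial correlation| 0.9999, GEV ≈ 1 on peak maps), and one subject's
backfitted mean durations land within a few ms of the planted
60/80/100/120 ms. Note the exact identity linking the three parameters:
occurrence × mean duration / 1000 = coverage / 100 per class. The
chi-square reproduces, from the packaged contingency table, the
gender-imbalance statistic of a published patients-vs-controls cohort.

## Command line

```bash
microstates run-all --seed 1 --out out/            # full synthetic pipeline
microstates simulate --out sim/                    # recordings + ground truth
microstates cluster sim/*_eeg.tsv --k 4 --out templates.tsv
microstates backfit sim/patients_00_eeg.tsv --templates templates.tsv --out seg.tsv
microstates params seg.tsv --out params.tsv
microstates meta --input studies.tsv --out-prefix meta
```

`run-all` writes every intermediate (recordings, ground truth, templates,
segmentations, parameter and comparison tables, meta-analysis results) and
a `manifest.json` with SHA-256 hashes; identical config + seed reproduces
identical hashes.

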