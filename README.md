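# cinedenoise

Evaluation pipeline for denoising low-SNR cardiac cine-MR volumes and
quantifying how filtering changes the measurement of left-ventricular (LV)
function.  It is aimed at small-animal imaging groups who acquire cine series
with volume coils (low SNR) and want to know whether post-hoc denoising makes
manual segmentation of cardiac-function parameters more accurate and more
reproducible — without access to the original rat acquisitions, which are
replaced here by a synthetic LV phantom with exact ground truth.

## What it computes

**Denoisers** (each applied independently to every 3D phase volume of a 4D
cine series, never across the phase axis):

- *Anisotropic diffusion* (Perona–Malik): `u ← u + dt · div(c(|∇u|) ∇u)` with
  exponential conduction `c(g) = exp(−(g/κ)²)` in flux form with zero-flux
  boundaries, so the intensity sum is conserved.
- *Total variation* (ROF): minimizes `TV(u) + ‖u − f‖²/(2λ)` by Chambolle's
  dual projection (isotropic TV).
- *Optimized Rician non-local means* (ORNLM): patch-similarity weights
  `w = exp(−d²/h²)` over an 11³ = 1331-voxel search window with 3³ patches
  (26 neighbours), averaging *squared* intensities and removing the Rician
  bias via `√(max(NLM(u²) − 2σ², 0))`, using `E[M²] = S² + 2σ²`.

**Image quality**: SNR = mean ROI intensity / raw background SD, on a
mid-ventricular short-axis slice at end-diastole; CNR = SNR(blood) −
SNR(myocardium).  The Gaussian approximation of Rician noise is flagged valid
when SNR > 4.

**Cardiac function**: from per-phase label maps (background/cavity/
myocardium), end-diastolic and end-systolic volumes (EDV, ESV, µL) at the
phases of extreme cavity volume, ejection fraction
EF = 100·(EDV − ESV)/EDV (%), and LV mass LVM = myocardial volume ×
1.05 g/cm³ (mg).

**Agreement**: paired differences (absolute, and relative to the pair
average), Pearson r, two-tailed paired t-tests with significance stars, and a
gold-standard mass comparison (percent error relative to the true mass) — the
intra-observer, inter-observer and gold-standard tables of a two-observer
variability study with simulated observers whose contour jitter scales
inversely with the measured CNR.

## Worked example

```python
from cinedenoise import desk_study_config, run_study

report = run_study(desk_study_config(master_seed=1))
print(report.quality.groupby("condition")[["snr_blood", "cnr"]].mean().round(1))
inter = report.tables.query("study == 'inter' and parameter == 'LVM'")
print(inter[["condition", "mean_rel_pct", "sd_rel_pct", "r"]].round(2).to_string(index=False))
```

prints

```
           snr_blood    cnr
condition
aniso           88.2   43.1
ornlm           52.1   26.2
raw             12.1    5.9
tv            1405.0  694.2

condition  mean_rel_pct  sd_rel_pct    r
      raw         -6.93        7.66 0.94
    aniso         -0.29        0.41 1.00
       tv          0.00        0.00 1.00
    ornlm         -0.84        0.86 1.00
```

Reading: the calibrated raw series sits at the target blood SNR of ~12 and a
CNR of ~6; every filter raises both by a large factor, so the simulated
observers' contour jitter (`c / CNR`, here ~1 voxel for raw) collapses after
filtering, and with it the inter-observer disagreement in LV mass drops from
~7% on raw images to under 1% on filtered ones.

The same pipeline is scriptable from the shell:

```bash
cinedenoise phantom --out ph.nii.gz --seg-out seg.nii.gz --noise-sigma 0.25
cinedenoise denoise --method ornlm --in ph.nii.gz --out ph_f.nii.gz --sigma auto
cinedenoise metrics --series ph_f.nii.gz --seg seg.nii.gz --out metrics.csv
cinedenoise function --seg seg.nii.gz --out function.csv
cinedenoise study run --seed 1 --out results/
```

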