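# petmrvol

Concordance of tumour volumes across imaging modalities in cervical cancer:
**MTV** (metabolic tumour volume from FDG-PET, by percent-of-SUVmax
thresholding), **FTV** (functional tumour volume from diffusion-weighted
MRI, by manual delineation or by K-means clustering of (S0, ADC) features)
and **ATV** (anatomical tumour volume from T2-weighted MRI planimetry, the
reference).  The package is aimed at imaging researchers who want a tested,
scriptable version of this analysis — including the statistics that decide
which SUV threshold best matches anatomy — plus synthetic multimodal
phantoms with analytic ground truth so every stage can be validated without
patient data.

## The models

* **ADC mapping** — per voxel, the mono-exponential diffusion model
  `S_b = S0·exp(−b·ADC)` is fitted to a multi-b-value series (log-linear
  initialisation, batched Levenberg–Marquardt refinement).
* **MTV** — inside a VOI, `MTV_t = vol{ x : SUV(x) ≥ (t/100)·SUVmax }` for
  t = 20…80% in 5% steps; superlevel-set nesting makes MTV non-increasing
  in t.
* **FTV (semi-automated)** — K-means with k = 3 on z-scored (S0, ADC) pairs;
  clusters map to fat/fibrotic, solid tumour and normal/cystic tissue by
  ADC-centroid order, and only the tumour cluster is kept.
* **Concordance** — per modality m: the paired difference of means
  `mean(ATV) − mean(m)`, the percent difference `100·diff/mean(ATV)`, a
  two-tailed paired t test, and Pearson's r.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate the default PET phantom (Gaussian hot spot, peak SUV 9.2, over a
0.6 background, with a 3×-hotter "bladder" sphere outside the VOI), sweep
the thresholds and compare against the closed-form superlevel-set volumes:

```python
from petmrvol import (PetPhantomSpec, generate_pet_phantom, mtv_sweep,
                      difference_from_means)

pet, voi, analytic = generate_pet_phantom(PetPhantomSpec(), seed=0)
sweep = mtv_sweep(pet, voi)
print(f"SUVmax = {sweep.suv_max:.1f}")
for t in (20, 30, 50, 80):
    print(f"MTV_{t}: {sweep.volumes_cm3[t]:6.1f} cm3  (closed form {analytic[t]:6.1f})")
diff, pct = difference_from_means(55.5, 58.4)
print(f"mean ATV - mean MTV_30 = {diff:.1f} cm3 ({pct:.1f}%)")
```

prints

```
SUVmax = 9.2
MTV_20:  107.2 cm3  (closed form  107.8)
MTV_30:   65.7 cm3  (closed form   64.9)
MTV_50:   27.3 cm3  (closed form   26.8)
MTV_80:    5.0 cm3  (closed form    4.7)
mean ATV - mean MTV_30 = -2.9 cm3 (-5.2%)
```

The sweep tracks the analytic volumes to within a fraction of one
surface-voxel layer, and the last line is the headline concordance
statistic: at the 30% threshold the metabolic volume overshoots the
anatomical mean by only 2.9 cm³ (5.2%).

The same workflow is available from the shell:

```bash
petmrvol phantom --seed 3 --out work/          # synthetic PET + DWI + truth masks
petmrvol adc --dwi work/dwi.nii.gz --bvals work/bvals.txt \
             --mask work/dwi_voi.nii.gz \
             --out-adc work/adc.nii.gz --out-s0 work/s0.nii.gz
petmrvol ftv --s0 work/s0.nii.gz --adc work/adc.nii.gz \
             --voi work/dwi_voi.nii.gz --seed 17 --out work/ftv.csv
petmrvol mtv --pet work/pet.nii.gz --voi work/pet_voi.nii.gz --out work/mtv.csv
petmrvol run --seed 1 --out work/cohort        # full 29-patient synthetic study
```

`run` writes `cohort_estimates.csv`, `cohort_truth.csv` and the two report
tables (`table3.csv`: means, paired differences, percents, p-values;
`table4.csv`: Pearson correlations), byte-identical across reruns with the
same configuration.

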