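# cinestrain

Layer-specific endocardial **circumferential strain** analysis for
short-axis cardiac cine contours, together with a parametric beating-LV
phantom generator, cohort assembly rules and the planned-contrast
statistical battery used in population CMR studies.

The package is aimed at researchers who study left-ventricular (LV)
function across population subgroups (sex × age band × cardiovascular
health) and want a fully tested, reproducible pipeline from raw endocardial
contours to group-level inference — without access to restricted imaging
cohorts. A synthetic cohort generator with published group-level
distributions as defaults stands in for the real data.

## The measurements

For each short-axis cine slice the endocardial perimeter length `L_n` is
extracted from the closed contour at frame `n`, and strain is

```
ε_n = (L_n − L_0) / L_0
```

with `L_0` the perimeter at end diastole (frame 0). Slices are split
base→apex into three regions (each holding 2–4 slices for stacks of 6–10);
the regional strain curve is the frame-wise mean of member-slice curves and
the reported value is its most negative point ×100:

* **BCS / MCS / ACS** — basal / mid-ventricular / apical circumferential strain (%),
* **GCS** — global circumferential strain, the same construction over all slices.

Volumes use slice summation (Simpson's rule for a gapped stack): enclosed
contour area × slice spacing (8 mm thickness + 2 mm gap = 10 mm), summed
over slices, giving EDV and ESV, hence `LVEF = 100·(EDV−ESV)/EDV` and
`ESVi = ESV/BSA` (BSA via Du Bois by default).

The statistical battery mirrors the classical planned-comparison workflow:
pooled-variance Student's *t*-tests on lumped groups, a one-way ANOVA per
variable over the 12 stratification cells gating a fixed set of 17 planned
contrasts at a Bonferroni-corrected threshold (0.05/17 rounded → p ≤ 0.003),
percentile bootstrap CIs throughout, ±2.7 SD whole-individual outlier
removal, and Pearson correlations of every variable with age and BSA in the
four lumped sex × health groups.

## Worked example

```python
import cinestrain as cs

group = cs.GroupSpec(sex="female", age_band="65-74", health="healthy")
subject = cs.sample_subject(group, rng_seed=11)
stack = cs.synthesize_cine(subject, cs.AcquisitionParams(n_slices=8), rng_seed=12)
m = cs.measure_subject(subject, stack)
print(f"ground truth: c_mid = {subject.c_mid:.4f}, EDV draw = {subject.edv_true:.1f} ml")
for k in ("ACS", "MCS", "BCS", "GCS", "EDV", "ESV", "LVEF", "ESVi", "BSA"):
    print(f"{k:>5}: {m[k]:8.2f}")
```

prints

```
ground truth: c_mid = 0.2749, EDV draw = 127.1 ml
  ACS:   -45.36
  MCS:   -27.39
  BCS:   -32.01
  GCS:   -33.62
  EDV:   127.10
  ESV:    59.90
 LVEF:    52.87
 ESVi:    30.13
  BSA:     1.99
```

The subject's mid-region contraction fraction was drawn as 0.2749, and the
pipeline measures MCS = −27.39% — the small gap from −27.49% is the 0.2 mm
contour jitter; with `jitter_sd_mm=0` the recovery is exact to machine
precision. EDV equals the 127.1 ml draw because the phantom is sized so the
slice-summation volume matches it. GCS is the slice-count-weighted
combination of the three regional values.

The same pipeline runs from the shell:

```bash
cinestrain all --seed 7 --out runs/demo          # full chain
cinestrain stats --seed 9 --out runs/demo        # re-run inference only
```

producing `subjects.csv`, `contours/*.jsonl`, `analysis.csv`, the
`stats/` result tables and a Table-style listing of contrasts significant
at p ≤ 0.003.

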