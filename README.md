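# dtialps

Diffusion tensor image analysis **along the perivascular space** (DTI-ALPS)
as a reusable, tested pipeline — from diffusion-weighted signals to the ALPS
index and its reliability statistics — together with a synthetic
corona-radiata phantom that emulates a multi-condition acquisition protocol
(direction counts, averaging, echo/diffusion time, head position, imaging
plane, scanner noise profile) so the method's robustness can be studied at
desk scale without human data.

## The measurement

At the level of the lateral ventricle body, projection fibers run
inferior-superior (z), association fibers anterior-posterior (y), and the
perivascular spaces of the medullary veins right-left (x) — perpendicular to
both fiber systems. Water moving along the perivascular channels elevates
Dxx in both fiber regions, so the ratio

```
ALPS index = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

(computed from the scanner-frame tensor diagonal over four ROIs, per
hemisphere and bilaterally averaged) is a non-invasive proxy for
interstitial-fluid / glymphatic diffusivity. The package is aimed at
researchers who use or evaluate the ALPS index and want a controlled
test bed: a ground-truth phantom, DWI simulation with Rician noise, OLS
tensor fitting, the 3-axis ADC ("DWI-ALPS") route, six ROI patterns, and
ICC / paired-t / Pearson / repeated-measures-ANOVA reliability reports.

## Worked example

```python
import dtialps as d

spec  = d.PhantomSpec()                                  # default geometry
field = d.build_corona_radiata_phantom(spec)
acq   = d.simulate_dwi(field, d.make_scheme(12, 2, 85), snr_b0=40, seed=1)
maps  = d.maps_from_tensor(d.fit_tensor_loglinear(acq))
rois  = d.alps.build_pattern_rois(field.roi_centers, "sphere", 12)
res   = d.compute_alps(d.measure_rois(maps, rois, pixel_spacing=spec.voxel_size_mm))
print(f"ALPS-Bil = {res.alps_bil:.4f}  (ground truth {d.ground_truth_alps(spec):.4f})")
```

prints

```
ALPS-Bil = 1.5757  (ground truth 1.5822)
```

— a 12-direction, 2-average acquisition at SNR 40 recovers the phantom's
analytic index (1.5822, from the compartment table) within a fraction of a
percent; with `snr_b0=float("inf")` the two numbers agree to machine
precision. The full simulated study runs as

```python
results = d.run_study(d.StudyDesign(seed=1))      # 7 subjects x 12 conditions
report  = d.check_findings(results)
print(f"{report.n_passed}/8 findings checks passed")
for k, c in report.checks.items():
    print(k, "PASS" if c.passed else "FAIL", c.values)
```

which reports, e.g., test-retest ICC 0.998 at matched conditions, ICC
dropping to 0.62 under an 8.5° plane tilt and 0.10 under a 20° chin-up,
12- vs 3-axis indices that differ in paired mean (p < 1e-6) yet correlate at
r ≈ 0.999, and a monotone decrease of the index with diffusion time
(1.271 → 1.248 → 1.235 across 29/35.7/40.7 ms).

A CLI mirrors the library: `dtialps simulate | fit | alps | stats |
experiment` (see `dtialps --help`). Data travel as NIfTI-1 plus FSL-style
`.bval`/`.bvec`; results as CSV/JSON with a provenance block (package
version, seed, config hash).

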