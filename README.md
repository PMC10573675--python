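# lithovol

Hounsfield-window volumetry of renal stones on CT, with the full
inter-/intra-observer agreement analysis and a synthetic phantom simulator.

Urinary stone burden is still mostly graded by the maximum stone diameter,
but a single diameter misrepresents anything that is not a sphere: a round
12 mm stone carries 3.5× the material of a 20 × 5 × 5 mm plate. `lithovol`
implements volumetric stone burden measurement the way it is done
interactively on non-contrast CT — the operator picks an inclusive HU
*density window* `[hu_low, hu_high]` that fits the stone, voxels inside the
window are grouped into connected components, and each stone's volume is

    V = (number of voxels) × sx·sy·sz   [mm³]

— together with everything needed to *validate* such a tool: Lin's
concordance correlation coefficient (CCC), Kendall's coefficient of
concordance W, replicate coefficients of variation (CV), Bland–Altman
bias/limits of agreement/repeatability coefficient, paired t and
Mann–Whitney U tests, and a phantom generator with analytic ground truth
for end-to-end checks. A pluggable `duration = volume / ablation_rate`
model estimates laser lithotripsy time from the segmented volume.

It is aimed at endourology researchers evaluating volumetry software or
reliability-study designs, and at developers who need a tested, scriptable
reference for stone volumetry on DICOM/NIfTI data.

## Worked example

```python
from lithovol import sphere_volume, ellipsoid_volume
from lithovol.datasets import interobserver_median_table
from lithovol.agreement import agreement_report

v_round = sphere_volume(12.0)            # 4/3·π·(d/2)³
v_flat = ellipsoid_volume(20.0, 5.0, 5.0)  # π/6·l·w·h
print(f"round stone 12x12x12 mm : {v_round:7.1f} mm3")
print(f"flat  stone 20x5x5  mm  : {v_flat:7.1f} mm3")
print(f"burden ratio            : {v_round / v_flat:.1f}x")

report = agreement_report(interobserver_median_table())
print(f"overall Kendall W = {report.overall_kendall['w']:.4f} "
      f"(p = {report.overall_kendall['p']:.2g})")
for pair, entry in report.pairwise.items():
    c = entry["lin_ccc"]
    print(f"{pair:22s} CCC = {c['ccc']:.4f} "
          f"(95% CI {c['ci_low']:.4f}-{c['ci_high']:.4f})")
```

prints

```
round stone 12x12x12 mm :   904.8 mm3
flat  stone 20x5x5  mm  :   261.8 mm3
burden ratio            : 3.5x
overall Kendall W = 0.9919 (p = 1.5e-11)
expert_vs_junior       CCC = 0.9946 (95% CI 0.9907-0.9969)
expert_vs_senior       CCC = 0.9885 (95% CI 0.9808-0.9931)
junior_vs_senior       CCC = 0.9925 (95% CI 0.9874-0.9956)
```

The first block is the classic argument for volumetry: despite its larger
maximum diameter, the flat stone holds less than a third of the round
stone's volume (904.8 → reported as 904 mm³, 261.8 → 262 mm³). The second
block analyses the bundled reliability dataset — 50 renal-stone cases,
each segmented five times by three observers of different experience
levels, published as per-case median volumes — and finds near-perfect
agreement: a concordance W of 0.99 among the three observers and pairwise
Lin CCCs of 0.989–0.995, i.e. experience level barely affects the measured
volume.

## Command line

```sh
lithovol segment --input scan.nii.gz --hu-low 500 --hu-high 2000 --out seg.json
lithovol phantom --seed 5 --out phantom.nii.gz        # + .truth.json
lithovol study simulate --cases 50 --observers 3 --replicates 5 \
    --seed 1 --out measurements.csv
lithovol agree --table measurements.csv --out report.json   # + report.md
lithovol ld --volume 923 --rates rates.json --laser TFL --fiber 272 \
    --energy 0.5 --frequency 20 --composition COM
```

`segment` accepts a DICOM series directory (rescale slope/intercept
applied, slices sorted along the stack normal) or a NIfTI file. The
simulator renders synthetic CT phantoms — spheres, rotated ellipsoids and
branched staghorn-like stones with partial-volume blur and noise — and
re-measures them with observers whose lower threshold jitters from
replicate to replicate, producing measurement tables with known ground
truth. See `docs/methods.md` for the model details and the design
decisions.

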