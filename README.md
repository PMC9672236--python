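# gatedqa

Quality assurance for respiratory-gated (4D) PET motion-compensation
protocols, using experimental phantoms.

Patient breathing smears the activity distribution in thoracic PET,
degrading tumor volume, uptake and detectability estimates.  Scanners offer
many gating protocols — prospective windows triggered a fixed delay after
end-inhale or end-exhale, retrospective reconstructions in N time phases —
and sites need a reproducible way to decide which protocol preserves image
quality best.  `gatedqa` implements a phantom-based methodology: a static
(motionless) acquisition of each phantom is the ideal reference, and every
motion-compensated image is scored by **recovery coefficients**

```
RC_VA = V_mov / V_static        volume accuracy      (body phantom, 6 hot spheres)
RC_CA = C_mov / C_static        concentration accuracy (6 cylindrical inserts,
                                decay-compensated by 2^(Δt/T½))
RC_R  = Rod_mov / Rod_static    spatial resolution   (cold-rod phantom sectors)
```

with RC = 1 the ideal response.  Volumes come from 40%-of-maximum threshold
segmentation with region growing (a failed segmentation is reported with
the conventional RC = 5 overestimation sentinel); rods are counted as
4-connected components below 40% of the slice maximum inside triangular
sector ROIs, a sector being *distinguished* when ≥ 75% of its rods are
found.  Protocol pairs are declared comparable when both a Wilcoxon
signed-rank test (Bonferroni-adjusted) and a Bland–Altman percentage
analysis (95% CI of the mean percentage difference comprising zero) agree.

Because scanner time is scarce, the package ships a synthetic study
generator: digital body/insert/cold-rod phantoms, breathing waveforms
(sinusoidal, patient-like cos⁴ with end-exhale dwell and 3 mm hysteresis,
seeded irregular), both gating families reduced to displacement kernels,
and a forward model (kernel-convolution + 4.7 mm FWHM PSF + duty-cycle
scaled Poisson noise) producing 2 mm static / 4 mm gated NIfTI images.

## Worked example

```python
from gatedqa.pipeline import run_qa

cfg = {
    "simulate": {
        "phantoms": ["nema"],
        "patterns": ["sinusoidal"],
        "phantom_spacing_mm": 2.0,
        "protocols": [
            {"kind": "prospective_exhale", "window_fraction": 0.3},
            {"kind": "prospective_inhale", "window_fraction": 0.4},
            {"kind": "retrospective", "n_phases": 4},
        ],
        "settings": {"noise": True, "time_offset_s": 900.0},
    },
    "analyses": ["volume", "noise"],
    "compare": {"reference": "exhale_30", "alpha": 0.05},
}
report = run_qa(cfg, out_dir="out", seed=17)
print(report.summary_frame().to_string(index=False))
```

prints (seed 17):

```
analysis  protocol  mean_rc    sd_rc  n
  volume  4_phases 2.150034 1.514362  6
  volume exhale_30 2.875208 1.740765  6
  volume inhale_40 3.369326 1.806666  6
```

Each row is the mean ± SD volume RC over the six spheres (retrospective
phases averaged first).  Values above 1 are motion-driven overestimation;
the smallest spheres fail segmentation under heavy blur and enter as the
RC = 5 sentinel — the run log lists each failure.  The accompanying noise
table (SD of a 30 ml background VOI, averaged here over images) shows the
duty-cycle effect — fewer accepted counts, noisier image:

```
protocol
4_phases     1406.3
exhale_30    1322.1
inhale_40    1101.7
```

`out/` holds tidy CSVs (`rc_records.csv` per measurement,
`rc_collapsed.csv` with retrospective phases averaged, `rc_summary.csv`,
`sectors.csv`, `noise.csv`, `comparisons.csv`, `ranking.csv`) plus
`provenance.json` (config hash, seed).  Column names match the fields of
`RcRecord`: analysis, protocol, pattern, target, phase, static_value,
moving_value, rc, failed.

The same run is available from the shell:

```bash
gatedqa all --config study.yaml --out out --seed 17
gatedqa simulate --config study.yaml --out images --seed 17   # NIfTI + manifest only
```

Real acquisitions are analysed by constructing a `StudyBundle` from images
read with `read_volume` (NIfTI or DICOM series) and user reference ROIs
(`RoiSpec`: spheres, cylinders, triangle prisms), then calling
`analyze_study`.

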