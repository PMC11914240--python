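# plaquekit

Multi-level agreement analysis of coronary plaque metrics between
**NIRS-IVUS** (near-infrared spectroscopy intravascular ultrasound, the
invasive reference standard) and **coronary CT angiography (CTA)**, with a
focus on how coronary **calcium burden** distorts CTA's plaque
quantification.

CTA is the first-line non-invasive test for coronary artery disease, but
blooming artefacts around calcium and limited spatial resolution bias its
lumen, vessel and plaque-composition measurements. Quantifying *how much*
— and whether the disagreement with intravascular imaging grows with the
calcium burden — requires a chain of analyses that this package implements
as a tested, reusable pipeline for imaging-core-lab statisticians:

1. **Frame-level data model** — matched NIRS-IVUS/CTA cross-sections with
   lumen/vessel areas and circumferential tissue annotations
   (CSV/JSON schema, validation, round-trip I/O).
2. **Plaque metrics** — spread-out plots (angle x pullback position),
   volumes by trapezoidal integration, and the burden indices

   - plaque burden `PB = 100 x (vessel - lumen) / vessel` per frame,
   - `TAV = vessel volume - lumen volume`, `PAV = 100 x TAV / vessel volume`,
   - `LCBI` / `CaBI` = flagged cells / total cells x 1000 on the
     spread-out plot, `maxLCBI_4mm` = max LCBI over any 4 mm window,
   - mean Ca area = Ca volume / segment length; Ca arc = 360 x CaBI / 1000,
   - a configurable Hounsfield-unit tissue classifier (NC/FF/FT/CA).
3. **Lesion analysis** — lesions as >= 3 consecutive frames with
   PB >= 40%, merged across sub-threshold gaps < 5 mm; MLA, max PB,
   flank reference areas, remodelling index; lesions found on NIRS-IVUS
   are transferred frame-for-frame to CTA.
4. **Agreement statistics** — Wilcoxon signed-rank tests; Bland–Altman
   limits of agreement (parametric `mean +/- 1.96 SD`, or median and
   2.5th/97.5th percentiles via quantile regression); `ICC(A,2)`
   (two-way random effects, absolute agreement, average measures) by REML
   with subject and modality random intercepts, optionally adjusted for
   calcium via restricted cubic splines; tercile/decile stratification
   with a Fisher-z / DerSimonian–Laird heterogeneity test across strata.
5. **Interaction models** — proportional-odds (segment/lesion) and OLS
   (frame-level, subject-clustered) regressions of the NIRS-IVUS value on
   the CTA value, with a calcium x measurement interaction test and
   predicted difference-vs-calcium curves.
6. **Synthetic cohorts** — a generator with per-subject random effects,
   AR(1)-smooth pullback profiles, zero-inflated persistent calcium and
   calcium-dependent CTA bias, so the whole pipeline is testable against
   known ground truth.

## Worked example

```python
import numpy as np, pandas as pd
from plaquekit import (SyntheticCohortSpec, generate_cohort, segment_metrics,
                       detect_lesions, icc_mixed, bland_altman, icc_band)
from plaquekit.pipeline import frame_table

spec = SyntheticCohortSpec(n_subjects=16, vessels_per_subject=2,
                           frames_per_segment=60, seed=3)
dataset, truth = generate_cohort(spec)
print(f"matched cross-sections: {len(dataset)}")

key, nirs_seg, cta_seg = next(dataset.segments())
m = segment_metrics(nirs_seg)
print(f"segment {key}: PAV {m.pav:.1f}%, LCBI {m.lcbi:.0f}, "
      f"maxLCBI4mm {m.max_lcbi_4mm:.0f}, CaBI {m.cabi:.0f}, "
      f"mean Ca area {m.mean_ca_area:.2f} mm2")

frm = frame_table(dataset)
wide = frm.pivot_table(index="frame_id", columns="modality", values="pb")
bias, lo, hi = bland_altman((wide["NIRS_IVUS"] - wide["CTA"]).to_numpy(),
                            "parametric")
print(f"frame-level plaque-burden bias {bias:.2f}% (LOA {lo:.2f} to {hi:.2f})")

long = pd.DataFrame({"subject": np.repeat(wide.index, 2),
                     "modality": np.tile(["NIRS_IVUS", "CTA"], len(wide)),
                     "value": wide[["NIRS_IVUS", "CTA"]].to_numpy().ravel()})
r = icc_mixed(long, n_boot=500, seed=0)
print(f"plaque-burden ICC(A,2) = {r.icc:.2f} "
      f"(95% CI {r.ci[0]:.2f}-{r.ci[1]:.2f}, {icc_band(r.icc)} agreement)")
```

Output:

```
matched cross-sections: 1920
segment ('S000', 'V0'): PAV 31.0%, LCBI 20, maxLCBI4mm 111, CaBI 336, mean Ca area 1.29 mm2
frame-level plaque-burden bias 2.83% (LOA -4.83 to 10.49)
plaque-burden ICC(A,2) = 0.95 (95% CI 0.94-0.95, excellent agreement)
```

The synthetic CTA here carries a calcium-dependent multiplicative bias, so
NIRS-IVUS reads ~3 plaque-burden points higher on average; the ICC is
nonetheless excellent because the between-frame spread dominates the
modality disagreement.

## Command line

```bash
plaquekit simulate --preset paper-like --seed 1 --out frames.csv
plaquekit lesions  --input frames.csv --out lesions.csv
plaquekit report   --input frames.csv --seed 1 --out report_dir
```

`report` executes the full chain (metrics -> lesions -> agreement ->
interaction models) and writes tidy CSV tables, model JSON reports,
spread-out plot exports and a manifest whose config hash and seed make the
whole bundle reproducible byte-for-byte. Analysis options live in a YAML
`RunConfig` (`plaquekit report --config run.yaml`).

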