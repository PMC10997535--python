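# scoutlmd

Quantitative estimation of the **lung mean dose (LMD)** delivered during
hepatic radioembolization, from co-registered scout-dose SPECT/CT volumes.

Before treating liver tumors with beta-emitting microspheres
(holmium-166 or yttrium-90), a small *scout dose* — either
[99mTc]-macroaggregated albumin (MAA) or a small batch of the treatment
microspheres themselves — is injected to predict how much activity will
shunt through hepatopulmonary anastomoses into the lungs.  Patients are
excluded, or their activity reduced, when the predicted lung mean dose
exceeds 30 Gy for a single treatment or 50 Gy cumulatively, to guard
against radiation pneumonitis.  MAA is known to overestimate lung shunting
(fragment and free-pertechnetate uptake in the lungs), so an accurate
volumetric estimator matters clinically: it avoids unnecessary exclusions.

`scoutlmd` implements the volumetric estimator, the VOI construction it
depends on, a synthetic phantom-cohort generator with known ground truth,
and the paired cohort statistics used to compare scout methods against the
posttreatment gold standard.

## The estimator

For each scan, with organ VOIs segmented on the co-registered low-dose CT:

```
eLMD [Gy] = (C_left-lung-VOI / C_total-body) * A_net [GBq] * k_E [J/GBq] / M_left-lung-VOI [kg]
```

* `C_left-lung-VOI` — counts in the **left lung** only (less prone to
  spill-in of liver activity than the right), after removing every voxel
  within a **3-D 2 cm Euclidean margin of the liver VOI** (computed in mm
  on the anisotropic grid, so misregistration/breathing/partial-volume
  spill-over near the liver dome never contaminates the numerator);
* `C_total-body` — counts inside the CT threshold-based body contour;
* `A_net` — net administered *treatment* activity (for all scan roles;
  a scout contributes only its count ratio);
* `k_E = 15.87 J/GBq` — energy-deposition conversion factor;
* `M_left-lung-VOI` — VOI volume × assumed lung density 0.3 g/mL.

Dose is assumed equal in both lungs, so the left-lung mean stands for the
whole-lung mean.  Because only a count *ratio* enters, the estimate is
invariant to the absolute calibration of the reconstruction.

The package also provides the conventional planar-style two-region lung
shunt fraction `LSF = C_lung / (C_lung + C_liver)` and the 30/50 Gy
eligibility decision.

## Worked example

Simulate a 10-patient cohort (three co-registered scans per patient on a
96×96×72 grid at 4 mm), estimate every dose, and run the paired comparison:

```bash
cat > example.yaml <<'EOF'
seed: 42
simulate:
  n_patients: 10
EOF
scoutlmd all --config example.yaml --output-dir example_out
```

which prints (and writes to `example_out/report.txt`):

```
Cohort comparison (n = 10; 0 patient(s) excluded)
  eLMD MAA-scout: median 2.39 Gy (range 0.65-6.97 Gy)
  eLMD Ho-scout: median 0.00 Gy (range 0.00-0.77 Gy)
  LMD Ho-treatment: median 0.01 Gy (range 0.00-0.77 Gy)
  dMAA (scout - treatment): median 2.27 Gy (range 0.64-6.97 Gy)
  dHo-scout (scout - treatment): median 0.00 Gy (range -0.01-0.01 Gy)
  Spearman MAA vs treatment: r = -0.13, p = 0.726
  Spearman Ho-scout vs treatment: r = 0.55, p = 0.098
  Wilcoxon MAA vs treatment: p = 0.00195 (n_eff = 10)
  Wilcoxon Ho-scout vs treatment: p = 1 (n_eff = 3)
  eLMD_MAA > LMD_treatment in 10/10 patients
```

Reading the numbers: most simulated patients have a zero true shunt, so
the holmium scout and the posttreatment scan both report (near-)zero doses
and track each other, while the MAA scans — which carry the simulated
fragmentation and free-background bias — overestimate the lung dose in
every patient, significantly so under the Wilcoxon signed-rank test.
`example_out/` also contains `doses.csv` (one row per scan with counts,
shunt ratio, VOI mass and eligibility flag), `deltas.csv` (the per-patient
diverging-difference table), `comparison.json`, and the NIfTI volumes plus
`truth.csv` from the simulation.

The same stages run separately as `scoutlmd simulate`, `scoutlmd dose`
(on a file manifest of NIfTI volumes, optionally `--write-masks`) and
`scoutlmd compare`; every run drops a provenance record (config hash,
seed, version) into its output directory.

Programmatic use mirrors the CLI:

```python
from scoutlmd import (PhantomSpec, ScanModel, ScanRole, make_phantom,
                      simulate_scan, segment_body, build_voi_set,
                      estimate_lmd_spect)

phantom = make_phantom(PhantomSpec(), seed=1)
scan, truth = simulate_scan(phantom, ScanModel(shunt_fraction_s=0.05, poisson=False),
                            ScanRole.HO_TREATMENT, a_net_gbq=6.0)
vois = build_voi_set(phantom.labels, segment_body(phantom.density), margin_mm=20.0)
print(estimate_lmd_spect(scan, vois).elmd_gy, truth.true_lmd_gy)
# 8.154988982800013 8.154988982800013
```

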