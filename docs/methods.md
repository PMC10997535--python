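# Methods

## Dose model

The lung mean dose estimate follows the count-ratio absorbed-dose
formalism for volumetric (SPECT/CT) scout imaging:

    eLMD [Gy] = (C_lungVOI / C_body) · A_net [GBq] · k_E [J/GBq] / M_lungVOI [kg]

with the numerator region restricted to the **left lung**.  The underlying
assumptions, shared with clinical practice, are: complete local energy
absorption in lung tissue, negligible lung dose from extra-pneumonic
activity, uniform lung density, and left/right perfusion symmetry (the
left-lung mean is reported as the whole-lung mean).  Because numerator and
denominator come from the same reconstruction, absolute calibration
cancels; only relative voxel counts matter, and no decay or sensitivity
correction is applied.

Constants, all configurable:

| parameter | default | units | meaning |
|---|---|---|---|
| `k_e_j_per_gbq` | 15.87 | J/GBq | energy deposited per unit net administered activity for the holmium-166 treatment; honored verbatim as the clinical convention, not re-derived |
| `rho_lung_g_per_ml` | 0.3 | g/mL | assumed uniform lung density for VOI mass |
| `margin_mm` | 20 | mm | 3-D Euclidean liver margin excluded from the lung VOIs |
| `threshold_hu` | −400 | HU | CT body-contour threshold (conventional air/tissue cut; the mask is the largest connected component with interior holes filled) |
| dose limits | 30 / 50 | Gy | single-treatment and cumulative eligibility limits |

`A_net` is always the net *treatment* activity (calibrated activity minus
administration-system residual), for all three scan roles; a scout scan
contributes only its count ratio.  Using each scan's own injected activity
instead would understate the prediction by one to two orders of magnitude.

## VOI construction

* **Body contour**: voxels ≥ `threshold_hu`, reduced to the largest
  6-connected component, interior holes filled.  This mask — not the label
  map's body class — is the total-count denominator region.  Whether the
  liver+margin should also be removed from the denominator is ambiguous in
  the field; this implementation keeps the full body mask (the effect is
  second-order: the margin region holds a few percent of body counts).
* **Liver margin**: the liver label dilated by `margin_mm`, computed with
  an exact Euclidean distance transform sampled at the grid spacing.  The
  distance is voxel-centre to voxel-centre in mm — the deterministic,
  testable reading of a "2 cm margin"; boundary-to-boundary alternatives
  differ by at most one voxel.
* **Evaluation regions**: each lung label minus the dilated liver.  An
  empty left-lung evaluation region is a hard error ("left lung fully
  excluded"): the estimate is then impossible.

The pipeline requires all of a patient's volumes on one voxel lattice and
refuses (rather than resamples) on mismatch: silent interpolation would
corrupt count totals.  Oblique (non-axis-aligned) NIfTI orientations are
rejected for the same reason.

## Synthetic phantom and cohort generator

Each digital patient is four voxelized ellipsoids (body, liver, left lung,
right lung) on a 96×96×72 grid at 4 mm, with adult-realistic volumes
(liver ≈ 1.1 L, lungs ≈ 0.85–1.1 L after rasterization) and both lung
bases ~6–16 mm above the liver dome, so the 2 cm margin genuinely removes
basal lung voxels.  Per-patient geometry jitter (±1.5 mm centres, ±2 %
axes) is small enough to preserve organ disjointness and a tissue shell
between every organ and the body surface; both are re-validated at
rasterization (a lung touching the surface would leak out of the
hole-filled CT body contour and silently corrupt the denominator).  The synthetic CT assigns −1000/−800/+50/0 HU to
air/lung/liver/other body.

Activity is a partition of the administered particles: fraction `s` (the
true shunt) spread uniformly over both lungs, the remainder in the liver.
MAA scans add two phenomenological bias fractions — `f` for albumin
fragmentation (extra apparent lung uptake) and `b` for free pertechnetate
(uniform whole-body background).  The literature names these mechanisms
but quantifies neither per patient, so they are exposed as configuration,
and the defaults below are illustrative synthetic conditions, not
estimates of the clinical effect.

Degradations, in order: rigid misregistration shift (linear interpolation),
Gaussian PSF blur, Poisson sampling.  An optional field-of-view crop
removes the superior fraction of lung-bearing axial slices from the scan
volume (labels and activity), emulating the narrow SPECT axial coverage;
because lung concentration is uniform, the ratio estimator remains
unbiased under truncation.

Cohort defaults (chosen once to land the simulated doses in clinically
reported ranges; medians/ranges in the generator docstrings):

* `s`: zero-inflated — zero with probability 0.6, otherwise log-normal
  with median 0.002 and log-sd 1.0, capped at 0.2.  With ~6 GBq and
  ~2.2 kg of lung this puts nonzero posttreatment doses at ~0.1–3 Gy and
  the cohort median at 0 Gy.
* `f`: log-normal, median 0.004, log-sd 1.2, clipped to [5·10⁻⁴, 0.1];
  `b`: uniform on [0.01, 0.04].  Together they put the median MAA
  estimate near 1.5 Gy with a tail to tens of Gy.
* `A_net`: log-normal, median 6.159 GBq, clipped to [2.207, 12.897] GBq —
  the typical treatment-activity range.
* degradations: 12 mm FWHM PSF, 5·10⁶ counts, per-scan shift of
  (0, 0, +4) mm superior plus isotropic 1.5 mm jitter, FOV crop uniform
  on [0, 0.35].

All randomness flows from one root seed through named child streams
(geometry / patient parameters / per-scan noise), so any stage can be
reproduced in isolation and two runs with one seed are bit-identical.

### What the generator does and does not emulate

It reproduces the features the estimator is sensitive to: count ratios,
anisotropic geometry, liver-to-lung spill from blur and misregistration,
Poisson statistics, FOV truncation, and a systematic MAA excess.  It does
**not** model projection-domain physics (collimator response, attenuation,
holmium downscatter), heterogeneous intra-lung perfusion, breathing motion
blur beyond the rigid shift, or realistic organ shapes.  Passing tests
therefore validate the estimation *pipeline* — not the clinical magnitude
of MAA overestimation, which the bias fractions merely parameterize.

## Numerical behavior worth knowing

* **Exact recovery.**  On a clean phantom (no blur, shift or noise) the
  estimator recovers `s·A_net·k_E/M_lungs` to machine precision: with
  uniform lung concentration, the left-lung count share exactly cancels
  the left-lung mass share, independent of the margin exclusion and FOV
  crop.
* **Partial-volume bias under blur.**  A 12 mm FWHM PSF (σ ≈ 5.1 mm)
  moves ≈ 0.4·σ·S/V ≈ 10 % of the lung's counts outside its boundary
  (measured: −10.3 % on the default left lung), while the denominator is
  barely affected because activity is concentrated away from the body
  surface.  This deficit is intrinsic to mask-sum quantification of
  blurred images at realistic organ surface-to-volume ratios; no phantom
  geometry short of a ~10 L lung brings it under 5 %.  The test suite
  therefore checks that Poisson sampling is unbiased against the blurred
  expectation (within 2 % over 20 seeds) and that the deterministic blur
  bias stays below 15 %.
* **Misregistration bias direction.**  A superior shift moves liver
  activity toward the lung VOIs.  The resulting *contamination* term grows
  monotonically with the shift and is reduced by the 2 cm margin — cleanly
  observable at `s = 0`, where the estimate is pure spill.  At larger
  shunt fractions the shift also moves the lung's own activity across the
  fixed evaluation-region boundary, a loss that can dominate the
  contamination gain and make the *net* estimate decrease with shift; the
  directional tests therefore isolate the contamination mechanism at zero
  shunt.
* **Ties and zeros in the statistics.**  Lung-dose cohorts are zero-heavy.
  The Wilcoxon implementation exposes both the classic `discard` policy
  and Pratt's method (zeros ranked, then dropped), defaulting to
  `discard`; with all differences zero it reports p = 1 and a degenerate
  flag instead of raising.  Exact p-values enumerate all 2ⁿ sign
  assignments of the observed midranks for effective n ≤ 15 (instant);
  beyond that a normal approximation with tie/zero-absorbing variance
  (Σr²/4) and continuity correction is used.  Spearman uses midranks, an
  exact permutation p below n = 10 and the t-approximation above.  A
  constant input makes the coefficient undefined: the low-level function
  raises, and the cohort summary records the correlation as undefined
  rather than aborting.
* **Reporting.**  Doses are written to CSV rounded to 2 decimals (full
  precision is kept in memory); the comparison stage consumes the CSV, so
  sub-0.005 Gy structure is deliberately not propagated into the report.

## Problem sizes

The default grid (663 552 voxels at 4 mm) keeps a full 37-patient cohort —
37 phantoms, 111 simulated scans, VOI construction and dose estimation —
at roughly 15 s on one core, so multi-seed replication studies and the
test suite run comfortably on a laptop.  Finer grids trade linearly
increased cost for smaller voxelization error in the margin exclusion.

## Known limitations

* The phantom's ellipsoid organs underrepresent the irregular liver dome,
  where margin exclusion matters most clinically.
* The MAA bias fractions are phenomenological; conclusions about the
  *size* of MAA overestimation in patients cannot be drawn from defaults.
* No partial-volume correction is attempted; the blur-induced underestimate
  above applies equally to all three scan roles and largely cancels in
  paired comparisons, but not in absolute dosimetry.
* Eligibility uses fixed 30/50 Gy limits; these thresholds themselves rest
  on sparse clinical evidence and are configurable, not endorsed.
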