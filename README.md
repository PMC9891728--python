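# coloc-stress

Quantitative image- and blot-analysis toolkit for studies of protein
relocation under calcium stress — in particular the proteolytic cleavage
of junctional proteins (e.g. junctophilin-1 and its ~44 kDa fragment)
and the activation of calpain-family proteases.  It is aimed at muscle
cell biologists who quantify confocal immunofluorescence z-stacks and
Western blots, and at anyone who wants these measures as tested,
reusable library functions rather than one-off scripts.

## What it computes

**Colocalization of two channels A, B on the same voxel grid** (after
per-channel background subtraction), four complementary measures:

- Pearson's pixel-by-pixel correlation
  `R = Σᵢ(Aᵢ−Ā)(Bᵢ−B̄) / √(Σᵢ(Aᵢ−Ā)² Σᵢ(Bᵢ−B̄)²)`;
- Li's Intensity Correlation Quotient, `ICQ = N₊/N − 0.5`, where `N₊`
  counts pixels whose covariance term `(Aᵢ−Ā)(Bᵢ−B̄)` is strictly
  positive; ICQ ∈ [−0.5, +0.5], +0.5 for identity, −0.5 for mutual
  exclusion, with the ICA scatter (covariance vs. intensity) returned
  for plotting;
- Van Steensel's cross-correlation analysis: `R(dx)` as channel B is
  translated along one axis by whole pixels, fitted with a Gaussian;
  the apex abscissa (**VS shift**, nm) measures vectorial
  de-localization and the **FWHM** (µm) measures dispersion.  When the
  Gaussian fits poorly (R² < 0.7), the measured profile's maximum and
  interpolated half-maximum width are reported instead.

**Nuclear localization**: Otsu segmentation of a nuclear-marker channel
and the nuclear/cytosolic density ratio (signal per voxel in each
region), a gain-invariant measure of nuclear import.

**Densitometry**: band signal mass above a flanking-margin baseline,
source-gel lane normalization, and least-squares decomposition of
closely spaced dual bands (e.g. the ~80/76 kDa protease doublet) into
per-band masses and their ratio.

**Nested statistics**: cells cluster within subjects, so summaries and
group tests operate on subject means (N subjects, n cells reported
separately), with automatic t vs. Mann-Whitney selection, the analytic
p of no correlation from (R, n), and noncentral-t power.

**Synthetic data**: every stage is exercised against generated scenes
with known ground truth — PSF-blurred punctate stacks (colocalized,
displaced, or dispersed), ellipsoidal nuclei with a known import
fraction, and Gaussian-band lane images.

## Worked example

Generate a scene whose channel B is displaced by a known 120 nm along
x, then analyze it:

```sh
coloc-stress simulate --out scene --seed 5 --displacement 120
coloc-stress coloc --a scene/channel_a.tif --b scene/channel_b.tif \
    --axis x --max-shift 10 --out cell.csv
```

prints

```
R=0.824 ICQ=0.209 VS=120 nm FWHM=0.52 um
```

The Van Steensel shift recovers the generating 120 nm displacement
exactly at this seed (two lateral pixels at 60 nm/px); R and ICQ are
pulled below their colocalized values (≈0.98 and ≈0.47 for an identical
pair under the same noise) because the displaced puncta no longer
overlap voxel-for-voxel.  Python equivalent:

```python
from coloc_stress import SceneParams, make_coloc_stack, analyze_pair

params = SceneParams(displacement=(120.0, 0.0, 0.0), seed=5)
a, b, truth = make_coloc_stack(params)
summary = analyze_pair(a, b, max_shift_px=10)
print(summary.r, summary.icq, summary.vs_shift_nm, summary.fwhm_um)
```

Batch runs reproduce the study-style tables (per-cell rows, then
average / median / SEM rows with N and n) from a single YAML
configuration: `coloc-stress run config.yaml` (see
`tests/test_pipeline.py` for a complete configuration).

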