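# Methods

## Wavelet decomposition

One separable analysis level with orthonormal Daubechies filters (db1–db4
hardcoded to 16+ significant digits; default **db2**, 4 taps). Per axis the
signal is low-pass and high-pass filtered and downsampled by 2; tensoring
the two branches over three axes gives the approximation `LLL` plus seven
details ordered `HLL, LHL, HHL, LLH, HLH, LHH, HHH` (letter *i* = filter on
axis *i*). The ordering is fixed because the combined descriptor's layout
depends on it. The approximation is computed and carried in `SubbandSet`
but contributes no features: the descriptor uses detail subbands only.

Boundary handling is configurable and recorded in every output:

- `symmetric` (default): half-point mirror extension, the common choice for
  image data. Subbands have `floor((n + L − 1)/2)` samples per axis — mildly
  redundant — and reconstruction is exact after cropping (verified ≤ 1e-8 max
  abs error in tests).
- `zero`: zero padding, same sizes.
- `periodization`: circular, non-redundant (`n/2` per axis, even dims
  required). Implemented as an explicit orthogonal circulant operator, so
  energy is conserved exactly; used by the energy-conservation tests.

Normalisation: standard orthonormal filter-bank scaling (low-pass sums to
√2). Any global rescaling of coefficients is irrelevant downstream, because
LBP codes depend only on intensity *order* within a neighbourhood.

## 3D local binary patterns

Fixed operator: radius 1, the 18 non-corner neighbours of the 3×3×3
neighbourhood. The corners are excluded so the neighbourhood is the set of
voxels in the axial, coronal, sagittal and diagonal planes through the
centre. Bit order is lexicographic by `(dz, dy, dx)` — any fixed order is
internally consistent; full and uniform histograms are permutations of each
other across orders, and riu bins depend only on popcount and uniformity.

Decisions worth stating:

- **Tie rule**: a neighbour *equal* to the centre sets its bit (`f(0)=1`).
  A constant volume therefore codes entirely to the all-ones code.
- **Boundaries**: voxels whose neighbourhood leaves the volume are skipped,
  never padded — padding would fabricate intensities. A histogram of an
  `A×B×C` volume counts `(A−2)(B−2)(C−2)` voxels.
- **Masks**: optional. Only voxels whose *centre* is inside the mask are
  coded; neighbours may lie outside the mask (but not the volume). Useful
  for gray-matter maps with large zero backgrounds.
- **Normalisation**: relative frequencies by default (volumes and subbands
  differ in size); raw counts behind a flag.
- **"Rotation" invariance** is circular rotation of the 18-bit string, the
  direct 3D transplant of the classic 2D construction. A bit rotation does
  *not* correspond to any rigid rotation of the 3D neighbourhood; the riu
  map is used as the established compact summary, not as a claim of
  physical rotation invariance.

Bin counts, all verified exhaustively in tests: full 2¹⁸ = 262,144;
uniform 18·17 + 2 = 308 uniform codes + 1 shared bin = 309; riu 18 + 2 = 20.

## Combined descriptor and FDR ranking

`extract_dwt_lbp20`: decompose once, riu-histogram each detail subband,
concatenate → 140 features in subband-major, bin-minor order. No global
rescaling beyond the per-histogram normalisation; classifier-side z-scoring
is the evaluator's job.

FDR uses **sample** standard deviations (n−1): the convention is unstated
in the usual presentations, ranking is unaffected as long as both classes
use the same one, and it is pinned here so test oracles are exact.
Degenerate features (zero variance in both classes) score 0 when the means
agree and +∞ when they differ — a feature constant within each class but
different between them separates the training data perfectly and is ranked
first. Ties break by ascending feature index (stable sort) for
cross-platform determinism.

## Nested cross-validation

Outer 10-fold / inner 10-fold, both **stratified** by class. Plain random
splitting can produce single-class folds at desk-scale n, which makes
sensitivity/specificity undefined; stratification is a documented deviation
from unconstrained random splitting. Folds derive deterministically from
one seed (inner-fold seeds are spawned per outer fold).

Per outer fold: FDR ranking on the outer-training rows only → for each
k = 1..K, mean inner-validation accuracy of a linear SVM (features z-scored
with inner-training statistics, C = 1 by default, optional grid
{0.01, 0.1, 1, 10, 100}) on the top-k features → **k\* = smallest k
attaining the maximum** mean inner accuracy (the parsimonious deterministic
tie rule) → refit on the full outer-training set and score the held-out
subset. K defaults to all features for descriptors up to 500 features and
caps at 500 beyond that (configurable), which keeps the 262,144-bin and
raw-coefficient baselines tractable without affecting typical selected
counts. Reported: per-fold confusion counts and selected k, plus mean ±
sample SD (n−1, over the 10 folds) of accuracy, sensitivity, specificity
and k. The positive class defaults to the second label in first-appearance
order and is recorded in the report.

Leakage is a first-class concern: ranking and scaling statistics never see
test rows, asserted by a canary test in which a feature informative only on
a fold's test rows must score 0 in that fold's ranking.

## Synthetic data: what it emulates and what it does not

Each volume is a unit-variance Gaussian random field with a class-specific
correlation scale (Gaussian smoothing of white noise, circular boundary),
plus an optional class-specific oriented sinusoidal grating and i.i.d.
Gaussian noise. Class differences live **only in local spatial structure**,
never in mean intensity — deliberately, because LBP codes are invariant to
intensity shifts, so a mean-shifted pair of classes is a negative control
the descriptor must *not* separate. `class_contrast` interpolates class B's
parameters toward class A's; 0 is an exact null (both classes one
distribution).

Defaults are the desk-scale evaluation setting: 32³ voxels, 30 volumes per
class, correlation scales (1, 2) voxels, noise SD 0.1, no gratings. The
scales were chosen once as a plainly visible texture difference (roughly
the smallest pair that differs by a full octave); at this setting the
end-to-end pipeline reaches ≥ 0.90 nested-CV accuracy (the tested
signal-recovery property) and the zero-contrast null sits in the chance
band.

A green synthetic run establishes that the pipeline *can* recover local
texture differences and is calibrated under the null. It does **not**
establish performance on real structural MRI: the generator has no anatomy,
no atrophy, no acquisition artefacts, no inter-subject registration error,
and its stationary Gaussian textures are far simpler than tissue
microstructure.

## Numerical choices

- All intensities processed as float64 regardless of on-disk dtype.
- Perfect-reconstruction tolerance 1e-8 (max abs), energy conservation
  1e-6 relative, histogram mass and FDR oracle agreement 1e-12.
- Feature tables are CSV with 17 significant digits: a write/read
  round-trip agrees to better than 1e-12 relative.
- `periodization` rejects odd axis lengths rather than silently padding.
- 4D NIfTI inputs are rejected, not squeezed; the affine is metadata only.

## Known limitations

- Single decomposition level only; no wavelet packets, no 2D slice-wise
  transform.
- LBP is fixed at 18 neighbours / radius 1; no interpolated spherical
  sampling.
- The riu "rotation" is a bit-string rotation (see above).
- Masks apply to raw-volume LBP descriptors; the combined descriptor
  ignores them because a voxel mask has no canonical image in the
  half-resolution subband lattice.
- Univariate feature selection only; interactions between features are
  invisible to FDR.
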