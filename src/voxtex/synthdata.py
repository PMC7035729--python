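"""Two-class synthetic 3D texture volumes.

Classes differ in *local spatial structure*, never in mean intensity: the
LBP code is invariant to intensity shifts, so a mean offset would be
invisible to the pipeline by construction.  Each volume is

    unit-variance Gaussian random field (correlation scale per class)
    + optional oriented sinusoidal grating (axis, period, amplitude)
    + i.i.d. Gaussian noise

``class_contrast`` interpolates class B's structural parameters toward
class A's: at contrast 0 both classes are draws from the same distribution
(a null/negative-control configuration), at contrast 1 class B uses its
stated parameters in full.

Randomness: one master seed; the stream for each volume derives from
(seed, class_id, draw_index), so enlarging a dataset never perturbs
existing draws.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volio import Volume3D, DatasetManifest, write_volume, save_manifest

__all__ = ["SynthParams", "Grating", "generate_volume", "generate_dataset",
           "generate_feature_matrix"]

CLASS_LABELS = ("A", "B")


@dataclass
class Grating:
    """Oriented sinusoid added to a class: sin(2*pi*coord/period) along axis."""

    axis: int = 0
    period: float = 4.0
    amplitude: float = 1.0


@dataclass
class SynthParams:
    """Stated world of the generator.

    Defaults match the desk-scale evaluation setting: 32**3 voxels and 30
    volumes per class; class A is a rough field (correlation scale 1 voxel),
    class B a smoother one (scale 2 voxels), with mild i.i.d. noise on top.
    """

    dims: tuple[int, int, int] = (32, 32, 32)
    n_per_class: int = 30
    class_contrast: float = 1.0
    smoothing_lengths: tuple[float, float] = (1.0, 2.0)
    gratings: tuple[Grating | None, Grating | None] = (None, None)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 8 for d in self.dims):
            raise ValueError(f"dims must each be >= 8, got {self.dims}")
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.class_contrast < 0:
            raise ValueError("class_contrast must be >= 0")

    def effective(self, class_id: int) -> tuple[float, Grating | None]:
        """Class parameters after applying the contrast knob.

        Class 0 keeps its stated parameters; class 1's smoothing length is
        interpolated from class 0's and its grating amplitude scaled, both
        by ``class_contrast``.
        """
        if class_id not in (0, 1):
            raise ValueError(f"class_id must be 0 or 1, got {class_id}")
        s0, s1 = self.smoothing_lengths
        g = self.gratings[class_id]
        if class_id == 0:
            return s0, g
        c = self.class_contrast
        s_eff = s0 + c * (s1 - s0)
        g_eff = None
        if g is not None:
            g_eff = Grating(axis=g.axis, period=g.period, amplitude=c * g.amplitude)
        return s_eff, g_eff


def _rng(params: SynthParams, class_id: int, draw_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([params.seed, class_id, draw_index])
    )


def generate_volume(class_id: int, params: SynthParams,
                    draw_index: int) -> Volume3D:
    """One deterministic draw of a class's texture."""
    s_eff, grating = params.effective(class_id)
    rng = _rng(params, class_id, draw_index)
    field_ = rng.standard_normal(params.dims)
    if s_eff > 0:
        field_ = gaussian_filter(field_, sigma=s_eff, mode="wrap")
        sd = field_.std()
        if sd > 0:
            field_ /= sd  # unit variance: smoothing changes structure, not scale
    if grating is not None and grating.amplitude != 0.0:
        coord = np.arange(params.dims[grating.axis], dtype=np.float64)
        wave = grating.amplitude * np.sin(2.0 * np.pi * coord / grating.period)
        shape = [1, 1, 1]
        shape[grating.axis] = -1
        field_ = field_ + wave.reshape(shape)
    if params.noise_sd > 0:
        field_ = field_ + params.noise_sd * rng.standard_normal(params.dims)
    label = CLASS_LABELS[class_id]
    return Volume3D(
        data=field_,
        source=f"synth seed={params.seed} class={label} draw={draw_index}",
    )


def generate_dataset(params: SynthParams, out_dir: str | os.PathLike):
    """Write 2 x n_per_class NIfTI volumes and a manifest CSV.

    Returns ``(volume_paths, manifest)``; manifest labels are "A"/"B".
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths: list[str] = []
    labels: list[str] = []
    for class_id, label in enumerate(CLASS_LABELS):
        for draw in range(params.n_per_class):
            vol = generate_volume(class_id, params, draw)
            path = os.path.join(out_dir, f"vol_{label}_{draw:03d}.nii.gz")
            write_volume(vol, path)
            paths.append(path)
            labels.append(label)
    manifest = DatasetManifest(paths=paths, labels=labels)
    save_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return paths, manifest


def generate_feature_matrix(params: SynthParams, extractor=None):
    """In-memory dataset -> FeatureMatrix (no disk I/O).

    ``extractor`` maps a Volume3D to a FeatureVector; defaults to the
    combined wavelet-subband riu-LBP descriptor.
    """
    from .features import extract_dwt_lbp20, FeatureMatrix

    if extractor is None:
        extractor = extract_dwt_lbp20
    vectors = []
    labels = []
    for class_id, label in enumerate(CLASS_LABELS):
        for draw in range(params.n_per_class):
            vectors.append(extractor(generate_volume(class_id, params, draw)))
            labels.append(label)
    return FeatureMatrix.from_vectors(vectors, labels)
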