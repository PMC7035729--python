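"""Volume and table I/O.

Reads and writes 3D scalar volumes as NIfTI-1 (via nibabel), dataset
manifests (CSV with ``path`` and ``label`` columns) and per-volume feature
tables (CSV).  Volumes are treated as plain voxel lattices: the NIfTI affine
is carried along as provenance metadata but never enters any computation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume3D",
    "DatasetManifest",
    "read_volume",
    "write_volume",
    "load_manifest",
    "write_feature_table",
    "read_feature_table",
]


@dataclass
class Volume3D:
    """A 3D scalar intensity grid.

    Parameters
    ----------
    data:
        3D float array of intensities, indexed ``[x, y, z]`` (0-based).
    mask:
        Optional boolean array of the same shape; ``True`` marks voxels whose
        codes enter a histogram.
    source:
        Free-text provenance (file path, generator settings, ...).
    affine:
        Optional 4x4 voxel-to-world matrix kept as metadata only.
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    source: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume3D requires a 3D array, got shape {self.data.shape}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class DatasetManifest:
    """Ordered (path, label) pairs driving batch feature extraction."""

    paths: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.paths) != len(self.labels):
            raise ValueError("paths and labels must have equal length")
        if len(set(self.paths)) != len(self.paths):
            dupes = sorted({p for p in self.paths if self.paths.count(p) > 1})
            raise ValueError(f"duplicate paths in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.paths)

    @property
    def classes(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def require_two_classes(self) -> tuple[str, str]:
        cls = self.classes
        if len(cls) != 2:
            raise ValueError(
                f"classification requires exactly two classes, found {cls}"
            )
        return cls[0], cls[1]


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Load a single 3D NIfTI volume.

    4D images (time series) are rejected rather than squeezed: the texture
    pipeline is defined on single volumes only.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(path)
    shape = img.shape
    if len(shape) != 3:
        raise ValueError(
            f"expected a 3D image, got shape {shape} from {path}"
        )
    data = np.asarray(img.get_fdata(dtype=np.float64))
    return Volume3D(data=data, source=path, affine=np.asarray(img.affine))


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a Volume3D as NIfTI-1 (.nii or .nii.gz by extension)."""
    affine = vol.affine if vol.affine is not None else np.eye(4)
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    nib.save(img, os.fspath(path))


def load_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Read a manifest CSV with header columns ``path`` and ``label``."""
    df = pd.read_csv(path, dtype=str)
    for col in ("path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} lacks required column '{col}'")
    return DatasetManifest(paths=df["path"].tolist(), labels=df["label"].tolist())


def save_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    pd.DataFrame({"path": manifest.paths, "label": manifest.labels}).to_csv(
        path, index=False
    )


def write_feature_table(matrix, path: str | os.PathLike, *,
                        paths: list[str] | None = None) -> None:
    """Write a FeatureMatrix as CSV: path, label, then one column per feature.

    Values are written with 17 significant digits so a reload agrees to
    better than 1e-12 relative.
    """
    n = matrix.values.shape[0]
    if paths is None:
        paths = [f"row{i}" for i in range(n)]
    if len(paths) != n:
        raise ValueError(
            f"{len(paths)} paths for {n} feature rows: manifest/matrix mismatch"
        )
    cols = [f"f{i:05d}" for i in range(matrix.values.shape[1])]
    df = pd.DataFrame(matrix.values, columns=cols)
    df.insert(0, "label", list(matrix.labels))
    df.insert(0, "path", paths)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | os.PathLike):
    """Reload a feature table CSV -> (FeatureMatrix, paths)."""
    from .features import FeatureMatrix

    df = pd.read_csv(path)
    paths = df["path"].astype(str).tolist()
    labels = df["label"].astype(str).tolist()
    values = df.drop(columns=["path", "label"]).to_numpy(dtype=np.float64)
    return FeatureMatrix(values=values, labels=labels), paths
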