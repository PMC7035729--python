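"""18-neighbour 3D local binary patterns.

Each voxel is compared against the 18 face- and edge-adjacent voxels of its
3x3x3 neighbourhood (the 8 corners are excluded).  Neighbour *i* contributes
bit *i-1* of an 18-bit code; a neighbour at or above the centre intensity
sets its bit (ties count as 1).  Codes are summarised as histograms in three
variants:

``full``
    One bin per code: 2**18 = 262,144 bins.
``uniform``
    A code is *uniform* when, read circularly, it has at most two 0<->1
    transitions.  Each of the 308 uniform codes gets its own bin (ascending
    code order) and all non-uniform codes share a final bin: 309 bins.
``riu``
    Rotation-invariant uniform: uniform codes collapse to their popcount
    (0..18), non-uniform codes share bin 19: 20 bins.  "Rotation" here is
    circular rotation of the 18-bit string, i.e. the code's orbit under
    bit shifts, not a rigid rotation of the voxel neighbourhood.

Neighbour ordering is pinned (lexicographic by (dz, dy, dx)) so that codes,
and hence the full/uniform histograms, are reproducible across runs; the
riu bins depend only on popcount and uniformity and are ordering-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .volio import Volume3D

__all__ = [
    "N_NEIGHBORS",
    "N_CODES",
    "LBPConfig",
    "PatternTable",
    "Histogram",
    "neighbor_offsets",
    "code_at",
    "code_volume",
    "circular_transitions",
    "is_uniform",
    "build_pattern_table",
    "riu2_bin",
    "lbp_histogram",
    "variant_n_bins",
]

N_NEIGHBORS = 18
N_CODES = 1 << N_NEIGHBORS  # 262,144
_CODE_MASK = N_CODES - 1
_VARIANTS = ("full", "uniform", "riu")


def neighbor_offsets() -> list[tuple[int, int, int]]:
    """The 18 neighbour offsets (dx, dy, dz), in their fixed bit order.

    Offsets are the 3x3x3 lattice points excluding the centre and the eight
    corners (at most two nonzero components each), sorted lexicographically
    by (dz, dy, dx).  ``offsets[i]`` owns bit ``i`` of the code.
    """
    offs = [
        (dx, dy, dz)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) < 3
    ]
    assert len(offs) == N_NEIGHBORS
    return offs


@dataclass
class LBPConfig:
    """Configuration of the 3D LBP operator.

    The neighbourhood is fixed (18 neighbours, radius 1); the knobs are the
    histogram variant and whether histograms are normalised to relative
    frequencies (the default, so volumes of different sizes are comparable).
    """

    variant: str = "riu"
    normalize: bool = True
    n_neighbors: int = N_NEIGHBORS
    radius: int = 1
    offsets: list[tuple[int, int, int]] = field(default_factory=neighbor_offsets)

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")
        if self.n_neighbors != N_NEIGHBORS or self.radius != 1:
            raise ValueError("only the 18-neighbour, radius-1 operator is supported")


@dataclass
class PatternTable:
    """Total map from every 18-bit code to its histogram bin."""

    variant: str
    n_bits: int
    code_to_bin: np.ndarray  # shape (2**18,), int32
    n_bins: int


@dataclass
class Histogram:
    bins: np.ndarray
    n_coded: int
    variant: str
    normalized: bool


def variant_n_bins(variant: str) -> int:
    return {"full": N_CODES, "uniform": 309, "riu": 20}[variant]


def _check_code(code: int) -> None:
    if not 0 <= code < N_CODES:
        raise ValueError(f"code {code} outside [0, {N_CODES - 1}]")


def circular_transitions(code: int) -> int:
    """Number of 0<->1 changes reading the 18 bits circularly (always even)."""
    _check_code(code)
    rot = ((code >> 1) | ((code & 1) << (N_NEIGHBORS - 1))) & _CODE_MASK
    return int(code ^ rot).bit_count()

def is_uniform(code: int) -> bool:
    """True iff the code has at most two circular bit transitions."""
    return circular_transitions(code) <= 2


@lru_cache(maxsize=None)
def _tables() -> dict[str, np.ndarray]:
    codes = np.arange(N_CODES, dtype=np.uint32)
    rot = ((codes >> 1) | ((codes & 1) << (N_NEIGHBORS - 1))) & _CODE_MASK
    trans = np.bitwise_count(codes ^ rot)
    popcount = np.bitwise_count(codes)
    uniform = trans <= 2
    riu = np.where(uniform, popcount, 19).astype(np.int32)
    # uniform variant: uniform codes in ascending code order, shared last bin
    rank = np.cumsum(uniform) - 1
    n_uniform = int(uniform.sum())  # 18*17 + 2 = 308
    uni = np.where(uniform, rank, n_uniform).astype(np.int32)
    return {"riu": riu, "uniform": uni, "_n_uniform": np.int64(n_uniform)}


def build_pattern_table(variant: str) -> PatternTable:
    """Bin map over all 262,144 codes for the uniform or riu variant."""
    if variant not in ("uniform", "riu"):
        raise ValueError(f"pattern tables exist for 'uniform' and 'riu', got {variant!r}")
    t = _tables()
    table = t[variant]
    n_bins = int(t["_n_uniform"]) + 1 if variant == "uniform" else 20
    return PatternTable(variant=variant, n_bits=N_NEIGHBORS,
                        code_to_bin=table, n_bins=n_bins)


def riu2_bin(code: int) -> int:
    """Rotation-invariant-uniform bin: popcount if uniform, else 19."""
    _check_code(code)
    return int(code).bit_count() if is_uniform(code) else 19


def code_at(vol: Volume3D, voxel: tuple[int, int, int],
            cfg: LBPConfig | None = None) -> int:
    """18-bit code of one voxel; its whole neighbourhood must be in-volume."""
    cfg = cfg or LBPConfig()
    x, y, z = voxel
    dims = vol.dims
    if not all(1 <= v <= d - 2 for v, d in zip((x, y, z), dims)):
        raise IndexError(
            f"voxel {voxel} has neighbours outside volume of dims {dims}"
        )
    centre = vol.data[x, y, z]
    code = 0
    for i, (dx, dy, dz) in enumerate(cfg.offsets):
        if vol.data[x + dx, y + dy, z + dz] - centre >= 0:
            code |= 1 << i
    return code


def code_volume(vol: Volume3D, cfg: LBPConfig | None = None) -> np.ndarray:
    """Codes of all interior voxels, shape (A-2, B-2, C-2), int32."""
    cfg = cfg or LBPConfig()
    a, b, c = vol.dims
    if min(a, b, c) < 3:
        raise ValueError(f"volume dims {vol.dims} too small for a 3x3x3 neighbourhood")
    data = vol.data
    centre = data[1 : a - 1, 1 : b - 1, 1 : c - 1]
    codes = np.zeros(centre.shape, dtype=np.int32)
    for i, (dx, dy, dz) in enumerate(cfg.offsets):
        nb = data[1 + dx : a - 1 + dx, 1 + dy : b - 1 + dy, 1 + dz : c - 1 + dz]
        codes |= (nb >= centre).astype(np.int32) << i
    return codes


def lbp_histogram(vol: Volume3D, cfg: LBPConfig | None = None) -> Histogram:
    """Histogram of interior-voxel codes under the configured variant.

    Boundary voxels (incomplete neighbourhoods) are skipped, never padded.
    If the volume carries a mask, only voxels whose *centre* is inside the
    mask are coded; neighbours may lie outside the mask but not the volume.
    """
    cfg = cfg or LBPConfig()
    codes = code_volume(vol, cfg)
    if vol.mask is not None:
        sel = vol.mask[1:-1, 1:-1, 1:-1]
        flat = codes[sel]
    else:
        flat = codes.ravel()
    n_coded = flat.size
    if n_coded == 0:
        raise ValueError("no voxels to code (mask excludes the whole interior)")
    if cfg.variant == "full":
        bins = np.bincount(flat, minlength=N_CODES).astype(np.float64)
    else:
        table = build_pattern_table(cfg.variant)
        bins = np.bincount(table.code_to_bin[flat],
                           minlength=table.n_bins).astype(np.float64)
    if cfg.normalize:
        bins /= n_coded
    return Histogram(bins=bins, n_coded=int(n_coded), variant=cfg.variant,
                     normalized=cfg.normalize)
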