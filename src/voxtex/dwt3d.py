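"""Level-1 separable 3D discrete wavelet transform.

One analysis level splits a volume into one approximation subband (low-pass
along every axis) and seven detail subbands, one per combination of low/high
filtering over the three axes with at least one high-pass factor.  Detail
subbands are kept in the fixed order

    HLL, LHL, HHL, LLH, HLH, LHH, HHH

where letter *i* gives the filter applied along axis *i* (``L`` = scaling /
low-pass, ``H`` = wavelet / high-pass).  This ordering is load-bearing: the
combined texture descriptor concatenates per-subband histograms in it.

Filters are the orthonormal Daubechies family (db1–db4), hardcoded; the
default is db2 (4 taps).  Three boundary extension modes are supported:

``symmetric``
    Half-point mirror extension, the default for image data.  Subbands are
    slightly redundant (length ``floor((n + L - 1)/2)`` per axis) and
    reconstruction is exact after cropping.
``zero``
    Zero padding; same sizes as ``symmetric``.
``periodization``
    Circular, non-redundant transform (length ``n/2`` per axis, even dims
    required).  The transform matrix is orthogonal, so energy is conserved
    exactly and reconstruction is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volio import Volume3D

__all__ = [
    "SubbandSet",
    "decompose_level1",
    "reconstruct",
    "subband_labels",
    "wavelet_filters",
    "DETAIL_LABELS",
    "EXTENSION_MODES",
]

# Orthonormal scaling (reconstruction low-pass) filters.  sum = sqrt(2),
# sum of squares = 1.
_REC_LO = {
    "db1": [0.7071067811865476, 0.7071067811865476],
    "haar": [0.7071067811865476, 0.7071067811865476],
    "db2": [
        0.48296291314469025,
        0.8365163037378079,
        0.22414386804185735,
        -0.12940952255126037,
    ],
    "db3": [
        0.3326705529509569,
        0.8068915093133388,
        0.4598775021193313,
        -0.13501102001039084,
        -0.08544127388224149,
        0.035226291882100656,
    ],
    "db4": [
        0.23037781330885523,
        0.7148465705525415,
        0.6308807679295904,
        -0.02798376941698385,
        -0.18703481171888114,
        0.030841381835986965,
        0.032883011666982945,
        -0.010597401784997278,
    ],
}

EXTENSION_MODES = ("symmetric", "zero", "periodization")

# Detail order: lexicographic over (axis0, axis1, axis2) in {L, H} with H
# advancing axis-by-axis, excluding LLL (the approximation).
DETAIL_LABELS = ("HLL", "LHL", "HHL", "LLH", "HLH", "LHH", "HHH")


def wavelet_filters(name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (dec_lo, dec_hi, rec_lo, rec_hi) for a named wavelet."""
    try:
        rec_lo = np.asarray(_REC_LO[name], dtype=np.float64)
    except KeyError:
        raise ValueError(
            f"unknown wavelet {name!r}; available: {sorted(set(_REC_LO))}"
        ) from None
    dec_lo = rec_lo[::-1].copy()
    signs = (-1.0) ** np.arange(len(rec_lo))
    rec_hi = signs * dec_lo
    dec_hi = rec_hi[::-1].copy()
    return dec_lo, dec_hi, rec_lo, rec_hi


def subband_labels() -> list[str]:
    """The seven detail-subband labels in their fixed order.

    The first entry, ``HLL``, is the subband that is high-pass along the
    first axis and low-pass along the other two; ``LLL`` (the approximation)
    is deliberately absent.
    """
    return list(DETAIL_LABELS)


@dataclass
class SubbandSet:
    """Output of one 3D analysis level: approximation + 7 details."""

    approx: Volume3D
    details: list[Volume3D]
    orientation_labels: tuple[str, ...]
    wavelet_name: str
    extension_mode: str
    input_dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.details) != 7:
            raise ValueError(f"expected 7 detail subbands, got {len(self.details)}")
        shapes = {d.data.shape for d in self.details} | {self.approx.data.shape}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent subband dims: {sorted(shapes)}")

    @property
    def subband_dims(self) -> tuple[int, int, int]:
        return self.approx.dims


# ---------------------------------------------------------------------------
# 1D building blocks (operate along the last axis)

def _conv_valid_corr(ext: np.ndarray, filt: np.ndarray) -> np.ndarray:
    # y[t] = sum_j ext[t + j] * filt_reversed[j]  (np.convolve semantics)
    L = len(filt)
    n_out = ext.shape[-1] - L + 1
    rev = filt[::-1]
    y = np.zeros(ext.shape[:-1] + (n_out,), dtype=np.float64)
    for j in range(L):
        y += rev[j] * ext[..., j : j + n_out]
    return y


def _upconv_full(coef: np.ndarray, filt: np.ndarray) -> np.ndarray:
    # zero-upsample by 2 then full convolution with filt
    m = coef.shape[-1]
    L = len(filt)
    up = np.zeros(coef.shape[:-1] + (2 * m,), dtype=np.float64)
    up[..., ::2] = coef
    out = np.zeros(coef.shape[:-1] + (2 * m + L - 1,), dtype=np.float64)
    for j in range(L):
        out[..., j : j + 2 * m] += filt[j] * up
    return out


def _dwt1d(x: np.ndarray, dec_lo: np.ndarray, dec_hi: np.ndarray,
           mode: str) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[-1]
    L = len(dec_lo)
    if mode == "periodization":
        if n % 2:
            raise ValueError(
                f"periodization mode needs even axis lengths, got {n}"
            )
        w_lo, w_hi = _periodization_rows(n, dec_lo, dec_hi)
        return x @ w_lo.T, x @ w_hi.T
    pad = L - 1
    if mode == "symmetric":
        ext = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="symmetric")
    elif mode == "zero":
        ext = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="constant")
    else:
        raise ValueError(
            f"unknown extension mode {mode!r}; available: {EXTENSION_MODES}"
        )
    full = _conv_valid_corr(ext, dec_lo), _conv_valid_corr(ext, dec_hi)
    return full[0][..., 1::2], full[1][..., 1::2]


def _periodization_rows(n: int, dec_lo: np.ndarray,
                        dec_hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Rows are even circular shifts of the analysis filters; the stacked
    # (n x n) operator is orthogonal for orthonormal filter pairs.
    L = len(dec_lo)
    m = n // 2
    w_lo = np.zeros((m, n))
    w_hi = np.zeros((m, n))
    for k in range(m):
        cols = (2 * k + np.arange(L)) % n
        np.add.at(w_lo[k], cols, dec_lo)
        np.add.at(w_hi[k], cols, dec_hi)
    return w_lo, w_hi


def _idwt1d(ca: np.ndarray, cd: np.ndarray, rec_lo: np.ndarray,
            rec_hi: np.ndarray, mode: str, n_out: int) -> np.ndarray:
    if ca.shape != cd.shape:
        raise ValueError(
            f"approximation/detail shapes differ: {ca.shape} vs {cd.shape}"
        )
    L = len(rec_lo)
    if mode == "periodization":
        dec_lo = rec_lo[::-1]
        dec_hi = rec_hi[::-1]
        n = 2 * ca.shape[-1]
        w_lo, w_hi = _periodization_rows(n, dec_lo, dec_hi)
        out = ca @ w_lo + cd @ w_hi
        return out[..., :n_out]
    full = _upconv_full(ca, rec_lo) + _upconv_full(cd, rec_hi)
    start = L - 2
    return full[..., start : start + n_out]


def _apply_axis(func, x: np.ndarray, axis: int, *args):
    moved = np.moveaxis(x, axis, -1)
    res = func(moved, *args)
    if isinstance(res, tuple):
        return tuple(np.moveaxis(r, -1, axis) for r in res)
    return np.moveaxis(res, -1, axis)


# ---------------------------------------------------------------------------
# public 3D API

def decompose_level1(vol: Volume3D, wavelet_name: str = "db2",
                     extension_mode: str = "symmetric") -> SubbandSet:
    """One separable analysis level: 1 approximation + 7 detail subbands.

    Each axis of the volume is split by the wavelet's low-pass (scaling) and
    high-pass filters followed by dyadic downsampling; the eight subbands are
    the tensor combinations of the two branches over the three axes.  Every
    axis of ``vol`` must be at least as long as the filter.
    """
    if extension_mode not in EXTENSION_MODES:
        raise ValueError(
            f"unknown extension mode {extension_mode!r}; available: {EXTENSION_MODES}"
        )
    dec_lo, dec_hi, _, _ = wavelet_filters(wavelet_name)
    x = vol.data
    L = len(dec_lo)
    if min(x.shape) < L:
        raise ValueError(
            f"volume dims {x.shape} smaller than the {L}-tap {wavelet_name} filter"
        )

    bands: dict[str, np.ndarray] = {"": x}
    for axis in range(3):
        new: dict[str, np.ndarray] = {}
        for key, arr in bands.items():
            lo, hi = _apply_axis(_dwt1d, arr, axis, dec_lo, dec_hi, extension_mode)
            new[key + "L"] = lo
            new[key + "H"] = hi
        bands = new

    def wrap(key: str) -> Volume3D:
        return Volume3D(
            data=bands[key],
            source=(
                f"{vol.source}|dwt3d level1 {wavelet_name}/{extension_mode} {key}"
            ),
        )

    return SubbandSet(
        approx=wrap("LLL"),
        details=[wrap(k) for k in DETAIL_LABELS],
        orientation_labels=DETAIL_LABELS,
        wavelet_name=wavelet_name,
        extension_mode=extension_mode,
        input_dims=vol.dims,
    )


def reconstruct(sb: SubbandSet, target_dims: tuple[int, int, int] | None = None) -> Volume3D:
    """Inverse level-1 transform, cropped to ``target_dims``.

    With the dims the forward transform consumed this is a perfect inverse
    (up to floating round-off) for every supported extension mode.
    """
    if target_dims is None:
        target_dims = sb.input_dims
    _, _, rec_lo, rec_hi = wavelet_filters(sb.wavelet_name)
    mode = sb.extension_mode

    bands = {"LLL": sb.approx.data}
    for lab, det in zip(sb.orientation_labels, sb.details):
        bands[lab] = det.data

    # invert axes in reverse order; crop each axis to the length the forward
    # pass saw at that stage
    for axis in (2, 1, 0):
        n_out = target_dims[axis]
        new: dict[str, np.ndarray] = {}
        for prefix in sorted({k[:axis] for k in bands}):
            ca_m = np.moveaxis(bands[prefix + "L"], axis, -1)
            cd_m = np.moveaxis(bands[prefix + "H"], axis, -1)
            out = _idwt1d(ca_m, cd_m, rec_lo, rec_hi, mode, n_out)
            new[prefix] = np.moveaxis(out, -1, axis)
        bands = new

    return Volume3D(data=bands[""], source=f"reconstructed|{sb.wavelet_name}/{mode}")
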