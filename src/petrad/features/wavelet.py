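"""Undecimated separable coiflet-1 decomposition and per-subband features.

Each of the 8 subbands is the separable 3D filtering of the input with the
per-axis low (L) / high (H) pass coiflet-1 decomposition filters, without
downsampling, so every subband keeps the input's grid shape and the VOI mask
applies unchanged. The output at voxel (i,j,k) is the filter-weighted sum of
the input at (i+n, j+m, k+r) for taps n,m,r = 1..R (R = 6 for coiflet 1);
values past the grid are supplied by symmetric reflection. Subband labels
give the filter per axis in (x, y, z) order, e.g. HLH = high-pass along x,
low-pass along y, high-pass along z. The high-pass filter sums to zero, so
any H-containing subband of a constant volume vanishes.
"""

from __future__ import annotations

import numpy as np
import pywt

from .first_order import first_order_features
from .texture import texture_features

__all__ = ["SUBBAND_NAMES", "wavelet_decompose", "wavelet_feature_block"]

SUBBAND_NAMES = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]

# 6-tap coiflet-1 decomposition pair, taken from PyWavelets
_COIF1 = pywt.Wavelet("coif1")
DEC_LO = np.asarray(_COIF1.dec_lo, dtype=np.float64)
DEC_HI = np.asarray(_COIF1.dec_hi, dtype=np.float64)


def _filter_axis(x: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """y[i] = sum_{n=1..R} taps[n-1] * x_ext(i+n) along one axis.

    The window sits entirely on the positive side of i; symmetric reflection
    extends the grid past its upper edge.
    """
    r = len(taps)
    n = x.shape[axis]
    if n < r:
        raise ValueError(
            f"volume extent {n} along axis {axis} is smaller than the "
            f"filter length {r}"
        )
    pad = [(0, 0)] * x.ndim
    pad[axis] = (0, r)
    xp = np.pad(x, pad, mode="symmetric")
    y = np.zeros_like(x, dtype=np.float64)
    idx = [slice(None)] * x.ndim
    for k in range(r):
        idx[axis] = slice(k + 1, k + 1 + n)
        y += taps[k] * xp[tuple(idx)]
    return y


def wavelet_decompose(volume) -> dict[str, np.ndarray]:
    """Decompose a 3D grid into the 8 undecimated coiflet-1 subbands.

    Accepts an :class:`~petrad.volume_io.SUVVolume` or a raw 3D array and
    returns ``{"LLL": array, ..., "HHH": array}``, each the input's shape.
    """
    x = volume.values if hasattr(volume, "values") else np.asarray(volume)
    x = x.astype(np.float64)
    if x.ndim != 3:
        raise ValueError(f"expected 3D volume, got {x.ndim}D")
    filters = {"L": DEC_LO, "H": DEC_HI}
    # filter once per axis per letter, then combine
    partial = {"": x}
    for axis in range(3):
        nxt = {}
        for label, arr in partial.items():
            for letter, taps in filters.items():
                nxt[label + letter] = _filter_axis(arr, taps, axis)
        partial = nxt
    return {name: partial[name] for name in SUBBAND_NAMES}


def wavelet_feature_block(voi_volume, mask=None, bin_width: float = 0.1) -> dict[str, float]:
    """First-order + textural features of every subband: 8 x 48 = 384 values.

    Subbands can be negative, so texture/histogram binning is re-anchored at
    each subband's masked minimum. Names are suffixed with the subband label
    (e.g. ``energy_HHL``).
    """
    if hasattr(voi_volume, "mask"):  # VOI
        mask = voi_volume.mask
        values = voi_volume.suv
    else:
        values = np.asarray(voi_volume, dtype=np.float64)
        if mask is None:
            raise ValueError("mask required when passing a raw array")
        mask = np.asarray(mask, dtype=bool)

    class _MaskedBand:
        def __init__(self, suv, mask):
            self.suv = suv
            self.mask = mask
            self.masked_values = suv[mask]

    # pad the VOI bounding box by the filter length (symmetric reflection)
    # before filtering, so boxes smaller than the filter support still work
    r = len(DEC_LO)
    padded = np.pad(values, r, mode="symmetric")
    crop = tuple(slice(r, r + s) for s in values.shape)

    # subband content below double-precision accumulation noise (e.g. the
    # high-pass response of a constant region) is treated as exactly zero,
    # so scale-free statistics are not computed on rounding dust
    noise_floor = 1e-10 * max(1.0, float(np.abs(values).max()))

    out: dict[str, float] = {}
    for band, sub_p in wavelet_decompose(padded).items():
        sub = sub_p[crop]
        if np.abs(sub[mask]).max() < noise_floor:
            sub = np.zeros_like(sub)
        voi_band = _MaskedBand(sub, mask)
        for name, value in first_order_features(voi_band.masked_values, bin_width).items():
            out[f"{name}_{band}"] = value
        for name, value in texture_features(voi_band, bin_width).items():
            out[f"{name}_{band}"] = value
    assert len(out) == 384, f"wavelet block must have 384 features, got {len(out)}"
    return out
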