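"""Radiomic feature extraction: 440 features per VOI per timepoint.

The panel is 14 first-order statistics + 8 shape/size features + 34 textural
features (23 co-occurrence, 11 run-length) computed on the original SUV
image, plus the same 14 + 34 on each of the 8 undecimated coiflet-1 wavelet
subbands (384 wavelet features).
"""

from __future__ import annotations

from ..volume_io import VOI
from .first_order import FIRST_ORDER_NAMES, DegenerateFeatureWarning, first_order_features
from .shape import SHAPE_NAMES, max_3d_diameter, shape_features, surface_area
from .texture import (
    DIRECTIONS_13,
    GLCM,
    GLCM_NAMES,
    GLRLM,
    GLRLM_NAMES,
    compute_glcm,
    compute_glrlm,
    discretize,
    glcm_features,
    glrlm_features,
    texture_features,
)
from .wavelet import SUBBAND_NAMES, wavelet_decompose, wavelet_feature_block

__all__ = [
    "FIRST_ORDER_NAMES",
    "SHAPE_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "SUBBAND_NAMES",
    "DIRECTIONS_13",
    "GLCM",
    "GLRLM",
    "DegenerateFeatureWarning",
    "first_order_features",
    "shape_features",
    "surface_area",
    "max_3d_diameter",
    "discretize",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "texture_features",
    "wavelet_decompose",
    "wavelet_feature_block",
    "extract_features",
    "feature_names",
]


def extract_features(voi: VOI, bin_width: float = 0.1) -> dict[str, float]:
    """All 440 radiomic features of one VOI at one timepoint."""
    out: dict[str, float] = {}
    out.update(first_order_features(voi.masked_values, bin_width))
    out.update(shape_features(voi))
    out.update(texture_features(voi, bin_width))
    out.update(wavelet_feature_block(voi, bin_width=bin_width))
    assert len(out) == 440, f"expected 440 features, got {len(out)}"
    return out


def feature_names() -> list[str]:
    """The 440 feature names in extraction order."""
    names = list(FIRST_ORDER_NAMES) + list(SHAPE_NAMES)
    names += GLCM_NAMES + GLRLM_NAMES
    for band in SUBBAND_NAMES:
        names += [f"{n}_{band}" for n in FIRST_ORDER_NAMES]
        names += [f"{n}_{band}" for n in GLCM_NAMES + GLRLM_NAMES]
    return names
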