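"""Gray-level co-occurrence and run-length texture features.

Intensities inside the VOI are discretized with a fixed bin width (0.1 SUV
by default), bins anchored at the VOI minimum, so features are invariant to
adding a constant to all intensities. Both matrices pool the 13 unique 3D
directions at Chebyshev distance 1 into a single matrix before features are
computed; the GLCM additionally counts each pair in both directions
(symmetrization) and uses an inter-voxel distance of 1 voxel by default.
Logs are base 2 with the 0*log(0) = 0 convention.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "DIRECTIONS_13",
    "GLCM",
    "GLRLM",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "discretize",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "texture_features",
]

#: the 13 unique 3D directions at Chebyshev distance 1 (up to sign)
DIRECTIONS_13 = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

GLCM_NAMES = [
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_entropy",
    "dissimilarity",
    "difference_variance",
    "energy_c",
    "entropy_c",
    "homogeneity_1",
    "homogeneity_2",
    "imc1",
    "imc2",
    "idmn",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "variance_c",
]

GLRLM_NAMES = [
    "sre",
    "lre",
    "gln",
    "rln",
    "rp",
    "lglre",
    "hglre",
    "srlgle",
    "srhgle",
    "lrlgle",
    "lrhgle",
]


@dataclasses.dataclass(frozen=True)
class GLCM:
    """Symmetric, normalized gray-level co-occurrence matrix."""

    matrix: np.ndarray  # (N_g, N_g) joint probabilities
    offsets: tuple = DIRECTIONS_13

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("GLCM must be square")
        if (m < 0).any():
            raise ValueError("GLCM entries must be non-negative")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM must be normalized to sum 1")
        if not np.array_equal(m, m.T):
            raise ValueError("GLCM must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def n_levels(self) -> int:
        return self.matrix.shape[0]


@dataclasses.dataclass(frozen=True)
class GLRLM:
    """Gray-level run-length matrix of raw run counts summed over directions."""

    matrix: np.ndarray  # (N_g, max_run_length) counts
    directions: tuple = DIRECTIONS_13

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2:
            raise ValueError("GLRLM must be 2D")
        if (m < 0).any():
            raise ValueError("GLRLM entries must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def n_runs(self) -> float:
        return float(self.matrix.sum())


def discretize(voi_or_values, mask=None, bin_width: float = 0.1) -> np.ndarray:
    """Map masked intensities to integer levels 1..N_g; 0 marks out-of-mask.

    ``level(v) = floor((v - min) / bin_width) + 1`` with the minimum taken
    over masked voxels only.
    """
    if hasattr(voi_or_values, "mask"):  # VOI
        values = voi_or_values.suv
        mask = voi_or_values.mask
    else:
        values = np.asarray(voi_or_values, dtype=np.float64)
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    if not mask.any():
        raise ValueError("empty VOI")
    values = np.asarray(values, dtype=np.float64)
    vmin = values[mask].min()
    levels = np.zeros(values.shape, dtype=np.int64)
    levels[mask] = np.floor((values[mask] - vmin) / bin_width).astype(np.int64) + 1
    return levels


def _shift_slices(shape, d):
    """Source/destination slice pairs for offset d on a grid of given shape."""
    src, dst = [], []
    for axis, step in enumerate(d):
        n = shape[axis]
        if step == 0:
            src.append(slice(0, n))
            dst.append(slice(0, n))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def compute_glcm(
    levels: np.ndarray,
    mask: np.ndarray | None = None,
    offsets=DIRECTIONS_13,
    distance: int = 1,
) -> GLCM:
    """Count in-mask voxel pairs over all offsets, symmetrize and normalize."""
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    else:
        levels = np.where(np.asarray(mask, dtype=bool), levels, 0)
    n_g = int(levels.max())
    if n_g < 1:
        raise ValueError("no masked voxels")
    counts = np.zeros((n_g, n_g), dtype=np.float64)
    for d in offsets:
        dd = tuple(int(c) * distance for c in d)
        src, dst = _shift_slices(levels.shape, dd)
        a = levels[src].ravel()
        b = levels[dst].ravel()
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        flat = np.bincount(
            (a[valid] - 1) * n_g + (b[valid] - 1), minlength=n_g * n_g
        )
        counts += flat.reshape(n_g, n_g)
    counts = counts + counts.T  # symmetrize: count each pair in both directions
    total = counts.sum()
    if total == 0:
        raise ValueError(
            "no valid in-mask voxel pairs; the VOI must contain at least one "
            "neighboring pair of masked voxels"
        )
    return GLCM(matrix=counts / total, offsets=tuple(offsets))


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def glcm_features(glcm: GLCM) -> dict[str, float]:
    """The 23 co-occurrence (Haralick-family) features of a normalized GLCM.

    A single-level (degenerate) matrix takes the homogeneous limits:
    contrast 0, energy 1, entropy 0, and correlation 1 (a constant region is
    perfectly correlated with its neighborhood).
    """
    p = glcm.matrix
    n_g = glcm.n_levels
    i = np.arange(1, n_g + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)  # symmetric: px == py
    mu_x = float((i * px).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    sigma_x = np.sqrt(var_x)

    # sum and difference histograms
    sum_idx = (ii + jj).astype(np.int64).ravel()
    p_sum = np.bincount(sum_idx, weights=p.ravel(), minlength=2 * n_g + 1)[2:]
    k_sum = np.arange(2, 2 * n_g + 1, dtype=np.float64)
    diff_idx = np.abs(ii - jj).astype(np.int64).ravel()
    p_diff = np.bincount(diff_idx, weights=p.ravel(), minlength=n_g)
    k_diff = np.arange(0, n_g, dtype=np.float64)

    autocorrelation = float((ii * jj * p).sum())
    cluster = ii + jj - 2.0 * mu_x
    contrast = float(((ii - jj) ** 2 * p).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    energy = float((p**2).sum())
    entropy = _entropy2(p.ravel())

    if sigma_x > 0:
        correlation = (autocorrelation - mu_x * mu_x) / (sigma_x * sigma_x)
    else:
        correlation = 1.0  # homogeneous limit

    sum_average = float((k_sum * p_sum).sum())
    sum_entropy = _entropy2(p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    diff_average = float((k_diff * p_diff).sum())
    difference_entropy = _entropy2(p_diff)
    difference_variance = float(((k_diff - diff_average) ** 2 * p_diff).sum())

    # informational measures of correlation from joint and marginal entropies
    hx = _entropy2(px)
    pxpy = np.outer(px, px)
    joint_nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[joint_nz] * np.log2(pxpy[joint_nz])).sum())
    hxy2 = _entropy2(pxpy.ravel())
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    abs_diff = np.abs(ii - jj)
    off_diag = abs_diff > 0
    inverse_variance = float((p[off_diag] / abs_diff[off_diag] ** 2).sum())

    return {
        "autocorrelation": autocorrelation,
        "cluster_prominence": float((cluster**4 * p).sum()),
        "cluster_shade": float((cluster**3 * p).sum()),
        "cluster_tendency": float((cluster**2 * p).sum()),
        "contrast": contrast,
        "correlation": float(correlation),
        "difference_entropy": difference_entropy,
        "dissimilarity": dissimilarity,
        "difference_variance": difference_variance,
        "energy_c": energy,
        "entropy_c": entropy,
        "homogeneity_1": float((p / (1.0 + abs_diff)).sum()),
        "homogeneity_2": float((p / (1.0 + abs_diff**2)).sum()),
        "imc1": float(imc1),
        "imc2": imc2,
        "idmn": float((p / (1.0 + (abs_diff / n_g) ** 2)).sum()),
        "idn": float((p / (1.0 + abs_diff / n_g)).sum()),
        "inverse_variance": inverse_variance,
        "maximum_probability": float(p.max()),
        "sum_average": sum_average,
        "sum_entropy": sum_entropy,
        "sum_variance": sum_variance,
        "variance_c": float(((ii - mu_x) ** 2 * p).sum()),
    }


def compute_glrlm(
    levels: np.ndarray,
    mask: np.ndarray | None = None,
    directions=DIRECTIONS_13,
) -> GLRLM:
    """Count maximal runs of equal level along each direction and sum them.

    A run is a maximal set of collinear in-mask voxels sharing a discretized
    level; out-of-mask voxels break runs.
    """
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    else:
        levels = np.where(np.asarray(mask, dtype=bool), levels, 0)
    n_g = int(levels.max())
    if n_g < 1:
        raise ValueError("no masked voxels")
    shape = np.array(levels.shape)
    max_len = int(np.ceil(np.sqrt((shape.astype(float) ** 2).sum()))) + 1
    counts = np.zeros((n_g, max_len), dtype=np.float64)

    coords = np.argwhere(levels > 0)
    vals = levels[levels > 0]
    for d in directions:
        dv = np.asarray(d, dtype=np.int64)
        # run starts: predecessor out of grid, out of mask, or different level
        prev = coords - dv
        inside = np.all((prev >= 0) & (prev < shape), axis=1)
        prev_level = np.zeros(len(coords), dtype=np.int64)
        prev_level[inside] = levels[tuple(prev[inside].T)]
        start = prev_level != vals
        cur = coords[start]
        level = vals[start]
        length = np.ones(len(cur), dtype=np.int64)
        alive = np.ones(len(cur), dtype=bool)
        while alive.any():
            nxt = cur[alive] + dv
            ok = np.all((nxt >= 0) & (nxt < shape), axis=1)
            same = np.zeros(len(nxt), dtype=bool)
            if ok.any():
                same[ok] = levels[tuple(nxt[ok].T)] == level[alive][ok]
            idx = np.flatnonzero(alive)
            ended = idx[~same]
            np.add.at(counts, (level[ended] - 1, length[ended] - 1), 1.0)
            cont = idx[same]
            cur[cont] += dv
            length[cont] += 1
            alive = np.zeros(len(cur), dtype=bool)
            alive[cont] = True
    # trim trailing all-zero run-length columns (keep at least one)
    nz = np.nonzero(counts.sum(axis=0))[0]
    counts = counts[:, : (nz.max() + 1 if len(nz) else 1)]
    return GLRLM(matrix=counts, directions=tuple(directions))


def glrlm_features(glrlm: GLRLM, n_voxels: int) -> dict[str, float]:
    """The 11 run-length features; run percentage = total runs / n_voxels."""
    r = glrlm.matrix
    n_runs = r.sum()
    if n_runs <= 0:
        raise ValueError("GLRLM contains no runs")
    n_g, max_j = r.shape
    i = np.arange(1, n_g + 1, dtype=np.float64)[:, None]
    j = np.arange(1, max_j + 1, dtype=np.float64)[None, :]
    r_g = r.sum(axis=1)  # per gray level
    r_l = r.sum(axis=0)  # per run length
    return {
        "sre": float((r / j**2).sum() / n_runs),
        "lre": float((r * j**2).sum() / n_runs),
        "gln": float((r_g**2).sum() / n_runs),
        "rln": float((r_l**2).sum() / n_runs),
        "rp": float(n_runs / n_voxels),
        "lglre": float((r / i**2).sum() / n_runs),
        "hglre": float((r * i**2).sum() / n_runs),
        "srlgle": float((r / (i**2 * j**2)).sum() / n_runs),
        "srhgle": float((r * i**2 / j**2).sum() / n_runs),
        "lrlgle": float((r * j**2 / i**2).sum() / n_runs),
        "lrhgle": float((r * i**2 * j**2).sum() / n_runs),
    }


def texture_features(voi, bin_width: float = 0.1) -> dict[str, float]:
    """The 34 textural features (23 GLCM + 11 GLRLM) of a VOI."""
    levels = discretize(voi, bin_width=bin_width)
    glcm = compute_glcm(levels)
    glrlm = compute_glrlm(levels)
    out = glcm_features(glcm)
    out.update(glrlm_features(glrlm, n_voxels=int((levels > 0).sum())))
    return out
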