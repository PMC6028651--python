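"""Synthetic PET cohorts with the statistical structure the pipeline assumes.

The generator emulates a 30-patient esophageal-cancer cohort with 7 local
progressions and 23 controls: paired pre-/mid-treatment SUV volumes with an
ellipsoidal primary-tumor VOI, class-dependent uptake and intratumoral
texture (a spatially correlated Gaussian field whose correlation length
differs by outcome), a class-dependent mid-treatment response factor, and
exponential event times whose rates differ by the configured hazard ratio.
Clinical covariates are drawn from the cohort's marginal distributions and
carry no planted outcome signal, so any synthetic predictive performance
must come from the image features.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import PatientRecord, SUVVolume, VOIMask

__all__ = [
    "CohortConfig",
    "generate_tumor",
    "generate_records",
    "generate_cohort",
    "sample_exponential_times",
]


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Per-class pairs are ordered (local control, local progression). Lengths
    are mm, uptake is SUV (g/mL), times are months.
    """

    n_patients: int = 30
    n_progression: int = 7
    grid_size: int = 32
    spacing: float = 4.0
    tumor_radius_range: tuple[float, float] = (8.0, 16.0)
    background_suv: float = 1.0
    tumor_suv_mean: tuple[float, float] = (6.0, 7.0)
    texture_correlation_length: tuple[float, float] = (3.0, 9.0)
    texture_amplitude: float = 1.5
    noise_sd: float = 0.3
    mid_crt_response_factor: tuple[float, float] = (0.4, 0.85)
    hazard_ratio: float = 8.0
    censor_rate: float = 0.2
    pfs_median_low_risk: float = 24.0
    lc_median_progression: float = 6.0
    followup_range: tuple[float, float] = (6.0, 48.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_progression < self.n_patients:
            raise ValueError("need 0 < n_progression < n_patients")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor rate must be in [0, 1]")
        for name in ("spacing", "texture_amplitude", "noise_sd"):
            if getattr(self, name) < 0 or (name == "spacing" and self.spacing == 0):
                raise ValueError(f"{name} must be positive")
        if min(self.tumor_radius_range) <= 0:
            raise ValueError("tumor radii must be positive")


def _tumor_fields(config: CohortConfig, class_label: int, rng: np.random.Generator):
    """Mask, noiseless tumor image and the pre-treatment noise draw."""
    n = config.grid_size
    semi_axes_mm = rng.uniform(*sorted(config.tumor_radius_range), size=3)
    semi_axes = semi_axes_mm / config.spacing
    if np.any(semi_axes >= n / 2):
        raise ValueError(
            f"tumor semi-axes {semi_axes_mm} mm exceed the "
            f"{n * config.spacing} mm grid"
        )
    center = (n - 1) / 2.0
    coords = np.indices((n, n, n), dtype=np.float64) - center
    mask = (coords[0] / semi_axes[0]) ** 2 + (coords[1] / semi_axes[1]) ** 2 + (
        coords[2] / semi_axes[2]
    ) ** 2 <= 1.0

    corr_len = config.texture_correlation_length[class_label]
    white = rng.normal(size=(n, n, n))
    if config.texture_amplitude > 0 and corr_len > 0:
        field = gaussian_filter(white, sigma=corr_len / config.spacing)
        sd = field.std()
        if sd > 0:
            field = field / sd
        field *= config.texture_amplitude
    else:
        field = np.zeros((n, n, n))

    mean = config.tumor_suv_mean[class_label]
    noiseless = np.full((n, n, n), config.background_suv)
    noiseless[mask] = mean + field[mask]
    noise = rng.normal(0.0, config.noise_sd, size=(n, n, n)) if config.noise_sd > 0 else np.zeros((n, n, n))
    return mask, noiseless, noise


def generate_tumor(
    config: CohortConfig, class_label: int, rng: np.random.Generator
) -> tuple[SUVVolume, VOIMask]:
    """One pre-treatment tumor volume and its VOI mask.

    Tumor voxels are the class mean plus a correlated Gaussian texture field
    plus independent voxel noise; the background is flat; SUV is clipped at 0.
    """
    mask, noiseless, noise = _tumor_fields(config, class_label, rng)
    values = noiseless.copy()
    values[mask] += noise[mask]
    np.clip(values, 0.0, None, out=values)
    spacing = (config.spacing,) * 3
    return SUVVolume(values, spacing), VOIMask(mask.astype(np.uint8), spacing)


def sample_exponential_times(
    rng: np.random.Generator,
    labels: np.ndarray,
    base_median: float,
    hazard_ratio: float,
    censor_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with a class hazard ratio and uniform censoring.

    Class 0 has median ``base_median`` (rate ln2/median); class 1's rate is
    ``hazard_ratio`` times larger. With probability ``censor_rate`` a patient
    is censored at a uniform fraction of their event time.
    """
    labels = np.asarray(labels)
    rate = np.log(2.0) / base_median * np.where(labels == 1, hazard_ratio, 1.0)
    times = rng.exponential(1.0 / rate)
    events = np.ones(len(labels), dtype=int)
    censored = rng.random(len(labels)) < censor_rate
    times = np.where(censored, times * rng.uniform(0.0, 1.0, len(labels)), times)
    events[censored] = 0
    return times, events


_LOCATIONS = np.array([0, 1, 2, 3])  # cervical, upper, middle, lower thoracic
_LOCATION_P = np.array([1, 10, 12, 7]) / 30.0
_T_STAGE = np.array([2, 3, 4])
_T_P = np.array([4, 20, 6]) / 30.0
_CHEMO = np.array([1, 2, 3, 4])
_CHEMO_P = np.array([2, 3, 8, 17]) / 30.0
_BED = np.array([67.2, 71.175, 73.925])
_BED_P = np.array([4, 12, 14]) / 30.0


def generate_records(config: CohortConfig, rng: np.random.Generator | None = None) -> list[PatientRecord]:
    """Clinical table and survival times for one cohort (no volumes).

    Exactly ``n_progression`` patients carry label 1. Clinical covariates
    are sampled from the cohort margins (26:4 male:female, etc.) with no
    dependence on the label. PFS times are exponential with the configured
    class hazard ratio and censoring; local-control events are observed for
    every progression (by definition of the label) and absent for controls,
    who are censored at their follow-up time.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients
    labels = np.zeros(n, dtype=int)
    labels[: config.n_progression] = 1
    labels = rng.permutation(labels)

    pfs_times, pfs_events = sample_exponential_times(
        rng, labels, config.pfs_median_low_risk, config.hazard_ratio, config.censor_rate
    )
    followup = rng.uniform(*config.followup_range, size=n)
    # administrative censoring at the end of each patient's follow-up window
    over = pfs_times > followup
    pfs_times = np.where(over, followup, pfs_times)
    pfs_events = np.where(over, 0, pfs_events)
    lc_fail = rng.exponential(config.lc_median_progression / np.log(2.0), size=n)

    records = []
    for i in range(n):
        label = int(labels[i])
        if label == 1:
            lc_time, lc_event = float(lc_fail[i]), 1
        else:
            lc_time, lc_event = float(followup[i]), 0
        records.append(
            PatientRecord(
                id=f"P{i + 1:03d}",
                location=int(rng.choice(_LOCATIONS, p=_LOCATION_P)),
                t_stage=int(rng.choice(_T_STAGE, p=_T_P)),
                n_stage=int(rng.random() < 19 / 30.0),
                m_stage=int(rng.random() < 7 / 30.0),
                bed_gy=float(rng.choice(_BED, p=_BED_P)),
                chemo_cycles=int(rng.choice(_CHEMO, p=_CHEMO_P)),
                age=float(rng.integers(44, 76)),
                gender=int(rng.random() < 4 / 30.0),
                label=label,
                lc_time=lc_time,
                lc_event=lc_event,
                pfs_time=float(pfs_times[i]),
                pfs_event=int(pfs_events[i]),
            )
        )
    return records


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], list[dict[str, tuple[SUVVolume, VOIMask]]]]:
    """Full cohort: records plus paired pre/mid volumes and masks.

    The mid-treatment volume rescales the tumor's excess uptake over
    background by the class response factor and adds fresh voxel noise; the
    VOI contour is carried over unchanged (propagated contours).
    """
    rng = np.random.default_rng(config.seed)
    records = generate_records(config, rng)
    spacing = (config.spacing,) * 3
    images = []
    for rec in records:
        mask, noiseless, noise = _tumor_fields(config, rec.label, rng)
        pre = noiseless.copy()
        pre[mask] += noise[mask]
        np.clip(pre, 0.0, None, out=pre)

        f = config.mid_crt_response_factor[rec.label]
        mid = np.full(mask.shape, config.background_suv)
        mid[mask] = config.background_suv + f * (noiseless[mask] - config.background_suv)
        if config.noise_sd > 0:
            mid[mask] += rng.normal(0.0, config.noise_sd, size=int(mask.sum()))
        np.clip(mid, 0.0, None, out=mid)

        voi_mask = VOIMask(mask.astype(np.uint8), spacing)
        images.append(
            {
                "pre": (SUVVolume(pre, spacing), voi_mask),
                "mid": (SUVVolume(mid, spacing), voi_mask),
            }
        )
    return records, images
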