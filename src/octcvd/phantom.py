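"""Synthetic macular OCT phantoms and clinical metadata.

Real 3D macular OCT volumes (128 horizontal B-scans per eye) with linked
cardiovascular outcomes cannot be redistributed, so this module generates
phantom cohorts carrying the statistical structure the downstream analysis
assumes: layered B-scan geometry with the ten named retinal boundaries plus
a choroidal band, multiplicative speckle, per-eye scan quality (left eye
slightly better on average), both eyes per subject with correlated anatomy,
and clinical metadata whose per-group distributions are calibrated to the
published CVD+/CVD- characteristics table.

The discriminative signal is planted explicitly: CVD+ subjects get a
choroidal band whose mean thickness is scaled by ``1 + choroid_effect``
(optionally also RNFL/GCL thinning). Because the effect location and size
are known, representation learning, classification and explainability
stages can all be tested against a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from octcvd.errors import ConfigurationError

#: Retinal boundary names, top to bottom. The band *below* each boundary up
#: to the next one is the layer the boundary name conventionally delimits;
#: OB_RPE..CHOROID_LOWER is the choroidal band.
BOUNDARY_NAMES = (
    "ILM",
    "RNFL",
    "GCL",
    "IPL",
    "INL",
    "OPL",
    "BMEIS",
    "IB_OPR",
    "IB_RPE",
    "OB_RPE",
    "CHOROID_LOWER",
)

#: Band names: each band is delimited above by the previous boundary and
#: below by the boundary it is named after (so "CHOROID_LOWER" names the
#: choroidal band between OB_RPE and CHOROID_LOWER).
BAND_NAMES = BOUNDARY_NAMES[1:]

CHOROID_BAND = "CHOROID_LOWER"

BACKGROUND_REFLECTIVITY = 0.05  # vitreous, above the ILM
BELOW_REFLECTIVITY = 0.02  # sclera/shadow below the choroid


@dataclass(frozen=True)
class LayerSpec:
    """One retinal band: geometry plus mean backscatter reflectivity."""

    name: str
    mean_thickness: float  # pixels
    thickness_sd: float  # pixels, per-scan variation
    reflectivity: float  # dimensionless, in [0, 1]

    def __post_init__(self):
        if self.name not in BOUNDARY_NAMES:
            raise ConfigurationError(f"unknown layer name {self.name!r}")
        if self.mean_thickness <= 0:
            raise ConfigurationError("layer thickness must be positive")
        if not 0.0 <= self.reflectivity <= 1.0:
            raise ConfigurationError("reflectivity must lie in [0, 1]")


# (mean thickness at 128-px image height, sd, reflectivity); thicknesses
# scale linearly with image height. Reflectivities follow the usual OCT
# contrast pattern: bright RNFL and RPE, darker nuclear layers, mid-grey
# choroid.
_DEFAULT_BANDS = (
    ("RNFL", 8.0, 0.8, 0.85),
    ("GCL", 8.0, 0.8, 0.35),
    ("IPL", 6.0, 0.6, 0.50),
    ("INL", 6.0, 0.6, 0.28),
    ("OPL", 5.0, 0.5, 0.55),
    ("BMEIS", 12.0, 1.2, 0.20),
    ("IB_OPR", 4.0, 0.4, 0.75),
    ("IB_RPE", 3.0, 0.3, 0.62),
    ("OB_RPE", 4.0, 0.4, 0.90),
    ("CHOROID_LOWER", 24.0, 2.4, 0.45),
)


def default_layers(image_height: int = 128) -> List[LayerSpec]:
    """Default 10-band retinal stack, scaled to the given image height."""
    s = image_height / 128.0
    return [
        LayerSpec(name, m * s, sd * s, r) for name, m, sd, r in _DEFAULT_BANDS
    ]


@dataclass(frozen=True)
class PhantomConfig:
    """Knobs of the phantom generator.

    ``choroid_effect`` is the planted signal: the relative change of the
    CVD+ choroidal mean thickness (0.3 means 30% thicker). ``rnfl_effect``
    optionally thins RNFL+GCL in CVD+ subjects (off by default so that the
    choroid is the unique ground-truth signal).
    """

    image_height: int = 128
    image_width: int = 128
    n_bscans: int = 128
    speckle_level: float = 0.15
    choroid_effect: float = 0.0
    rnfl_effect: float = 0.0
    quality_mean_left: float = 0.75
    quality_mean_right: float = 0.65
    quality_sd: float = 0.08
    undulation_amp: float = 2.0  # pixels at 128-px height; scales with height
    choroid_texture: float = 0.15  # vascular texture amplitude inside the band
    inter_eye_corr: float = 0.8  # correlation of the two eyes' anatomy
    thickness_jitter: float = 0.08  # subject-level log-scale choroid spread
    seed: int = 0

    def __post_init__(self):
        if self.n_bscans < 1:
            raise ConfigurationError("n_bscans must be >= 1")
        if abs(self.choroid_effect) >= 1:
            raise ConfigurationError("|choroid_effect| must be < 1")
        if self.speckle_level < 0:
            raise ConfigurationError("speckle_level must be >= 0")
        if not 0.0 <= self.inter_eye_corr <= 1.0:
            raise ConfigurationError("inter_eye_corr must lie in [0, 1]")


@dataclass
class SubjectRecord:
    """Clinical metadata for one subject; the unit of cohort construction."""

    subject_id: str
    age: float  # years
    sex: str  # "F" | "M"
    ethnicity: str
    bmi: float  # kg/m^2
    sbp: float  # mm Hg
    dbp: float  # mm Hg
    hba1c: float  # mmol/mol
    alcohol: str  # "never" | "previous" | "current" | "NA"
    cvd_label: str  # "CVD+" | "CVD-"
    event_offset: float  # years to first MI/stroke; NaN for CVD-
    diabetes: bool = False
    cardiomyopathy: bool = False

    def __post_init__(self):
        if self.age <= 0:
            raise ConfigurationError("age must be positive")
        if self.cvd_label == "CVD+" and not (
            np.isfinite(self.event_offset) and self.event_offset > 0
        ):
            raise ConfigurationError("CVD+ requires a positive event_offset")


@dataclass
class OCTVolume:
    """One eye's macular volume with ground-truth boundary maps.

    ``bscans``: (n_bscans, H, W) float32 in [0, 1].
    ``boundaries``: (n_bscans, 11, W) int16 row index of each named boundary
    per column, ordered as :data:`BOUNDARY_NAMES`.
    """

    subject_id: str
    eye: str  # "L" | "R"
    bscans: np.ndarray
    boundaries: np.ndarray
    nominal_quality: float = float("nan")

    @property
    def n_bscans(self) -> int:
        return self.bscans.shape[0]


@dataclass
class CohortDataset:
    """A generated cohort: metadata table plus per-subject-eye volumes."""

    records: pd.DataFrame
    volumes: Dict[Tuple[str, str], OCTVolume]
    config: PhantomConfig

    @property
    def n_subjects(self) -> int:
        return len(self.records)


# --- per-group metadata distributions (published cohort characteristics) ---

_ETHNICITY_LEVELS = ("White", "Mixed", "Asian", "Black", "Chinese", "Other")
_ALCOHOL_LEVELS = ("never", "previous", "current", "NA")

_METADATA = {
    "CVD+": {
        "bmi": (28.31, 4.45),
        "sbp": (147.26, 19.57),
        "dbp": (84.75, 10.23),
        "hba1c": (36.52, 4.32),
        "alcohol_p": (0.0359, 0.0572, 0.9069, 0.0),
        "ethnicity_p": (0.9018, 0.0426, 0.0393, 0.0033, 0.0016, 0.0115),
    },
    "CVD-": {
        "bmi": (27.43, 4.33),
        "sbp": (145.10, 18.75),
        "dbp": (83.22, 9.73),
        "hba1c": (36.59, 6.61),
        "alcohol_p": (0.0392, 0.0392, 0.9183, 0.0033),
        "ethnicity_p": (0.8922, 0.0425, 0.0441, 0.0082, 0.0049, 0.0082),
    },
}
AGE_MEAN, AGE_SD = 60.78, 6.47  # identical across groups (matched design)
FEMALE_FRACTION = 0.2974
EVENT_WINDOW_YEARS = 5.0
_DIABETES_RATE = 0.05
_CARDIOMYOPATHY_RATE = 0.01


def _normalized(p):
    p = np.asarray(p, dtype=float)
    return p / p.sum() if p.sum() > 0 else p


def generate_bscan(
    layers: List[LayerSpec],
    config: PhantomConfig,
    rng: np.random.Generator,
    *,
    thickness_scales: Optional[Dict[str, float]] = None,
    speckle_level: Optional[float] = None,
    noise_sd: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render one B-scan.

    Returns ``(image, boundary_map)`` where ``image`` is (H, W) float32 in
    [0, 1] and ``boundary_map`` is (11, W) int16 with the row index of each
    boundary of :data:`BOUNDARY_NAMES` per column. Band thickness is
    constant across columns within a scan; all boundaries share a smooth
    low-frequency sinusoidal undulation, so the ground-truth band thickness
    is exactly the sampled per-scan value in every column.
    """
    H, W = config.image_height, config.image_width
    scales = thickness_scales or {}
    if speckle_level is None:
        speckle_level = config.speckle_level

    ilm_base = int(round(0.12 * H))
    amp_margin = int(np.ceil(config.undulation_amp * H / 128.0)) + 1
    budget = (H - 1) - ilm_base - amp_margin
    mean_total = sum(spec.mean_thickness for spec in layers)
    if mean_total > budget or budget < len(layers) or ilm_base - amp_margin < 0:
        raise ConfigurationError(
            f"layer stack (mean {mean_total:.0f}px) + margins overflow "
            f"image height {H}"
        )

    # per-scan band thicknesses (integer pixels, at least 1); rare tail
    # draws that would overflow the height budget are rescaled to fit
    thick = np.empty(len(layers), dtype=np.int64)
    for k, spec in enumerate(layers):
        t = rng.normal(spec.mean_thickness, spec.thickness_sd)
        t *= scales.get(spec.name, 1.0)
        thick[k] = max(1, int(round(t)))
    if thick.sum() > budget:
        shrink = budget / thick.sum()
        thick = np.maximum(1, np.floor(thick * shrink).astype(np.int64))

    # boundary undulation: sum of <=3 low-frequency sinusoids, random
    # phase; amplitude is anatomy-proportional (scales with image height)
    amp_total = config.undulation_amp * H / 128.0
    n_comp = int(rng.integers(1, 4))
    x = np.arange(W)
    und = np.zeros(W)
    for _ in range(n_comp):
        amp = amp_total * rng.uniform(0.3, 1.0) / n_comp
        freq = rng.uniform(0.5, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        und += amp * np.sin(2 * np.pi * freq * x / W + phase)

    bounds = np.empty((len(BOUNDARY_NAMES), W), dtype=np.int16)
    bounds[0] = np.round(ilm_base + und).astype(np.int16)
    for k in range(len(layers)):
        bounds[k + 1] = bounds[k] + thick[k]

    refl = np.array(
        [BACKGROUND_REFLECTIVITY]
        + [spec.reflectivity for spec in layers]
        + [BELOW_REFLECTIVITY],
        dtype=np.float32,
    )
    rows = np.arange(H).reshape(H, 1)
    band_idx = (rows >= bounds[:, None, :]).sum(axis=0)  # (H, W) in 0..11
    img = refl[band_idx]

    if config.choroid_texture > 0:
        # vascular texture tied to band-relative depth: when the band
        # thickens the pattern stretches with it, so thickness change is
        # visible throughout the band, not just at its lower edge
        i_choroid = BOUNDARY_NAMES.index(CHOROID_BAND)
        top, bot = bounds[i_choroid - 1].astype(np.float64), bounds[i_choroid]
        depth = np.maximum(bot - top, 1.0)
        rel = (rows - top[None, :]) / depth[None, :]
        in_band = (rows >= top[None, :]) & (rows < bot[None, :])
        # one cycle across the band: the lamination wavelength stays large
        # enough that a windowed flow estimator can track the stretch
        img = img + np.where(
            in_band,
            config.choroid_texture * np.sin(2 * np.pi * rel),
            0.0,
        )
        img = np.clip(img, 0.0, 1.0)

    if speckle_level > 0:
        shape = 1.0 / speckle_level**2  # gamma with mean 1, sd speckle_level
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)
    if noise_sd > 0:  # detector/shot noise of low-quality acquisitions
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    if speckle_level > 0 or noise_sd > 0:
        img = np.clip(img, 0.0, 1.0)
    return img.astype(np.float32), bounds


def measure_band_thickness(
    boundary_map: np.ndarray, band: str = CHOROID_BAND
) -> np.ndarray:
    """Per-column thickness of a band from a ground-truth boundary map."""
    i = BOUNDARY_NAMES.index(band)
    if i == 0:
        raise ConfigurationError("ILM names the top boundary, not a band")
    return (
        boundary_map[i].astype(np.int64) - boundary_map[i - 1].astype(np.int64)
    )


def _draw_record(
    subject_id: str, cvd_label: str, rng: np.random.Generator
) -> SubjectRecord:
    m = _METADATA[cvd_label]
    age = float(np.clip(rng.normal(AGE_MEAN, AGE_SD), 30.0, 95.0))
    sex = "F" if rng.random() < FEMALE_FRACTION else "M"
    ethnicity = str(rng.choice(_ETHNICITY_LEVELS, p=_normalized(m["ethnicity_p"])))
    alcohol = str(rng.choice(_ALCOHOL_LEVELS, p=_normalized(m["alcohol_p"])))
    if cvd_label == "CVD+":
        # event strictly in (0, 5] years after imaging
        event_offset = EVENT_WINDOW_YEARS * (1.0 - rng.random())
    else:
        event_offset = float("nan")
    return SubjectRecord(
        subject_id=subject_id,
        age=age,
        sex=sex,
        ethnicity=ethnicity,
        bmi=float(rng.normal(*m["bmi"])),
        sbp=float(rng.normal(*m["sbp"])),
        dbp=float(rng.normal(*m["dbp"])),
        hba1c=float(rng.normal(*m["hba1c"])),
        alcohol=alcohol,
        cvd_label=cvd_label,
        event_offset=event_offset,
        diabetes=bool(rng.random() < _DIABETES_RATE),
        cardiomyopathy=bool(rng.random() < _CARDIOMYOPATHY_RATE),
    )


def generate_subject(
    cvd_label: str,
    config: PhantomConfig,
    rng: np.random.Generator,
    subject_id: str = "S0000",
    layers: Optional[List[LayerSpec]] = None,
) -> Tuple[SubjectRecord, OCTVolume, OCTVolume]:
    """Generate one subject: metadata plus left and right eye volumes.

    Both eyes share a subject-level anatomy latent with correlation
    ``config.inter_eye_corr``; CVD+ choroidal mean thickness is scaled by
    ``1 + choroid_effect``. The left eye draws a higher mean quality score,
    which lowers its effective speckle level.
    """
    if layers is None:
        layers = default_layers(config.image_height)
    record = _draw_record(subject_id, cvd_label, rng)

    u_subject = rng.normal()
    a = np.sqrt(config.inter_eye_corr)
    volumes = []
    for eye, q_mean in (("L", config.quality_mean_left), ("R", config.quality_mean_right)):
        u_eye = a * u_subject + np.sqrt(1.0 - a * a) * rng.normal()
        choroid_scale = float(np.exp(config.thickness_jitter * u_eye))
        if cvd_label == "CVD+":
            choroid_scale *= 1.0 + config.choroid_effect
        scales = {CHOROID_BAND: choroid_scale}
        if config.rnfl_effect != 0.0 and cvd_label == "CVD+":
            scales["RNFL"] = 1.0 - config.rnfl_effect
            scales["GCL"] = 1.0 - config.rnfl_effect

        # lower quality = more speckle plus a higher detector-noise floor,
        # so the QI ranking tracks the nominal quality draw
        quality = float(np.clip(rng.normal(q_mean, config.quality_sd), 0.05, 1.0))
        speckle = config.speckle_level * (1.6 - quality)
        noise_sd = 0.3 * (1.0 - quality)

        imgs = np.empty(
            (config.n_bscans, config.image_height, config.image_width),
            dtype=np.float32,
        )
        maps = np.empty(
            (config.n_bscans, len(BOUNDARY_NAMES), config.image_width),
            dtype=np.int16,
        )
        for i in range(config.n_bscans):
            imgs[i], maps[i] = generate_bscan(
                layers, config, rng,
                thickness_scales=scales, speckle_level=speckle,
                noise_sd=noise_sd,
            )
        volumes.append(
            OCTVolume(record.subject_id, eye, imgs, maps, nominal_quality=quality)
        )
    return record, volumes[0], volumes[1]


def generate_cohort(
    n_cases: int,
    n_controls: int,
    config: Optional[PhantomConfig] = None,
    seed: Optional[int] = None,
    layers: Optional[List[LayerSpec]] = None,
) -> CohortDataset:
    """Generate a labelled cohort, deterministic under a fixed seed.

    Age and sex marginals are identical across labels by construction, so
    downstream matching is testable; CVD+ event offsets are uniform on
    (0, 5] years.
    """
    if n_cases < 1 or n_controls < 1:
        raise ConfigurationError("n_cases and n_controls must be >= 1")
    if config is None:
        config = PhantomConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    labels = ["CVD+"] * n_cases + ["CVD-"] * n_controls
    rows, volumes = [], {}
    for i, label in enumerate(labels):
        sid = f"S{i:04d}"
        record, vol_l, vol_r = generate_subject(
            label, config, rng, subject_id=sid, layers=layers
        )
        rows.append(vars(record).copy())
        volumes[(sid, "L")] = vol_l
        volumes[(sid, "R")] = vol_r
    records = pd.DataFrame(rows)
    return CohortDataset(records=records, volumes=volumes, config=config)


# ----------------------------- persistence --------------------------------


def save_volume(path, volume: OCTVolume) -> None:
    """Write one subject-eye volume to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("bscans", data=volume.bscans, compression="gzip")
        f.create_dataset("boundaries", data=volume.boundaries, compression="gzip")
        f.attrs["subject_id"] = volume.subject_id
        f.attrs["eye"] = volume.eye
        f.attrs["nominal_quality"] = volume.nominal_quality


def load_volume(path) -> OCTVolume:
    with h5py.File(path, "r") as f:
        return OCTVolume(
            subject_id=str(f.attrs["subject_id"]),
            eye=str(f.attrs["eye"]),
            bscans=f["bscans"][()],
            boundaries=f["boundaries"][()],
            nominal_quality=float(f.attrs["nominal_quality"]),
        )


def save_cohort(dataset: CohortDataset, outdir) -> None:
    """Write a cohort as metadata CSV plus one HDF5 file per subject-eye."""
    outdir = Path(outdir)
    (outdir / "volumes").mkdir(parents=True, exist_ok=True)
    dataset.records.to_csv(outdir / "metadata.csv", index=False)
    for (sid, eye), vol in dataset.volumes.items():
        save_volume(outdir / "volumes" / f"{sid}_{eye}.h5", vol)


def load_cohort(indir, config: Optional[PhantomConfig] = None) -> CohortDataset:
    indir = Path(indir)
    records = pd.read_csv(indir / "metadata.csv")
    volumes = {}
    for path in sorted((indir / "volumes").glob("*.h5")):
        vol = load_volume(path)
        volumes[(vol.subject_id, vol.eye)] = vol
    return CohortDataset(
        records=records, volumes=volumes, config=config or PhantomConfig()
    )
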