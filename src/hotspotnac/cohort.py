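"""Synthetic patient cohorts for the hotspot pipeline.

Real inputs to the pipeline are per-patient cell-detection tables from
co-registered H&E / Ki67 / pH3 whole-slide images: tumor cells (TC),
stromal and intratumoral TILs (sTIL, tTIL) detected on H&E, and Ki67+ /
pH3+ signals detected on the serial IHC sections in their own (misaligned)
coordinate frames. This module generates cohorts with that structure plus
the ground truth needed for oracle tests: the true Ki67/pH3 phenotype of
every tumor cell and the true IHC-to-H&E misalignment transform.

The generative model is deliberately simple: per 1000x1000 px patch the
count of each cell class is an independent Poisson draw with a
class-outcome-specific rate, and positions are uniform within the patch.
Each tumor cell is Ki67+ with probability ``ki67_fraction`` and, if Ki67+,
additionally pH3+ with probability ``ph3_fraction / ki67_fraction`` — so
every pH3+ cell is Ki67+ (mitotic cells are a subset of cycling cells) and
the marginal pH3+ probability is exactly ``ph3_fraction``. IHC channel
point lists are the flagged tumor-cell coordinates pushed through a
similarity misalignment plus isotropic Gaussian jitter.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import CohortIOError, ValidationError

__all__ = [
    "PCR",
    "RD",
    "CHANNEL_HE",
    "CHANNEL_KI67",
    "CHANNEL_PH3",
    "CohortSpec",
    "ClassRates",
    "MisalignmentTransform",
    "SyntheticCohort",
    "default_rates",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "detections_to_geojson",
]

PCR = "pCR"
RD = "RD"

CHANNEL_HE = "HE"
CHANNEL_KI67 = "KI67"
CHANNEL_PH3 = "PH3"

HE_CELL_TYPES = ("TC", "sTIL", "tTIL")

DETECTION_COLUMNS = [
    "patient_id",
    "region_id",
    "channel",
    "cell_type",
    "cell_id",
    "x",
    "y",
]
TRUTH_PHENOTYPE_COLUMNS = [
    "patient_id",
    "region_id",
    "cell_id",
    "x",
    "y",
    "is_ki67",
    "is_ph3",
]
TRUTH_TRANSFORM_COLUMNS = [
    "patient_id",
    "channel",
    "rotation",
    "scale",
    "dx",
    "dy",
    "jitter_sd",
]


@dataclass(frozen=True)
class CohortSpec:
    """Size and geometry of a synthetic cohort.

    Defaults mirror the study design the pipeline targets: 76 biopsy
    patients (44 pCR, 32 RD), 8000x8000 px image regions tiled into
    1000x1000 px patches.
    """

    n_patients: int = 76
    n_pcr: int = 44
    n_rd: int = 32
    regions_per_patient: int = 1
    region_size_px: int = 8000
    patch_size_px: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_pcr", "n_rd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_pcr + self.n_rd != self.n_patients:
            raise ValidationError(
                "n_pcr + n_rd must equal n_patients "
                f"({self.n_pcr} + {self.n_rd} != {self.n_patients})"
            )
        if self.regions_per_patient < 1:
            raise ValidationError(
                f"regions_per_patient must be >= 1, got {self.regions_per_patient}"
            )
        if self.region_size_px <= 0 or self.patch_size_px <= 0:
            raise ValidationError("region_size_px and patch_size_px must be positive")
        if self.region_size_px % self.patch_size_px != 0:
            raise ValidationError(
                "region_size_px must be divisible by patch_size_px "
                f"({self.region_size_px} % {self.patch_size_px} != 0)"
            )

    @property
    def grid_dim(self) -> int:
        return self.region_size_px // self.patch_size_px

    @property
    def patches_per_region(self) -> int:
        return self.grid_dim**2


@dataclass(frozen=True)
class ClassRates:
    """Per-patch Poisson rates and marker fractions for one outcome class.

    ``tc``, ``stil`` and ``ttil`` are mean cell counts per 1000x1000 px
    patch.  ``ki67_fraction`` is the probability that a tumor cell is Ki67+
    (cycling, the P population); ``ph3_fraction`` the marginal probability
    that it is pH3+ (mitotic, the M population).  Mitosis implies cycling,
    hence ``ph3_fraction <= ki67_fraction``.
    """

    tc: float = 100.0
    stil: float = 15.0
    ttil: float = 10.0
    ki67_fraction: float = 0.2
    ph3_fraction: float = 0.02

    def __post_init__(self) -> None:
        for name in ("tc", "stil", "ttil"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} rate must be >= 0, got {getattr(self, name)}")
        for name in ("ki67_fraction", "ph3_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.ph3_fraction > self.ki67_fraction:
            raise ValidationError(
                "ph3_fraction must be <= ki67_fraction "
                f"({self.ph3_fraction} > {self.ki67_fraction})"
            )


def default_rates(label: str) -> ClassRates:
    """Default class rates: pCR tumors carry twice the RD tTIL density.

    The direction (elevated intratumoral TILs in responders) is the
    well-established association between TIL density and pathological
    complete response; the 2x magnitude is the package's default effect
    size and is freely configurable.
    """
    if label == PCR:
        return ClassRates(ttil=20.0)
    if label == RD:
        return ClassRates(ttil=10.0)
    raise ValidationError(f"label must be '{PCR}' or '{RD}', got {label!r}")


@dataclass(frozen=True)
class MisalignmentTransform:
    """Similarity misalignment applied to IHC points, plus detection jitter.

    Maps an H&E-frame point p to the IHC frame as ``s * R(rotation) p +
    (dx, dy)`` and then adds isotropic Gaussian jitter with standard
    deviation ``jitter_sd`` (pixels), emulating both the serial-section
    offset between slides and detector localisation noise.
    """

    rotation: float = 0.02
    scale: float = 1.01
    dx: float = 25.0
    dy: float = -18.0
    jitter_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0, got {self.scale}")
        if self.jitter_sd < 0:
            raise ValidationError(f"jitter_sd must be >= 0, got {self.jitter_sd}")

    @classmethod
    def identity(cls, jitter_sd: float = 0.0) -> "MisalignmentTransform":
        return cls(rotation=0.0, scale=1.0, dx=0.0, dy=0.0, jitter_sd=jitter_sd)

    def apply(self, points: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Map H&E-frame points into the IHC frame; jitter only if rng given."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        rot = np.array([[c, -s], [s, c]])
        out = self.scale * pts @ rot.T + np.array([self.dx, self.dy])
        if rng is not None and self.jitter_sd > 0:
            out = out + rng.normal(0.0, self.jitter_sd, size=out.shape)
        return out

    def invert(self, points: np.ndarray) -> np.ndarray:
        """Exact inverse of the noiseless map (IHC frame back to H&E)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        rot_inv = np.array([[c, s], [-s, c]])
        return (pts - np.array([self.dx, self.dy])) @ rot_inv.T / self.scale


@dataclass
class SyntheticCohort:
    """A generated cohort: labels, detections, and ground truth.

    Attributes
    ----------
    spec : CohortSpec
        The geometry the cohort was generated under.
    labels : DataFrame with columns ``patient_id, label``.
    detections : DataFrame with columns ``patient_id, region_id, channel,
        cell_type, cell_id, x, y``.  H&E rows carry cell types TC/sTIL/tTIL
        in the reference frame; KI67/PH3 rows carry KI67_POS/PH3_POS points
        in the perturbed IHC frame (``cell_id`` links them to the tumor
        cell they mark).
    truth_phenotypes : per-tumor-cell ground truth (``is_ki67, is_ph3``).
    truth_transforms : the true misalignment per patient and IHC channel.
    """

    spec: CohortSpec
    labels: pd.DataFrame
    detections: pd.DataFrame
    truth_phenotypes: pd.DataFrame
    truth_transforms: pd.DataFrame

    def he_detections(self) -> pd.DataFrame:
        return self.detections[self.detections["channel"] == CHANNEL_HE]

    def ihc_detections(self, channel: str) -> pd.DataFrame:
        return self.detections[self.detections["channel"] == channel]

    def equals(self, other: "SyntheticCohort") -> bool:
        return (
            self.labels.reset_index(drop=True).equals(other.labels.reset_index(drop=True))
            and self.detections.reset_index(drop=True).equals(
                other.detections.reset_index(drop=True)
            )
            and self.truth_phenotypes.reset_index(drop=True).equals(
                other.truth_phenotypes.reset_index(drop=True)
            )
            and self.truth_transforms.reset_index(drop=True).equals(
                other.truth_transforms.reset_index(drop=True)
            )
        )


def _uniform_positions_in_patches(
    rng: np.random.Generator, counts: np.ndarray, patch_size: int, grid_dim: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw uniform positions for per-patch counts laid out row-major.

    Returns (x, y, patch_index) arrays for counts.sum() cells.
    """
    total = int(counts.sum())
    if total == 0:
        return np.empty(0), np.empty(0), np.empty(0, dtype=int)
    patch_idx = np.repeat(np.arange(grid_dim * grid_dim), counts.ravel())
    rows = patch_idx // grid_dim
    cols = patch_idx % grid_dim
    offs = rng.random((total, 2)) * patch_size
    x = cols * patch_size + offs[:, 0]
    y = rows * patch_size + offs[:, 1]
    return x, y, patch_idx


def generate_cohort(
    spec: CohortSpec | None = None,
    rates_pcr: ClassRates | None = None,
    rates_rd: ClassRates | None = None,
    transform: MisalignmentTransform | None = None,
) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort.

    Per patch, class counts are independent Poisson draws with the
    patient's outcome-class rates and positions are uniform; Ki67+/pH3+
    tumor-cell subsets are flagged as described in the module docstring;
    the same misalignment transform is applied to both IHC channels.
    Everything is a deterministic function of ``spec.seed``.
    """
    spec = spec if spec is not None else CohortSpec()
    rates_pcr = rates_pcr if rates_pcr is not None else default_rates(PCR)
    rates_rd = rates_rd if rates_rd is not None else default_rates(RD)
    transform = transform if transform is not None else MisalignmentTransform()

    rng = np.random.default_rng(spec.seed)
    g = spec.grid_dim
    ps = spec.patch_size_px

    width = max(3, len(str(max(spec.n_patients, 1))))
    patient_ids = [f"P{i + 1:0{width}d}" for i in range(spec.n_patients)]
    labels = [PCR] * spec.n_pcr + [RD] * spec.n_rd

    det_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    transform_rows: list[dict] = []

    for pid, label in zip(patient_ids, labels):
        rates = rates_pcr if label == PCR else rates_rd
        for channel in (CHANNEL_KI67, CHANNEL_PH3):
            transform_rows.append(
                {
                    "patient_id": pid,
                    "channel": channel,
                    "rotation": transform.rotation,
                    "scale": transform.scale,
                    "dx": transform.dx,
                    "dy": transform.dy,
                    "jitter_sd": transform.jitter_sd,
                }
            )
        for region in range(spec.regions_per_patient):
            rid = region
            xs: list[np.ndarray] = []
            ys: list[np.ndarray] = []
            types: list[np.ndarray] = []
            for cell_type, rate in (
                ("TC", rates.tc),
                ("sTIL", rates.stil),
                ("tTIL", rates.ttil),
            ):
                counts = rng.poisson(rate, size=(g, g))
                x, y, _ = _uniform_positions_in_patches(rng, counts, ps, g)
                xs.append(x)
                ys.append(y)
                types.append(np.repeat(cell_type, x.size))
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            cell_type = np.concatenate(types)
            cell_id = np.arange(x.size)

            he = pd.DataFrame(
                {
                    "patient_id": pid,
                    "region_id": rid,
                    "channel": CHANNEL_HE,
                    "cell_type": cell_type,
                    "cell_id": cell_id,
                    "x": x,
                    "y": y,
                }
            )
            det_frames.append(he)

            is_tc = cell_type == "TC"
            n_tc = int(is_tc.sum())
            is_ki67 = np.zeros(x.size, dtype=bool)
            is_ph3 = np.zeros(x.size, dtype=bool)
            if n_tc:
                k_draw = rng.random(n_tc) < rates.ki67_fraction
                cond = (
                    rates.ph3_fraction / rates.ki67_fraction
                    if rates.ki67_fraction > 0
                    else 0.0
                )
                p_draw = k_draw & (rng.random(n_tc) < cond)
                is_ki67[is_tc] = k_draw
                is_ph3[is_tc] = p_draw

            truth_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "region_id": rid,
                        "cell_id": cell_id[is_tc],
                        "x": x[is_tc],
                        "y": y[is_tc],
                        "is_ki67": is_ki67[is_tc],
                        "is_ph3": is_ph3[is_tc],
                    }
                )
            )

            for channel, flag, ihc_type in (
                (CHANNEL_KI67, is_ki67, "KI67_POS"),
                (CHANNEL_PH3, is_ph3, "PH3_POS"),
            ):
                pts = np.column_stack([x[flag], y[flag]])
                mapped = transform.apply(pts, rng=rng)
                det_frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": pid,
                            "region_id": rid,
                            "channel": channel,
                            "cell_type": ihc_type,
                            "cell_id": cell_id[flag],
                            "x": mapped[:, 0] if mapped.size else np.empty(0),
                            "y": mapped[:, 1] if mapped.size else np.empty(0),
                        }
                    )
                )

    detections = (
        pd.concat(det_frames, ignore_index=True)
        if det_frames
        else pd.DataFrame(columns=DETECTION_COLUMNS)
    )
    truth_phenotypes = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(columns=TRUTH_PHENOTYPE_COLUMNS)
    )
    detections = detections.astype(
        {"region_id": "int64", "cell_id": "int64", "x": "float64", "y": "float64"}
    )
    if len(truth_phenotypes):
        truth_phenotypes = truth_phenotypes.astype(
            {"region_id": "int64", "cell_id": "int64", "is_ki67": bool, "is_ph3": bool}
        )

    return SyntheticCohort(
        spec=spec,
        labels=pd.DataFrame({"patient_id": patient_ids, "label": labels}),
        detections=detections[DETECTION_COLUMNS],
        truth_phenotypes=truth_phenotypes[TRUTH_PHENOTYPE_COLUMNS]
        if len(truth_phenotypes)
        else truth_phenotypes,
        truth_transforms=pd.DataFrame(transform_rows, columns=TRUTH_TRANSFORM_COLUMNS),
    )


# ---------------------------------------------------------------------------
# On-disk representation: plain CSV tables plus a small JSON sidecar for the
# cohort geometry. Floats are written with full round-trip precision.

_FILES = {
    "labels": "labels.csv",
    "detections": "detections.csv",
    "truth_phenotypes": "truth_phenotypes.csv",
    "truth_transforms": "truth_transforms.csv",
}
_SPEC_FILE = "cohort_spec.json"


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> list[Path]:
    """Write a cohort to ``directory`` as CSV tables; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for attr, fname in _FILES.items():
        path = directory / fname
        # %.17g preserves float64 exactly, so read-back is lossless
        getattr(cohort, attr).to_csv(path, index=False, float_format="%.17g")
        written.append(path)
    spec_path = directory / _SPEC_FILE
    spec_path.write_text(json.dumps(dataclasses.asdict(cohort.spec), indent=2))
    written.append(spec_path)
    return written


def _read_csv(path: Path, required: Iterable[str]) -> pd.DataFrame:
    if not path.exists():
        raise CohortIOError(f"{path}: missing cohort file")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise CohortIOError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortIOError(f"{path}: missing required columns {missing}")
    return df


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    spec_path = directory / _SPEC_FILE
    if not spec_path.exists():
        raise CohortIOError(f"{spec_path}: missing cohort file")
    try:
        spec = CohortSpec(**json.loads(spec_path.read_text()))
    except (json.JSONDecodeError, TypeError) as exc:
        raise CohortIOError(f"{spec_path}: {exc}") from exc

    labels = _read_csv(directory / _FILES["labels"], ["patient_id", "label"])
    detections = _read_csv(directory / _FILES["detections"], DETECTION_COLUMNS)
    truth_ph = _read_csv(directory / _FILES["truth_phenotypes"], TRUTH_PHENOTYPE_COLUMNS)
    truth_tr = _read_csv(directory / _FILES["truth_transforms"], TRUTH_TRANSFORM_COLUMNS)
    detections = detections.astype(
        {"region_id": "int64", "cell_id": "int64", "x": "float64", "y": "float64"}
    )
    truth_ph = truth_ph.astype(
        {
            "region_id": "int64",
            "cell_id": "int64",
            "x": "float64",
            "y": "float64",
            "is_ki67": bool,
            "is_ph3": bool,
        }
    )
    truth_tr = truth_tr.astype(
        {c: "float64" for c in ("rotation", "scale", "dx", "dy", "jitter_sd")}
    )
    bad = set(labels["label"]) - {PCR, RD}
    if bad:
        raise CohortIOError(f"{directory / _FILES['labels']}: invalid labels {sorted(bad)}")
    return SyntheticCohort(
        spec=spec,
        labels=labels,
        detections=detections,
        truth_phenotypes=truth_ph,
        truth_transforms=truth_tr,
    )


def detections_to_geojson(detections: pd.DataFrame) -> dict:
    """Export detections as a GeoJSON FeatureCollection of Point features."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(r.x), float(r.y)]},
            "properties": {
                "patient_id": r.patient_id,
                "region_id": int(r.region_id),
                "channel": r.channel,
                "cell_type": r.cell_type,
            },
        }
        for r in detections.itertuples(index=False)
    ]
    return {"type": "FeatureCollection", "features": features}
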