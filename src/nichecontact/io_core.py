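"""Shared grid/label conventions, NIfTI and clinical-table I/O, configuration.

All volumes in one patient's record live on a common, already co-registered
grid (default 1 mm isotropic).  A :class:`LabelVolume` couples an integer
label array with the affine that maps voxel indices to world millimetre
coordinates; every distance downstream is reported in mm.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("nichecontact")

#: BraTS-style subregion codes; the segmentation source names the subregions
#: (enhancing tumor, necrosis, edema) but not integer codes, so this default
#: is overridable in the config.
DEFAULT_LABELS = {"necrosis": 1, "edema": 2, "enhancing": 4}

CLINICAL_COLUMNS = [
    "patient_id", "age_years", "sex", "kps", "resection", "mgmt", "ki67",
    "preop_seizures", "multifocal_preop", "multifocal_total",
    "os_months", "event",
]

_CATEGORICALS = {
    "sex": {"male", "female"},
    "resection": {"biopsy", "resection", "unknown"},
    "mgmt": {"methylated", "unmethylated", "not_evaluated"},
    "ki67": {"gt30", "lt30", "not_evaluated"},
}


class ValidationError(ValueError):
    """A record or volume violated an invariant of the pipeline."""


@dataclass(frozen=True)
class LabelScheme:
    """Integer codes for the tumor subregions of a segmentation."""

    necrosis: int = 1
    edema: int = 2
    enhancing: int = 4

    def __post_init__(self):
        codes = (self.necrosis, self.edema, self.enhancing)
        if len(set(codes)) != 3 or any(c <= 0 for c in codes):
            raise ValidationError(f"label codes must be distinct and > 0, got {codes}")

    @property
    def core(self) -> tuple[int, int]:
        """Labels forming the tumor core (enhancing + necrosis)."""
        return (self.enhancing, self.necrosis)


@dataclass
class LabelVolume:
    """A 3D integer label grid with its voxel-to-world affine.

    Parameters
    ----------
    data
        3D array of non-negative integer labels.
    affine
        4x4 voxel-index -> world-mm affine (voxel centers).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if np.max(np.abs(self.data - rounded), initial=0.0) > 1e-6:
                raise ValidationError("voxel values are not integral (tolerance 1e-6)")
            self.data = rounded.astype(np.int32)
        if self.data.size and self.data.min() < 0:
            raise ValidationError("labels must be non-negative")
        if np.any(self.spacing <= 0):
            raise ValidationError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths (sx, sy, sz) in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map an (m, 3) array of voxel indices to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_grid(self, other: "LabelVolume", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def labels(self) -> set[int]:
        return set(np.unique(self.data).tolist())


def check_same_grid(reference: LabelVolume, others: Mapping[str, LabelVolume]) -> None:
    """Reject grid mismatches before any quantification is attempted."""
    for name, vol in others.items():
        if not reference.same_grid(vol):
            raise ValidationError(
                f"volume '{name}' (shape {vol.shape}) is not on the reference grid "
                f"(shape {reference.shape}); inputs must be co-registered"
            )


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a 3D integer-valued NIfTI volume.

    Non-integer voxel values (beyond 1e-6) are rejected, not silently rounded;
    4D inputs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"{path.name}: expected 3D volume, got {data.ndim}D")
    return LabelVolume(data=data, affine=img.affine)


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.int16), vol.affine)
    nib.save(img, str(path))
    return path


@dataclass
class ClinicalRecord:
    """One patient's covariates and survival outcome."""

    patient_id: str
    age_years: float
    sex: str
    kps: int
    resection: str
    mgmt: str
    ki67: str
    preop_seizures: bool
    multifocal_preop: bool
    multifocal_total: bool
    os_months: float
    event: bool

    def validate(self) -> list[str]:
        problems = []
        if self.os_months < 0:
            problems.append(f"os_months must be >= 0, got {self.os_months}")
        if self.kps not in range(10, 101, 10):
            problems.append(f"kps must be in 10..100 step 10, got {self.kps}")
        for col, allowed in _CATEGORICALS.items():
            if getattr(self, col) not in allowed:
                problems.append(f"{col}={getattr(self, col)!r} not in {sorted(allowed)}")
        return problems


_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def _to_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    try:
        return _BOOL_MAP[str(value).strip().lower()]
    except KeyError:
        raise ValidationError(f"cannot parse boolean value {value!r}") from None


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read and validate the clinical CSV.

    Raises :class:`ValidationError` naming the offending rows (1-based data
    row numbers) if any record violates an invariant.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table is missing columns: {missing}")
    records, problems = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = ClinicalRecord(
                patient_id=str(row.patient_id),
                age_years=float(row.age_years),
                sex=str(row.sex),
                kps=int(row.kps),
                resection=str(row.resection),
                mgmt=str(row.mgmt),
                ki67=str(row.ki67),
                preop_seizures=_to_bool(row.preop_seizures),
                multifocal_preop=_to_bool(row.multifocal_preop),
                multifocal_total=_to_bool(row.multifocal_total),
                os_months=float(row.os_months),
                event=_to_bool(row.event),
            )
        except (ValueError, ValidationError) as exc:
            problems.append(f"row {i}: {exc}")
            continue
        row_problems = rec.validate()
        if row_problems:
            problems.append(f"row {i}: " + "; ".join(row_problems))
        else:
            records.append(rec)
    if problems:
        raise ValidationError("invalid clinical rows:\n" + "\n".join(problems))
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("patient_id values are not unique")
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])[CLINICAL_COLUMNS]
    df.to_csv(path, index=False)
    return path


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])[CLINICAL_COLUMNS]


@dataclass
class CohortTable:
    """Clinical records joined one-to-one with spatial quantifications."""

    clinical: pd.DataFrame
    spatial: pd.DataFrame

    def __post_init__(self):
        for name, df in (("clinical", self.clinical), ("spatial", self.spatial)):
            if df["patient_id"].duplicated().any():
                raise ValidationError(f"duplicate patient_id in {name} table")
        unmatched = set(self.spatial["patient_id"]) - set(self.clinical["patient_id"])
        if unmatched:
            raise ValidationError(
                f"spatial records without clinical records: {sorted(unmatched)[:5]}"
            )

    @property
    def n(self) -> int:
        return len(self.merged)

    @property
    def merged(self) -> pd.DataFrame:
        return self.clinical.merge(self.spatial, on="patient_id", how="inner",
                                   validate="one_to_one")


DEFAULT_CONFIG = {
    "labels": dict(DEFAULT_LABELS),
    "zone_patterns": {
        "tumor": "{patient_id}_tumor.nii.gz",
        "svz": "{patient_id}_svz.nii.gz",
        "sgz": "{patient_id}_sgz.nii.gz",
        "cortex": "{patient_id}_cortex.nii.gz",
    },
    "spatial": {
        "connectivity": 26,
        "min_component_voxels": 1,
        "fraction_denominator": "core",   # core | core+edema
    },
    "maxstat": {
        "eps_low": 0.1,
        "eps_high": 0.9,
        "replicates": 9999,
        "seed": 0,
    },
    "associations": {"alpha": 0.05},
}


def _deep_update(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load the YAML configuration, merged over package defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_update(cfg, user)
    return cfg


def scheme_from_config(cfg: Mapping) -> LabelScheme:
    return LabelScheme(**cfg["labels"])


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
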