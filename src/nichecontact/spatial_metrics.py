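"""Tumor-niche spatial quantification on co-registered label volumes.

For each patient: connected components of the tumor core, selection of the
largest focus (multifocal tumors are analysed through their main lesion),
center of mass of the core, minimal Euclidean distance from that point to
each neurogenic zone, relative tumor fraction inside each zone, and binary
contact (fraction strictly greater than zero).

Distances are point-to-voxel-center in world mm: the minimum over zone
voxels of the Euclidean distance from the core's center of mass to the
voxel's center.  Contact is defined through the overlap fraction, so a
positive fraction does not force a zero center-of-mass distance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import LabelScheme, LabelVolume, ValidationError, check_same_grid

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SpatialRecord:
    """Per-patient spatial metrics of the main tumor component."""

    patient_id: str
    n_components: int
    selected_component_voxels: int
    core_volume_mm3: float
    com_x_mm: float
    com_y_mm: float
    com_z_mm: float
    dist_svz_mm: float
    dist_sgz_mm: float
    frac_svz_pct: float
    frac_sgz_pct: float
    frac_cortex_pct: float
    contact_svz: bool
    contact_sgz: bool
    contact_cortex: bool
    multifocal_preop: bool

    def as_dict(self) -> dict:
        return asdict(self)


def tumor_core_mask(seg: LabelVolume, scheme: LabelScheme) -> np.ndarray:
    """Binary mask of the tumor core: enhancing tumor plus necrosis."""
    return np.isin(seg.data, scheme.core)


def tumor_mask(seg: LabelVolume, scheme: LabelScheme,
               denominator: str = "core") -> np.ndarray:
    """Tumor mask used as the fraction denominator (``core`` or ``core+edema``)."""
    if denominator == "core":
        return tumor_core_mask(seg, scheme)
    if denominator == "core+edema":
        return np.isin(seg.data, scheme.core + (scheme.edema,))
    raise ValidationError(f"unknown fraction denominator {denominator!r}")


def connected_components(mask: np.ndarray, connectivity: int = 26) -> list[np.ndarray]:
    """Connected components of a binary mask, largest first.

    Returns a list of (k, 3) voxel-index arrays sorted by size descending;
    ties are broken by the lexicographically smallest voxel index so the
    ordering is deterministic.
    """
    try:
        struct = _STRUCTS[connectivity]
    except KeyError:
        raise ValidationError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    labeled, n = ndimage.label(np.asarray(mask, dtype=bool), structure=struct)
    comps = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labeled == lab)
        comps.append(idx)
    comps.sort(key=lambda ix: (-len(ix), tuple(ix[0])))
    return comps


def select_main_component(
    components: list[np.ndarray], min_component_voxels: int = 1
) -> tuple[np.ndarray, bool]:
    """Pick the largest component; flag multifocality.

    A patient is multifocal preoperatively when more than one component
    reaches ``min_component_voxels``; the returned main component is always
    the largest one.
    """
    surviving = [c for c in components if len(c) >= min_component_voxels]
    if not surviving:
        raise ValidationError(
            f"no component with >= {min_component_voxels} voxels"
        )
    return surviving[0], len(surviving) > 1


def center_of_mass(mask: np.ndarray, volume: LabelVolume) -> np.ndarray:
    """Unweighted mean of voxel-center world coordinates of the foreground."""
    idx = np.argwhere(np.asarray(mask, dtype=bool))
    if len(idx) == 0:
        raise ValidationError("center of mass of an empty mask is undefined")
    return volume.world_coords(idx).mean(axis=0)


def min_distance_to_zone(com_mm: np.ndarray, zone: LabelVolume) -> float:
    """Minimal Euclidean distance (mm) from a world point to a zone's voxels.

    Zero is attainable only when the point coincides with a zone voxel
    center; the value is reported as measured, never clamped.
    """
    idx = np.argwhere(zone.data > 0)
    if len(idx) == 0:
        raise ValidationError("zone mask is empty")
    coords = zone.world_coords(idx)
    return float(np.sqrt(((coords - np.asarray(com_mm)) ** 2).sum(axis=1)).min())


def zone_fraction(tumor: np.ndarray, zone: np.ndarray) -> float:
    """Percentage of tumor voxels lying inside the zone."""
    tumor = np.asarray(tumor, dtype=bool)
    zone = np.asarray(zone, dtype=bool)
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValidationError("tumor mask is empty")
    return 100.0 * int((tumor & zone).sum()) / n_tumor


def quantify_patient(
    patient_id: str,
    seg: LabelVolume,
    zones: Mapping[str, LabelVolume],
    scheme: LabelScheme | None = None,
    connectivity: int = 26,
    min_component_voxels: int = 1,
    fraction_denominator: str = "core",
) -> SpatialRecord:
    """Assemble the full spatial record for one patient.

    ``zones`` must contain binary masks under keys ``svz``, ``sgz`` and
    ``cortex`` on the same grid as ``seg``.  All metrics are computed on the
    main (largest) component of the tumor mask; contact flags are exactly
    ``fraction > 0``.
    """
    scheme = scheme or LabelScheme()
    check_same_grid(seg, zones)
    for key in ("svz", "sgz", "cortex"):
        if key not in zones:
            raise ValidationError(f"missing zone mask {key!r}")

    full = tumor_mask(seg, scheme, fraction_denominator)
    comps = connected_components(full, connectivity)
    if not comps:
        raise ValidationError(f"patient {patient_id}: empty tumor mask")
    main_idx, multifocal = select_main_component(comps, min_component_voxels)
    main = np.zeros(seg.shape, dtype=bool)
    main[tuple(main_idx.T)] = True

    core = tumor_core_mask(seg, scheme) & main
    if not core.any():
        raise ValidationError(f"patient {patient_id}: main component has no core")
    com = center_of_mass(core, seg)
    voxel_mm3 = float(np.prod(seg.spacing))

    fracs = {z: zone_fraction(main, zones[z].data > 0) for z in ("svz", "sgz", "cortex")}
    return SpatialRecord(
        patient_id=patient_id,
        n_components=len(comps),
        selected_component_voxels=int(len(main_idx)),
        core_volume_mm3=float(core.sum()) * voxel_mm3,
        com_x_mm=float(com[0]), com_y_mm=float(com[1]), com_z_mm=float(com[2]),
        dist_svz_mm=min_distance_to_zone(com, zones["svz"]),
        dist_sgz_mm=min_distance_to_zone(com, zones["sgz"]),
        frac_svz_pct=fracs["svz"],
        frac_sgz_pct=fracs["sgz"],
        frac_cortex_pct=fracs["cortex"],
        contact_svz=fracs["svz"] > 0,
        contact_sgz=fracs["sgz"] > 0,
        contact_cortex=fracs["cortex"] > 0,
        multifocal_preop=multifocal,
    )


def spatial_frame(records: list[SpatialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])
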