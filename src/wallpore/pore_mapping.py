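"""Pore extraction, PD/OP size classification, interface assignment and
per-class counting.

Pores arrive either as a labeled/binary pore volume (components under
26-connectivity) or as an annotation table of centroids and diameters.
Kind is decided purely by equivalent diameter against a configurable
threshold: plasmodesmata (PD) are sub-0.1 µm channels while open pores
(OPs) are micrometer-scale wall interruptions, so the default threshold
of 0.2 µm sits between the two populations.

Assignment maps each pore to the interface whose nearest boundary-face
center is closest to the pore centroid (3D Euclidean, physical units);
pores farther than ``max_distance`` from every wall are left unassigned
and reported separately.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from wallpore.interface_graph import InterfaceRecord
from wallpore.volume_io import LabeledVolume, ValidationError, voxel_centers

__all__ = [
    "PoreRecord",
    "DEFAULT_PD_OP_THRESHOLD_UM",
    "DEFAULT_MAX_ASSIGN_DISTANCE_UM",
    "extract_pore_components",
    "pores_from_annotations",
    "classify_pores",
    "assign_pores",
    "count_by_class",
    "pores_to_frame",
]

logger = logging.getLogger(__name__)

#: PD/OP equivalent-diameter threshold (µm). Plasmodesmata are tens of
#: nanometers wide; open pores are "large" (micrometer scale). 0.2 µm
#: separates the two; always log the value actually used.
DEFAULT_PD_OP_THRESHOLD_UM = 0.2

#: pores belong on walls; centroids farther than this (µm) from every
#: boundary face signal segmentation noise and stay unassigned.
DEFAULT_MAX_ASSIGN_DISTANCE_UM = 2.0

IFACE_CLASSES = ("TT", "TP", "PP")
KIND_SETS = ("PD", "OP", "PD+OP")


@dataclasses.dataclass
class PoreRecord:
    """One pore: physical centroid, size, kind and interface assignment."""

    pore_id: int
    centroid: tuple[float, float, float]  # (z, y, x) µm
    volume: float  # µm³; 0.0 for point annotations
    eq_diameter: float  # µm
    kind: str = "unset"  # PD | OP | unset
    interface: tuple[int, int] | None = None
    iface_class: str | None = None

    def __post_init__(self) -> None:
        if self.eq_diameter <= 0:
            raise ValidationError(f"pore {self.pore_id}: eq_diameter must be > 0")


def _eq_diameter(volume: float) -> float:
    """Diameter of the sphere with the given volume."""
    return float((6.0 * volume / np.pi) ** (1.0 / 3.0))


def extract_pore_components(pores: LabeledVolume) -> list[PoreRecord]:
    """One record per pore component; kind unset, interface unassigned.

    If the volume carries more than one distinct non-zero label it is
    treated as instance-labeled (one label per pore). A purely binary
    volume is split into connected components under 26-connectivity,
    since small blobs fragment under 6-connectivity.
    """
    arr = pores.labels
    labels = pores.label_set()
    if labels.size == 0:
        return []
    if labels.size == 1 and labels[0] == 1:
        arr, _ = ndimage.label(arr > 0, structure=np.ones((3, 3, 3), dtype=bool))
        labels = np.unique(arr)
        labels = labels[labels > 0]

    voxvol = pores.voxel_volume
    records: list[PoreRecord] = []
    objects = ndimage.find_objects(arr)
    for lab in labels:
        sl = objects[int(lab) - 1]
        if sl is None:  # pragma: no cover - non-contiguous label ids
            continue
        mask = arr[sl] == lab
        idx = np.argwhere(mask) + np.array([s.start for s in sl])
        centers = voxel_centers(idx, pores.spacing)
        vol = idx.shape[0] * voxvol
        records.append(
            PoreRecord(
                pore_id=int(lab),
                centroid=tuple(centers.mean(axis=0)),
                volume=vol,
                eq_diameter=_eq_diameter(vol),
            )
        )
    return records


def pores_from_annotations(table: pd.DataFrame) -> list[PoreRecord]:
    """Build pore records from an annotation table (pores schema).

    Annotated diameters are taken as equivalent diameters; volume is the
    sphere volume implied by the diameter.
    """
    records = []
    for row in table.itertuples(index=False):
        d = float(row.diameter)
        records.append(
            PoreRecord(
                pore_id=int(row.pore_id),
                centroid=(float(row.cz), float(row.cy), float(row.cx)),
                volume=np.pi / 6.0 * d**3,
                eq_diameter=d,
                kind=str(row.kind),
            )
        )
    return records


def classify_pores(
    pores: list[PoreRecord],
    threshold: float = DEFAULT_PD_OP_THRESHOLD_UM,
) -> list[PoreRecord]:
    """Set ``kind``: OP iff equivalent diameter ≥ threshold, else PD."""
    if threshold <= 0:
        raise ValidationError("PD/OP threshold must be positive")
    logger.info("classifying %d pores with PD/OP threshold %.3g um", len(pores), threshold)
    for p in pores:
        p.kind = "OP" if p.eq_diameter >= threshold else "PD"
    return pores


def assign_pores(
    pores: list[PoreRecord],
    interfaces: list[InterfaceRecord],
    max_distance: float = DEFAULT_MAX_ASSIGN_DISTANCE_UM,
) -> list[PoreRecord]:
    """Assign each pore to the interface with the nearest boundary face.

    Ties (equidistant faces of different interfaces) go to the smaller
    ``(cell_a, cell_b)`` pair. Pores whose nearest face exceeds
    ``max_distance`` stay unassigned and are counted in the log.
    """
    if not interfaces:
        if pores:
            logger.warning("no interfaces: %d pores left unassigned", len(pores))
        for p in pores:
            p.interface, p.iface_class = None, None
        return pores

    centers = np.concatenate([r.face_centers() for r in interfaces], axis=0)
    owner = np.concatenate(
        [np.full(r.n_faces, i, dtype=np.int64) for i, r in enumerate(interfaces)]
    )
    pairs = [r.pair for r in interfaces]
    tree = cKDTree(centers)
    pts = np.array([p.centroid for p in pores], dtype=float).reshape(-1, 3)
    k = min(8, len(centers))
    dist, ind = tree.query(pts, k=k)
    dist = np.asarray(dist).reshape(len(pores), k)
    ind = np.asarray(ind).reshape(len(pores), k)

    n_unassigned = 0
    for i, p in enumerate(pores):
        dmin = dist[i, 0]
        if dmin > max_distance:
            p.interface, p.iface_class = None, None
            n_unassigned += 1
            continue
        # candidates within numerical tolerance of the minimum; tie-break
        # by lexicographically smallest cell pair
        tied = ind[i][dist[i] <= dmin + 1e-9 * max(1.0, dmin)]
        idx = min((int(owner[j]) for j in tied), key=lambda t: pairs[t])
        p.interface = pairs[idx]
        p.iface_class = interfaces[idx].iface_class
    if n_unassigned:
        logger.info(
            "%d of %d pores unassigned (min face distance > %.3g um)",
            n_unassigned,
            len(pores),
            max_distance,
        )
    return pores


def count_by_class(
    pores: list[PoreRecord],
    interfaces: list[InterfaceRecord],
) -> pd.DataFrame:
    """Counts and surface densities per interface class and pore kind.

    Returns one row per (iface_class, kind_set) with kind sets PD, OP and
    PD+OP; ``density`` is pores per µm² of that class's total wall area.
    Unassigned pores are excluded from the per-class rows and reported in
    the ``n_unassigned`` dataframe attribute.
    """
    area_by_class = {c: 0.0 for c in IFACE_CLASSES}
    for r in interfaces:
        area_by_class[r.iface_class] += r.area

    counts = {(c, k): 0 for c in IFACE_CLASSES for k in ("PD", "OP")}
    n_unassigned = 0
    for p in pores:
        if p.interface is None or p.iface_class is None:
            n_unassigned += 1
            continue
        if p.kind not in ("PD", "OP"):
            raise ValidationError(f"pore {p.pore_id} has unset kind; classify first")
        counts[(p.iface_class, p.kind)] += 1

    rows = []
    for c in IFACE_CLASSES:
        area = area_by_class[c]
        per_kind = {k: counts[(c, k)] for k in ("PD", "OP")}
        per_kind["PD+OP"] = per_kind["PD"] + per_kind["OP"]
        for kind_set in KIND_SETS:
            n = per_kind[kind_set]
            rows.append(
                {
                    "iface_class": c,
                    "kind_set": kind_set,
                    "n_pores": n,
                    "total_area_um2": area,
                    "density_per_um2": n / area if area > 0 else 0.0,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_unassigned"] = n_unassigned
    return out


def pores_to_frame(pores: list[PoreRecord]) -> pd.DataFrame:
    """Pore records as a flat table for CSV export."""
    return pd.DataFrame(
        {
            "pore_id": [p.pore_id for p in pores],
            "cz": [p.centroid[0] for p in pores],
            "cy": [p.centroid[1] for p in pores],
            "cx": [p.centroid[2] for p in pores],
            "volume_um3": [p.volume for p in pores],
            "eq_diameter_um": [p.eq_diameter for p in pores],
            "kind": [p.kind for p in pores],
            "cell_a": [p.interface[0] if p.interface else -1 for p in pores],
            "cell_b": [p.interface[1] if p.interface else -1 for p in pores],
            "iface_class": [p.iface_class or "unassigned" for p in pores],
        }
    )
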