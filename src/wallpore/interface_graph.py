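"""Cell-adjacency graph and shared-wall surface extraction.

An *interface* is the set of voxel faces shared by two distinct
non-background cell labels under 6-connectivity. Each interface is
classified by the cell-type pair of its two cells: TT (both tannin
cells), PP (both parenchyma cells) or TP (mixed). Face areas respect
anisotropic voxel spacing: a face normal to axis ``k`` has the area of
the voxel cross-section perpendicular to ``k``.

Diagonal (edge/corner) voxel contacts do not create an interface, and
background never does: volume borders are imaging artifacts, not walls.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd

from wallpore.volume_io import LabeledVolume, ValidationError, cell_type_map

__all__ = [
    "InterfaceRecord",
    "classify_interface",
    "extract_interfaces",
    "adjacency_graph",
    "interfaces_to_frame",
]

#: default area filter: spurious single-face contacts from label noise are
#: dropped below 4 voxel-faces' worth of area (configurable everywhere).
DEFAULT_MIN_AREA_FACES = 4


def classify_interface(type_a: str, type_b: str) -> str:
    """Interface class of a cell-type pair: TT, TP or PP (symmetric)."""
    for t in (type_a, type_b):
        if t not in ("TC", "PC"):
            raise ValidationError(f"unknown cell type {t!r}")
    n_tc = (type_a == "TC") + (type_b == "TC")
    return {2: "TT", 1: "TP", 0: "PP"}[n_tc]


@dataclasses.dataclass(frozen=True)
class InterfaceRecord:
    """One shared wall between two cells.

    ``faces`` is an ``(n, 4)`` integer array of boundary faces in
    deterministic scan order; each row is ``(z, y, x, axis)`` where
    ``(z, y, x)`` indexes the lower voxel of the face-sharing pair along
    ``axis`` (0=z, 1=y, 2=x). ``face_areas`` holds the per-face area so
    ``area == face_areas.sum()`` exactly.
    """

    cell_a: int
    cell_b: int
    iface_class: str
    area: float
    faces: np.ndarray
    face_areas: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def pair(self) -> tuple[int, int]:
        return (self.cell_a, self.cell_b)

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def face_centers(self) -> np.ndarray:
        """Physical centers (µm) of the boundary faces.

        A face between voxel ``(z, y, x)`` and its +axis neighbor lies on
        the shared voxel side: its center is at the voxel center shifted
        by half a voxel along the face axis.
        """
        d = np.asarray(self.spacing, dtype=float)
        centers = (self.faces[:, :3].astype(float) + 0.5) * d
        axis = self.faces[:, 3]
        for k in range(3):
            centers[axis == k, k] += d[k] / 2.0
        return centers


def _face_area_per_axis(spacing: tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = spacing
    # face normal to z has area dy*dx, etc.
    return np.array([dy * dx, dz * dx, dz * dy], dtype=float)


def extract_interfaces(
    cells: LabeledVolume,
    types: pd.DataFrame,
    min_area: float | None = None,
) -> list[InterfaceRecord]:
    """Extract one record per unordered pair of wall-sharing cells.

    Parameters
    ----------
    cells
        Cell-channel labeled volume.
    types
        Cell-type table covering every non-background label in ``cells``.
    min_area
        Interfaces with total area (µm²) below this are dropped. Defaults
        to 4 voxel-faces' worth of the largest face area.

    Returns
    -------
    Records sorted by ``(cell_a, cell_b)``; faces within a record are in
    scan order (axis z, y, x; C-order voxel index within each axis).
    """
    tmap = cell_type_map(types)
    labels = cells.labels
    areas = _face_area_per_axis(cells.spacing)
    if min_area is None:
        min_area = DEFAULT_MIN_AREA_FACES * areas.max()

    missing = set(cells.label_set().tolist()) - set(tmap)
    if missing:
        raise ValidationError(f"labels missing from cell-type table: {sorted(missing)}")

    pair_faces: dict[tuple[int, int], list[np.ndarray]] = {}
    pair_area: dict[tuple[int, int], float] = {}
    for axis in range(3):
        lo = labels[tuple(slice(None, -1) if k == axis else slice(None) for k in range(3))]
        hi = labels[tuple(slice(1, None) if k == axis else slice(None) for k in range(3))]
        mask = (lo != hi) & (lo > 0) & (hi > 0)
        if not mask.any():
            continue
        zz, yy, xx = np.nonzero(mask)
        a = lo[mask].astype(np.int64)
        b = hi[mask].astype(np.int64)
        pa, pb = np.minimum(a, b), np.maximum(a, b)
        faces = np.column_stack([zz, yy, xx, np.full(zz.shape, axis, dtype=np.int64)])
        # group faces by pair, preserving scan order within the axis
        order = np.lexsort((xx, yy, zz, pb, pa))
        pa, pb, faces = pa[order], pb[order], faces[order]
        keys = np.column_stack([pa, pb])
        change = np.nonzero(np.any(np.diff(keys, axis=0) != 0, axis=1))[0] + 1
        starts = np.concatenate([[0], change, [len(pa)]])
        for s, e in zip(starts[:-1], starts[1:]):
            key = (int(pa[s]), int(pb[s]))
            pair_faces.setdefault(key, []).append(faces[s:e])
            pair_area[key] = pair_area.get(key, 0.0) + (e - s) * areas[axis]

    records: list[InterfaceRecord] = []
    for key in sorted(pair_faces):
        if pair_area[key] < min_area:
            continue
        f = np.concatenate(pair_faces[key], axis=0)
        face_areas = areas[f[:, 3]]
        records.append(
            InterfaceRecord(
                cell_a=key[0],
                cell_b=key[1],
                iface_class=classify_interface(tmap[key[0]], tmap[key[1]]),
                area=float(face_areas.sum()),
                faces=f,
                face_areas=face_areas,
                spacing=cells.spacing,
            )
        )
    return records


def adjacency_graph(interfaces: list[InterfaceRecord]) -> nx.Graph:
    """Undirected cell-adjacency graph; edges weighted by wall area."""
    g = nx.Graph()
    for rec in interfaces:
        if g.has_edge(rec.cell_a, rec.cell_b):
            raise ValidationError(f"duplicate interface for pair {rec.pair}")
        g.add_edge(rec.cell_a, rec.cell_b, area=rec.area, iface_class=rec.iface_class)
    return g


def interfaces_to_frame(interfaces: list[InterfaceRecord]) -> pd.DataFrame:
    """Interface list as a flat table (cell_a, cell_b, class, area, n_faces)."""
    return pd.DataFrame(
        {
            "cell_a": [r.cell_a for r in interfaces],
            "cell_b": [r.cell_b for r in interfaces],
            "iface_class": [r.iface_class for r in interfaces],
            "area_um2": [r.area for r in interfaces],
            "n_faces": [r.n_faces for r in interfaces],
        }
    )
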