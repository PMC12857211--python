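"""Synthetic tissue volumes with two cell types and ground-truth wall pores.

Emulates the statistical structure of FIB-SEM observations of persimmon
mesocarp: a space-filling Voronoi mosaic of cells, a tannin-cell (TC) /
parenchyma-cell (PC) type assignment with optional spatial clustering,
and wall pores placed on shared cell walls as point processes —
plasmodesmata (PD) as a Matérn-style cluster process of small pores, open
pores (OPs) as a sparse homogeneous Poisson process of large pores, with
interface-class-specific intensities.

Per shared wall and pore kind the realized count is Poisson with mean
``intensity × wall area``; positions are uniform over the wall's boundary
faces (area-weighted, jittered within the face plane). Identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit, logit

from wallpore.interface_graph import InterfaceRecord, classify_interface, extract_interfaces
from wallpore.volume_io import LabeledVolume, ValidationError

__all__ = [
    "TissueSpec",
    "GroundTruth",
    "GenerationError",
    "generate_tissue",
    "generate_mosaic",
    "place_pores",
    "tc_fraction_realized",
]

#: default pore intensities (pores per µm² of wall) per (class, kind).
#: OPs are most frequent at TC–TC walls and rarest at PC–PC walls, while
#: total PD + OP intensity is the same (0.05 µm⁻²) in every class, so
#: combined counts are comparable across classes.
DEFAULT_PORE_INTENSITY: dict[tuple[str, str], float] = {
    ("TT", "OP"): 0.02,
    ("TP", "OP"): 0.01,
    ("PP", "OP"): 0.002,
    ("TT", "PD"): 0.03,
    ("TP", "PD"): 0.04,
    ("PP", "PD"): 0.048,
}


class GenerationError(RuntimeError):
    """Tissue generation failed (e.g. pore collision budget exceeded)."""


@dataclasses.dataclass(frozen=True)
class TissueSpec:
    """Parameters of one synthetic tissue volume.

    Defaults describe a small FIB-SEM-like subvolume: a 9.6 µm cube at
    0.1 µm isotropic voxels with 8 cells, a TC fraction of 0.35 with mild
    spatial clustering, PD diameters of 0.02–0.06 µm (painted as single
    voxels) and OP diameters of 0.5–3 µm.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.1)
    n_cells: int = 8
    tc_fraction: float = 0.35
    tc_clustering: float = 0.5
    pore_intensity: dict[tuple[str, str], float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PORE_INTENSITY)
    )
    pd_cluster_size: float = 4.0  # mean pores per PD cluster
    pd_cluster_radius: float = 0.5  # µm, offspring placed within this of center
    pd_diameter_range: tuple[float, float] = (0.02, 0.06)
    op_diameter_range: tuple[float, float] = (0.5, 3.0)
    seed: int = 0
    collision_budget: float = 0.1  # max overwritten fraction of painted voxels
    retry_cap: int = 10  # re-draws for pores crossing another wall

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValidationError("n_cells must be >= 2")
        if not 0.0 <= self.tc_fraction <= 1.0:
            raise ValidationError("tc_fraction must be in [0, 1]")
        if self.tc_clustering < 0:
            raise ValidationError("tc_clustering must be >= 0")
        for key, v in self.pore_intensity.items():
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"intensity for {key} must be finite and >= 0")
        for rng_ in (self.pd_diameter_range, self.op_diameter_range):
            if not (0 < rng_[0] <= rng_[1]):
                raise ValidationError(f"bad diameter range {rng_}")
        if self.pd_diameter_range[1] >= self.op_diameter_range[0]:
            raise ValidationError("PD and OP diameter ranges must be disjoint (PD < OP)")


@dataclasses.dataclass
class GroundTruth:
    """True cell types, interfaces and pores of a generated volume.

    ``pores`` follows the pore annotation schema plus the generating
    interface (``cell_a``, ``cell_b``, ``iface_class``); ``counts`` records
    one row per (interface, kind) with the generating intensity and the
    realized Poisson draw.
    """

    cell_types: pd.DataFrame
    interfaces: pd.DataFrame
    pores: pd.DataFrame
    counts: pd.DataFrame


def generate_mosaic(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    n_cells: int,
    rng: np.random.Generator,
) -> LabeledVolume:
    """Voronoi mosaic of ``n_cells`` uniform seeds in physical units.

    Distances are computed on voxel centers in micrometers, so anisotropic
    voxels give geometrically correct walls. Every voxel is assigned; the
    mosaic has no background.
    """
    extent = np.asarray(shape) * np.asarray(spacing)
    seeds = rng.uniform(0.0, 1.0, size=(n_cells, 3)) * extent
    axes = [(np.arange(n) + 0.5) * d for n, d in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    _, nearest = cKDTree(seeds).query(pts, workers=-1)
    labels = (nearest.astype(np.int32) + 1).reshape(shape)
    return LabeledVolume(labels=labels, spacing=spacing, channel="cell")


def _assign_types(
    labels: np.ndarray,
    adjacency: dict[int, list[int]],
    tc_fraction: float,
    tc_clustering: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Bernoulli typing plus one Potts-like clustering sweep.

    Each cell's TC log-odds is shifted by ``tc_clustering`` times its TC
    neighbor excess over the expectation, so the overall TC fraction stays
    near ``tc_fraction`` while like types aggregate.
    """
    cells = sorted(adjacency)
    f = float(np.clip(tc_fraction, 1e-9, 1 - 1e-9))
    is_tc = {c: rng.random() < tc_fraction for c in cells}
    if tc_clustering > 0:
        base = logit(f)
        for c in cells:
            nbrs = adjacency[c]
            n_tc = sum(is_tc[n] for n in nbrs)
            lo = base + tc_clustering * (n_tc - f * len(nbrs))
            is_tc[c] = rng.random() < expit(lo)
    return pd.DataFrame(
        {
            "cell_label": cells,
            "cell_type": ["TC" if is_tc[c] else "PC" for c in cells],
        }
    )


def _draw_positions_on_faces(
    rec: InterfaceRecord,
    n: int,
    rng: np.random.Generator,
    face_subset: np.ndarray | None = None,
) -> np.ndarray:
    """Uniform positions on a wall: area-weighted face choice + in-plane jitter."""
    centers = rec.face_centers()
    weights = rec.face_areas
    if face_subset is not None:
        centers, weights = centers[face_subset], weights[face_subset]
    p = weights / weights.sum()
    chosen = rng.choice(len(centers), size=n, p=p)
    pos = centers[chosen].copy()
    d = np.asarray(rec.spacing)
    axes = rec.faces[:, 3] if face_subset is None else rec.faces[face_subset, 3]
    for i, fi in enumerate(chosen):
        normal = axes[fi]
        for k in range(3):
            if k != normal:
                pos[i, k] += rng.uniform(-0.5, 0.5) * d[k]
    return pos


def place_pores(
    interfaces: list[InterfaceRecord],
    spec: TissueSpec,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw pore annotations for a set of interfaces.

    Returns ``(pores, counts)``: the pore annotation table with true kind
    and generating interface, and the per-(interface, kind) table of
    generating intensity and realized Poisson count. OPs follow a
    homogeneous Poisson process on each wall; PD follow a Matérn-style
    cluster process (Poisson cluster centers, geometric offspring counts
    with mean ``pd_cluster_size``, offspring within ``pd_cluster_radius``
    of the center).
    """
    pores_rows: list[dict] = []
    counts_rows: list[dict] = []
    pore_id = 0

    for rec in interfaces:
        for kind in ("PD", "OP"):
            lam = spec.pore_intensity.get((rec.iface_class, kind), 0.0)
            mean_count = lam * rec.area
            if kind == "OP":
                n = int(rng.poisson(mean_count)) if mean_count > 0 else 0
                positions = (
                    _draw_positions_on_faces(rec, n, rng) if n else np.empty((0, 3))
                )
            else:
                n = 0
                positions_list = []
                if mean_count > 0:
                    n_clusters = int(rng.poisson(mean_count / spec.pd_cluster_size))
                    centers = rec.face_centers()
                    for _ in range(n_clusters):
                        c = _draw_positions_on_faces(rec, 1, rng)[0]
                        size = int(rng.geometric(1.0 / spec.pd_cluster_size))
                        near = np.nonzero(
                            np.linalg.norm(centers - c, axis=1) <= spec.pd_cluster_radius
                        )[0]
                        if near.size == 0:
                            near = None  # degenerate: fall back to whole wall
                        positions_list.append(
                            _draw_positions_on_faces(rec, size, rng, face_subset=near)
                        )
                        n += size
                positions = (
                    np.concatenate(positions_list, axis=0)
                    if positions_list
                    else np.empty((0, 3))
                )
            lo, hi = spec.pd_diameter_range if kind == "PD" else spec.op_diameter_range
            diameters = rng.uniform(lo, hi, size=n)
            for j in range(n):
                pore_id += 1
                pores_rows.append(
                    {
                        "pore_id": pore_id,
                        "cz": positions[j, 0],
                        "cy": positions[j, 1],
                        "cx": positions[j, 2],
                        "diameter": diameters[j],
                        "kind": kind,
                        "cell_a": rec.cell_a,
                        "cell_b": rec.cell_b,
                        "iface_class": rec.iface_class,
                    }
                )
            counts_rows.append(
                {
                    "cell_a": rec.cell_a,
                    "cell_b": rec.cell_b,
                    "iface_class": rec.iface_class,
                    "kind": kind,
                    "intensity_per_um2": lam,
                    "area_um2": rec.area,
                    "n_realized": n,
                }
            )

    pores = pd.DataFrame(
        pores_rows,
        columns=[
            "pore_id", "cz", "cy", "cx", "diameter", "kind",
            "cell_a", "cell_b", "iface_class",
        ],
    )
    counts = pd.DataFrame(
        counts_rows,
        columns=[
            "cell_a", "cell_b", "iface_class", "kind",
            "intensity_per_um2", "area_um2", "n_realized",
        ],
    )
    return pores, counts


def _paint_pores(
    cells: LabeledVolume,
    pores: pd.DataFrame,
    interfaces: list[InterfaceRecord],
    spec: TissueSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Paint pores as spheres into an instance-labeled pore grid.

    A pore whose sphere would cover voxels of a third cell (crossing a
    second interface) is re-positioned on its wall up to ``retry_cap``
    times, then clipped to its own two cells. Raises ``GenerationError``
    if the overwritten-voxel fraction exceeds the collision budget.
    """
    d = np.asarray(cells.spacing)
    grid = np.zeros(cells.shape, dtype=np.int32)
    labels = cells.labels
    by_pair = {r.pair: r for r in interfaces}
    painted = 0
    overwritten = 0
    pores = pores.copy()

    # paint large pores first so a small pore landing on a big one costs a
    # single overwritten voxel instead of vanishing entirely
    order = pores.sort_values("diameter", ascending=False, kind="mergesort").index
    for row in pores.loc[order].itertuples():
        r = float(row.diameter) / 2.0
        pair = (int(row.cell_a), int(row.cell_b))
        rec = by_pair[pair]
        pos = np.array([row.cz, row.cy, row.cx])
        for _attempt in range(spec.retry_cap + 1):
            lo_idx = np.maximum(np.floor((pos - r) / d).astype(int), 0)
            hi_idx = np.minimum(np.ceil((pos + r) / d).astype(int), np.asarray(cells.shape))
            if np.any(hi_idx <= lo_idx):  # sub-voxel pore: take containing voxel
                idx = np.minimum(
                    np.floor(pos / d).astype(int), np.asarray(cells.shape) - 1
                )
                sphere = idx[None, :]
            else:
                sub = np.stack(
                    np.meshgrid(
                        *[np.arange(lo_idx[k], hi_idx[k]) for k in range(3)],
                        indexing="ij",
                    ),
                    axis=-1,
                ).reshape(-1, 3)
                centers = (sub + 0.5) * d
                inside = np.linalg.norm(centers - pos, axis=1) <= r
                sphere = sub[inside]
                if sphere.shape[0] == 0:
                    idx = np.minimum(
                        np.floor(pos / d).astype(int), np.asarray(cells.shape) - 1
                    )
                    sphere = idx[None, :]
            cell_hits = labels[sphere[:, 0], sphere[:, 1], sphere[:, 2]]
            crosses = np.any(~np.isin(cell_hits, pair))
            if not crosses or _attempt == spec.retry_cap:
                if crosses:  # clip to own cells after exhausting retries
                    sphere = sphere[np.isin(cell_hits, pair)]
                break
            pos = _draw_positions_on_faces(rec, 1, rng)[0]
        pores.loc[row.Index, ["cz", "cy", "cx"]] = pos
        old = grid[sphere[:, 0], sphere[:, 1], sphere[:, 2]]
        overwritten += int((old > 0).sum())
        painted += sphere.shape[0]
        grid[sphere[:, 0], sphere[:, 1], sphere[:, 2]] = int(row.pore_id)

    if painted and overwritten / painted > spec.collision_budget:
        raise GenerationError(
            f"pore collision fraction {overwritten / painted:.2f} exceeds budget "
            f"{spec.collision_budget}; lower pore intensities or diameters"
        )
    return grid, pores


def generate_tissue(
    spec: TissueSpec,
    paint: bool = True,
) -> tuple[LabeledVolume, LabeledVolume, GroundTruth]:
    """Generate one synthetic tissue volume with ground truth.

    Returns ``(cell volume, pore volume, ground truth)``. With
    ``paint=False`` the pore volume is all background and pores exist only
    as the ground-truth annotation table (fast path for large statistical
    simulations where painting voxels adds nothing).
    """
    rng = np.random.default_rng(spec.seed)
    cells = generate_mosaic(spec.shape, spec.spacing, spec.n_cells, rng)

    # adjacency from a typeless pass, then type, then classify for real
    placeholder = pd.DataFrame(
        {"cell_label": cells.label_set(), "cell_type": "PC"}
    )
    raw = extract_interfaces(cells, placeholder, min_area=0.0)
    adjacency: dict[int, list[int]] = {int(c): [] for c in cells.label_set()}
    for rec in raw:
        adjacency[rec.cell_a].append(rec.cell_b)
        adjacency[rec.cell_b].append(rec.cell_a)

    cell_types = _assign_types(
        cells.labels, adjacency, spec.tc_fraction, spec.tc_clustering, rng
    )
    tmap = dict(zip(cell_types["cell_label"], cell_types["cell_type"]))
    interfaces = [
        dataclasses.replace(
            rec, iface_class=classify_interface(tmap[rec.cell_a], tmap[rec.cell_b])
        )
        for rec in raw
    ]

    pores, counts = place_pores(interfaces, spec, rng)

    if paint and len(pores):
        grid, pores = _paint_pores(cells, pores, interfaces, spec, rng)
    else:
        grid = np.zeros(spec.shape, dtype=np.int32)

    iface_frame = pd.DataFrame(
        {
            "cell_a": [r.cell_a for r in interfaces],
            "cell_b": [r.cell_b for r in interfaces],
            "iface_class": [r.iface_class for r in interfaces],
            "area_um2": [r.area for r in interfaces],
        }
    )
    gt = GroundTruth(
        cell_types=cell_types, interfaces=iface_frame, pores=pores, counts=counts
    )
    pore_vol = LabeledVolume(labels=grid, spacing=spec.spacing, channel="pore")
    return cells, pore_vol, gt


def tc_fraction_realized(gt: GroundTruth) -> float:
    """Fraction of cells typed TC in a generated volume."""
    if len(gt.cell_types) == 0:
        raise ValidationError("empty ground truth")
    return float((gt.cell_types["cell_type"] == "TC").mean())
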