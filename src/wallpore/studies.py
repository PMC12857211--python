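"""Simulation studies validating the pipeline end to end.

These are the package's benchmark experiments: OP-density parameter
recovery on full synthetic tissues, power and type-I calibration of the
directional spacing contrasts, and the planar-Poisson closed-form check
for mean nearest-neighbor distance. Problem sizes are chosen so each
study runs in minutes on one CPU while per-class wall areas stay above
10⁴ µm².
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from wallpore.interface_graph import classify_interface, extract_interfaces
from wallpore.pore_mapping import (
    PoreRecord,
    assign_pores,
    classify_pores,
    count_by_class,
    pores_from_annotations,
)
from wallpore.spatial_stats import nn_distances, nn_spacing_analysis
from wallpore.synthetic_tissue import TissueSpec, generate_tissue, place_pores

__all__ = [
    "recovery_spec",
    "spacing_spec",
    "recover_op_densities",
    "spacing_contrast_rates",
    "poisson_wall_mean_nn",
]

#: OP surface intensities (pores per µm² of wall) defining the contrast
#: between interface classes: most frequent at TC–TC, rarest at PC–PC.
OP_INTENSITY = {"TT": 0.02, "TP": 0.01, "PP": 0.002}


def recovery_spec(seed: int) -> TissueSpec:
    """Tissue regime for density recovery: a 60 µm cube at 0.5 µm voxels,
    110 cells, balanced cell types so every interface class carries well
    over 10⁴ µm² of wall."""
    return TissueSpec(
        shape=(120, 120, 120),
        spacing=(0.5, 0.5, 0.5),
        n_cells=110,
        tc_fraction=0.5,
        tc_clustering=0.0,
        seed=seed,
    )


def spacing_spec(seed: int, equal_intensity: bool = False) -> TissueSpec:
    """Tissue regime for spacing statistics: coarser 1 µm voxels and
    fewer, larger cells (144 µm cube, 64 cells) so individual walls are
    big enough to hold several OPs each. PD intensity is zero here; the
    spacing contrasts concern OPs."""
    lam = {c: 0.01 for c in OP_INTENSITY} if equal_intensity else OP_INTENSITY
    intensity = {(c, "OP"): lam[c] for c in lam}
    intensity.update({(c, "PD"): 0.0 for c in lam})
    return TissueSpec(
        shape=(144, 144, 144),
        spacing=(1.0, 1.0, 1.0),
        n_cells=64,
        tc_fraction=0.5,
        tc_clustering=0.0,
        pore_intensity=intensity,
        seed=seed,
    )


def _quantify_annotations(gt_pores: pd.DataFrame, interfaces) -> list[PoreRecord]:
    pores = pores_from_annotations(
        gt_pores[["pore_id", "cz", "cy", "cx", "diameter", "kind"]]
    )
    classify_pores(pores)
    return assign_pores(pores, interfaces)


def recover_op_densities(n_seeds: int, base_seed: int) -> pd.DataFrame:
    """Estimate OP density per interface class on fresh tissues.

    Each seed generates a full tissue, extracts interfaces from the cell
    volume, assigns the ground-truth pore annotations by nearest wall
    face, and reads the OP density off the per-class count table.

    Returns one row per seed with the estimated densities, per-class
    areas, and whether the TT > TP > PP rank order was reproduced.
    """
    rows = []
    for k in range(n_seeds):
        seed = int(base_seed + k)
        spec = recovery_spec(seed)
        cells, _, gt = generate_tissue(spec, paint=False)
        interfaces = extract_interfaces(cells, gt.cell_types, min_area=0.0)
        pores = _quantify_annotations(gt.pores, interfaces)
        counts = count_by_class(pores, interfaces)
        op = counts[counts.kind_set == "OP"].set_index("iface_class")
        both = counts[counts.kind_set == "PD+OP"].set_index("iface_class")
        d = op["density_per_um2"]
        rows.append(
            {
                "seed": seed,
                "density_tt": d["TT"],
                "density_tp": d["TP"],
                "density_pp": d["PP"],
                "area_tt": op.loc["TT", "total_area_um2"],
                "area_tp": op.loc["TP", "total_area_um2"],
                "area_pp": op.loc["PP", "total_area_um2"],
                "total_density_tt": both.loc["TT", "density_per_um2"],
                "total_density_tp": both.loc["TP", "density_per_um2"],
                "total_density_pp": both.loc["PP", "density_per_um2"],
                "rank_correct": bool(d["TT"] > d["TP"] > d["PP"]),
            }
        )
    return pd.DataFrame(rows)


def spacing_contrast_rates(
    n_seeds: int,
    base_seed: int,
    equal_intensity: bool = False,
    unit: str = "per-interface-mean",
    alpha: float = 0.05,
    n_mosaics: int = 10,
) -> pd.DataFrame:
    """Rejection rates of the one-tailed PP-spacing contrasts over seeds.

    Seeds are spread over a pool of ``n_mosaics`` Voronoi mosaics; each
    seed re-draws the cell types and the pore pattern on its mosaic, so
    the rates marginalize over tissue geometry without regenerating a
    voxel mosaic per seed. Under the contrasting intensities this
    measures power; under equal intensities (``equal_intensity=True``)
    the rejection rate estimates the type-I error at ``alpha``.
    """
    n_mosaics = min(n_mosaics, n_seeds)
    pool = []
    for m in range(n_mosaics):
        spec = spacing_spec(int(base_seed + m), equal_intensity=equal_intensity)
        cells, _, gt = generate_tissue(spec, paint=False)
        raw = extract_interfaces(cells, gt.cell_types, min_area=0.0)
        labels = sorted({r.cell_a for r in raw} | {r.cell_b for r in raw})
        pool.append((spec, raw, labels))
    rows = []
    for k in range(n_seeds):
        spec, raw, labels = pool[k % n_mosaics]
        seed = int(base_seed + n_mosaics + k)
        rng = np.random.default_rng(seed)
        tmap = {c: ("TC" if rng.random() < spec.tc_fraction else "PC") for c in labels}
        interfaces = [
            dataclasses.replace(
                r, iface_class=classify_interface(tmap[r.cell_a], tmap[r.cell_b])
            )
            for r in raw
        ]
        pores_df, _ = place_pores(interfaces, spec, rng)
        pores = _quantify_annotations(pores_df, interfaces)
        nn = nn_distances(pores, kind_set="OP")
        res = nn_spacing_analysis(nn, unit=unit)
        entry = res.get(("all", "OP"), {"contrasts": {}})
        contrasts = entry["contrasts"]
        rows.append(
            {
                "seed": seed,
                "p_pp_gt_tt": contrasts["PP>TT"].p_one_tailed
                if "PP>TT" in contrasts
                else np.nan,
                "p_pp_gt_tp": contrasts["PP>TP"].p_one_tailed
                if "PP>TP" in contrasts
                else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["alpha"] = alpha
    return df


def poisson_wall_mean_nn(
    n_seeds: int,
    base_seed: int,
    intensity: float = 0.01,
    side: float = 500.0,
) -> float:
    """Edge-corrected mean NN distance of Poisson OPs on a flat wall.

    Points are a homogeneous Poisson process of the given intensity on a
    ``side`` × ``side`` µm wall; pores within twice the theoretical mean
    NN distance (2 · 1/(2√λ)) of the border are excluded as focal points
    but retained as neighbors. The closed-form expectation for the
    planar Poisson process is 1/(2√λ).
    """
    margin = 2.0 * 1.0 / (2.0 * np.sqrt(intensity))
    means = []
    for k in range(n_seeds):
        rng = np.random.default_rng(int(base_seed + k))
        n = rng.poisson(intensity * side * side)
        ys = rng.uniform(0, side, n)
        xs = rng.uniform(0, side, n)
        pores = [
            PoreRecord(
                pore_id=i + 1,
                centroid=(0.0, float(ys[i]), float(xs[i])),
                volume=1.0,
                eq_diameter=1.0,
                kind="OP",
                interface=(1, 2),
                iface_class="TT",
            )
            for i in range(n)
        ]
        table = nn_distances(pores, kind_set="OP")
        interior = (
            (table["pore_id"].map(lambda i: ys[i - 1]).between(margin, side - margin))
            & (table["pore_id"].map(lambda i: xs[i - 1]).between(margin, side - margin))
        )
        means.append(table.loc[interior, "nn_distance_um"].mean())
    return float(np.mean(means))
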