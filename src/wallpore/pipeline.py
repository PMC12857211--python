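"""Configuration-driven end-to-end runs: simulate → quantify → test → report.

A run is described by a ``RunConfig`` (YAML-serializable); outputs are
plain CSV/JSON files plus a manifest echoing every threshold actually
used, so a rerun with the same config and seed reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import wallpore
from wallpore import interface_graph, pore_mapping, spatial_stats, synthetic_tissue
from wallpore.volume_io import (
    LabeledVolume,
    ValidationError,
    read_table,
    read_volume,
    write_table,
    write_volume,
)

__all__ = ["RunConfig", "run_simulate", "run_quantify", "run_dynamics"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """One quantification run: either on-disk volumes or a tissue spec.

    Exactly one of (``cell_volume``, …) and ``tissue`` must be set.
    All thresholds are micrometers (areas µm²); ``nn_unit`` selects the
    t-test unit of observation.
    """

    # inputs, route A: files
    cell_volume: str | None = None
    cell_types: str | None = None
    pore_volume: str | None = None
    pore_table: str | None = None
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.1)
    # inputs, route B: simulation
    tissue: synthetic_tissue.TissueSpec | None = None
    # analysis parameters
    min_area: float | None = None
    pd_op_threshold: float = pore_mapping.DEFAULT_PD_OP_THRESHOLD_UM
    max_assign_distance: float = pore_mapping.DEFAULT_MAX_ASSIGN_DISTANCE_UM
    nn_unit: str = "per-pore"
    welch: bool = False
    alpha: float = 0.05
    group: str = "sample"
    seed: int = 0
    outdir: str = "results/run"

    def __post_init__(self) -> None:
        has_files = self.cell_volume is not None
        has_spec = self.tissue is not None
        if has_files == has_spec:
            raise ValidationError(
                "exactly one of an input cell volume or a tissue spec must be set"
            )
        if self.pd_op_threshold <= 0 or self.max_assign_distance <= 0:
            raise ValidationError("thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from YAML; keyword overrides take precedence."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "tissue" in raw and isinstance(raw["tissue"], dict):
            t = raw["tissue"]
            for key in ("shape", "spacing", "pd_diameter_range", "op_diameter_range"):
                if key in t:
                    t[key] = tuple(t[key])
            if "pore_intensity" in t:
                t["pore_intensity"] = {
                    tuple(k.split("/")): float(v) for k, v in t["pore_intensity"].items()
                }
            raw["tissue"] = synthetic_tissue.TissueSpec(**t)
        if "spacing" in raw:
            raw["spacing"] = tuple(raw["spacing"])
        return cls(**raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        if self.tissue is not None:
            t = d["tissue"]
            t["pore_intensity"] = {
                "/".join(k): v for k, v in t["pore_intensity"].items()
            }
        return d


def _manifest(config: RunConfig, stages: dict) -> dict:
    return {
        "config": config.to_manifest(),
        "versions": {
            "wallpore": wallpore.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": stages,
    }


def _load_inputs(config: RunConfig):
    """Produce (cells, types, pores) from files or by simulation."""
    if config.tissue is not None:
        spec = dataclasses.replace(config.tissue, seed=config.seed)
        cells, pore_vol, gt = synthetic_tissue.generate_tissue(spec)
        types = gt.cell_types
        if pore_vol.n_labels:
            pores = pore_mapping.extract_pore_components(pore_vol)
        else:
            pores = []
        return cells, types, pores
    cells = read_volume(config.cell_volume, spacing=config.spacing, channel="cell")
    types = read_table(config.cell_types, "cell_types")
    if config.pore_volume is not None:
        pvol = read_volume(config.pore_volume, spacing=config.spacing, channel="pore")
        pores = pore_mapping.extract_pore_components(pvol)
    elif config.pore_table is not None:
        pores = pore_mapping.pores_from_annotations(read_table(config.pore_table, "pores"))
    else:
        pores = []
    return cells, types, pores


def run_quantify(config: RunConfig) -> dict:
    """Full quantification: interfaces, pore mapping, NN spacing tests.

    Writes interfaces.csv, pores.csv, class_counts.csv, nn_distances.csv,
    tests.json and manifest.json under ``config.outdir`` and returns the
    result bundle in memory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    stage = "load"
    try:
        cells, types, pores = _load_inputs(config)
        stages["load"] = {"n_cells": int(cells.n_labels), "n_pore_components": len(pores)}

        stage = "interfaces"
        interfaces = interface_graph.extract_interfaces(cells, types, min_area=config.min_area)
        stages["interfaces"] = {
            "n_interfaces": len(interfaces),
            "total_area_um2": float(sum(r.area for r in interfaces)),
        }

        stage = "pores"
        pores = pore_mapping.classify_pores(pores, threshold=config.pd_op_threshold)
        pores = pore_mapping.assign_pores(
            pores, interfaces, max_distance=config.max_assign_distance
        )
        class_counts = pore_mapping.count_by_class(pores, interfaces)
        stages["pores"] = {
            "n_pores": len(pores),
            "n_unassigned": int(class_counts.attrs["n_unassigned"]),
        }

        stage = "spacing"
        nn = pd.concat(
            [
                spatial_stats.nn_distances(pores, kind_set=ks, group=config.group)
                for ks in ("OP", "PD+OP")
            ],
            ignore_index=True,
        )
        results = spatial_stats.nn_spacing_analysis(
            nn, unit=config.nn_unit, welch=config.welch
        )
        contrasts = spatial_stats.analysis_to_frame(results)
        stages["spacing"] = {"n_nn_rows": len(nn), "n_contrasts": len(contrasts)}
    except Exception as exc:
        for f in outdir.glob("*"):
            f.unlink()
        raise RuntimeError(f"quantify failed at stage {stage!r}: {exc}") from exc

    write_table(interface_graph.interfaces_to_frame(interfaces), outdir / "interfaces.csv")
    write_table(pore_mapping.pores_to_frame(pores), outdir / "pores.csv")
    write_table(class_counts, outdir / "class_counts.csv")
    write_table(nn, outdir / "nn_distances.csv")

    tests_payload = {
        f"{g}|{ks}": {
            "boxes": {
                cls: dataclasses.asdict(b) for cls, b in entry["boxes"].items()
            },
            "contrasts": {
                name: dataclasses.asdict(r) for name, r in entry["contrasts"].items()
            },
        }
        for (g, ks), entry in results.items()
    }
    (outdir / "tests.json").write_text(
        json.dumps(tests_payload, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "manifest.json").write_text(
        json.dumps(_manifest(config, stages), indent=2, sort_keys=True) + "\n"
    )
    return {
        "interfaces": interfaces,
        "pores": pores,
        "class_counts": class_counts,
        "nn": nn,
        "results": results,
        "contrasts": contrasts,
    }


def run_simulate(config: RunConfig) -> dict:
    """Generate a tissue volume and write volumes + ground truth."""
    if config.tissue is None:
        raise ValidationError("simulate requires a tissue spec")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = dataclasses.replace(config.tissue, seed=config.seed)
    cells, pore_vol, gt = synthetic_tissue.generate_tissue(spec)
    write_volume(cells, outdir / "cells.tif")
    write_volume(pore_vol, outdir / "pores.tif")
    write_table(gt.cell_types, outdir / "cell_types.csv")
    write_table(gt.interfaces, outdir / "true_interfaces.csv")
    write_table(gt.pores, outdir / "true_pores.csv")
    write_table(gt.counts, outdir / "true_counts.csv")
    (outdir / "manifest.json").write_text(
        json.dumps(_manifest(config, {"simulate": {"n_cells": int(cells.n_labels),
                                                   "n_pores": len(gt.pores)}}),
                   indent=2, sort_keys=True) + "\n"
    )
    return {"cells": cells, "pore_volume": pore_vol, "ground_truth": gt}


def run_dynamics(config: RunConfig, measurements: str | Path) -> dict:
    """Tukey HSD with compact letters over a measurement table."""
    from wallpore import dynamics_stats

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = read_table(measurements, "measurements")
    n_groups = table["group"].nunique()
    if n_groups < 2:
        raise ValidationError(
            f"Tukey HSD needs >= 2 groups with >= 2 replicates; got {n_groups} group(s)"
        )
    res = dynamics_stats.tukey_hsd(table, alpha=config.alpha)
    write_table(res.pairwise, outdir / "tukey_pairwise.csv")
    letters = pd.DataFrame(
        {"group": list(res.letters), "letters": list(res.letters.values())}
    )
    write_table(letters, outdir / "letters.csv")
    payload = {
        "alpha": res.alpha,
        "ms_error": res.ms_error,
        "df_error": res.df_error,
        "balanced": res.balanced,
        "letters": res.letters,
    }
    (outdir / "dynamics.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "manifest.json").write_text(
        json.dumps(
            _manifest(config, {"dynamics": {"n_groups": int(n_groups), "n_rows": len(table)}}),
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return {"tukey": res, "table": table}
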