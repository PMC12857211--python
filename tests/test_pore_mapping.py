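"""Pore component extraction, size classification, assignment, counting."""

import numpy as np
import pandas as pd
import pytest

from wallpore.interface_graph import extract_interfaces
from wallpore.pore_mapping import (
    assign_pores,
    classify_pores,
    count_by_class,
    extract_pore_components,
    pores_from_annotations,
)
from wallpore.volume_io import ValidationError

from conftest import make_volume, type_table


def flood_fill_count(binary):
    """Brute-force 26-connectivity component count."""
    visited = np.zeros_like(binary, dtype=bool)
    shape = binary.shape
    count = 0
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        count += 1
        stack = [start]
        visited[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= p[i] < shape[i] for i in range(3)):
                    if binary[p] and not visited[p]:
                        visited[p] = True
                        stack.append(p)
    return count


class TestExtract:
    def test_single_voxel_closed_form(self):
        arr = np.zeros((3, 3, 3), dtype=np.int32)
        arr[1, 1, 1] = 1
        recs = extract_pore_components(make_volume(arr, channel="pore"))
        assert len(recs) == 1
        assert recs[0].volume == pytest.approx(1.0)
        assert recs[0].eq_diameter == pytest.approx((6 / np.pi) ** (1 / 3))
        assert recs[0].centroid == pytest.approx((1.5, 1.5, 1.5))

    def test_diagonal_voxels_one_component_binary(self):
        arr = np.zeros((2, 2, 2), dtype=np.int32)
        arr[0, 0, 0] = 1
        arr[1, 1, 1] = 1  # touch only at a corner
        recs = extract_pore_components(make_volume(arr, channel="pore"))
        assert len(recs) == 1
        assert recs[0].volume == pytest.approx(2.0)

    def test_instance_labels_kept_separate(self):
        arr = np.zeros((1, 1, 3), dtype=np.int32)
        arr[0, 0, 0], arr[0, 0, 1] = 1, 2  # touching but distinct instances
        recs = extract_pore_components(make_volume(arr, channel="pore"))
        assert [r.pore_id for r in recs] == [1, 2]

    def test_empty_volume(self):
        assert extract_pore_components(
            make_volume(np.zeros((2, 2, 2), dtype=np.int32), channel="pore")
        ) == []

    def test_component_count_matches_flood_fill(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            shape = tuple(rng.integers(3, 15, size=3))
            binary = (rng.random(shape) < 0.08).astype(np.int32)
            recs = extract_pore_components(make_volume(binary, channel="pore"))
            assert len(recs) == flood_fill_count(binary)


class TestClassify:
    def test_threshold_rule(self):
        pores = pores_from_annotations(
            pd.DataFrame(
                {
                    "pore_id": [1, 2],
                    "cz": [0, 0],
                    "cy": [0, 0],
                    "cx": [0, 0],
                    "diameter": [1.0, 0.05],
                    "kind": ["unset", "unset"],
                }
            )
        )
        classify_pores(pores, threshold=0.2)
        assert [p.kind for p in pores] == ["OP", "PD"]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValidationError):
            classify_pores([], threshold=0.0)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        diam = rng.uniform(0.01, 3.0, size=50)
        pores = pores_from_annotations(
            pd.DataFrame(
                {
                    "pore_id": np.arange(1, 51),
                    "cz": 0.0,
                    "cy": 0.0,
                    "cx": 0.0,
                    "diameter": diam,
                    "kind": "unset",
                }
            )
        )
        counts = []
        for thr in (0.05, 0.2, 0.5, 1.0, 2.0):
            classify_pores(pores, threshold=thr)
            counts.append(sum(p.kind == "OP" for p in pores))
        assert counts == sorted(counts, reverse=True)


class TestAssign:
    def test_pore_on_face_assigned(self, two_cell_volume):
        vol, types = two_cell_volume
        ifaces = extract_interfaces(vol, types, min_area=0.0)
        pores = pores_from_annotations(
            pd.DataFrame(
                {
                    "pore_id": [1],
                    "cz": [0.5],
                    "cy": [0.5],
                    "cx": [1.0],  # exactly on the shared face
                    "diameter": [0.5],
                    "kind": ["OP"],
                }
            )
        )
        assign_pores(pores, ifaces, max_distance=2.0)
        assert pores[0].interface == (1, 2)
        assert pores[0].iface_class == "TP"

    def test_far_pore_unassigned(self, two_cell_volume):
        vol, types = two_cell_volume
        ifaces = extract_interfaces(vol, types, min_area=0.0)
        pores = pores_from_annotations(
            pd.DataFrame(
                {
                    "pore_id": [1],
                    "cz": [0.5],
                    "cy": [0.5],
                    "cx": [50.0],
                    "diameter": [0.5],
                    "kind": ["OP"],
                }
            )
        )
        assign_pores(pores, ifaces, max_distance=2.0)
        assert pores[0].interface is None

    def test_no_interfaces_all_unassigned(self):
        pores = pores_from_annotations(
            pd.DataFrame(
                {
                    "pore_id": [1],
                    "cz": [0.0],
                    "cy": [0.0],
                    "cx": [0.0],
                    "diameter": [0.5],
                    "kind": ["OP"],
                }
            )
        )
        assign_pores(pores, [], max_distance=2.0)
        assert pores[0].interface is None

    def test_ground_truth_assignment_recovered(self):
        from wallpore.synthetic_tissue import TissueSpec, generate_tissue

        spec = TissueSpec(
            shape=(48, 48, 48), spacing=(0.5, 0.5, 0.5), n_cells=12,
            tc_fraction=0.5, seed=5,
        )
        cells, _, gt = generate_tissue(spec, paint=False)
        ifaces = extract_interfaces(cells, gt.cell_types, min_area=0.0)
        pores = pores_from_annotations(
            gt.pores[["pore_id", "cz", "cy", "cx", "diameter", "kind"]]
        )
        assign_pores(pores, ifaces, max_distance=2.0)
        truth = {
            int(r.pore_id): (int(r.cell_a), int(r.cell_b)) for r in gt.pores.itertuples()
        }
        assigned = [p for p in pores if p.interface is not None]
        correct = sum(p.interface == truth[p.pore_id] for p in assigned)
        assert len(assigned) == len(pores)
        assert correct / len(pores) >= 0.99

    def test_partition_invariant(self, two_cell_volume):
        vol, types = two_cell_volume
        ifaces = extract_interfaces(vol, types, min_area=0.0)
        rng = np.random.default_rng(0)
        pores = pores_from_annotations(
            pd.DataFrame(
                {
                    "pore_id": np.arange(1, 21),
                    "cz": rng.uniform(0, 1, 20),
                    "cy": rng.uniform(0, 1, 20),
                    "cx": rng.uniform(0, 30, 20),
                    "diameter": 0.5,
                    "kind": "OP",
                }
            )
        )
        classify_pores(pores)
        assign_pores(pores, ifaces, max_distance=2.0)
        counts = count_by_class(pores, ifaces)
        n_assigned = counts[counts.kind_set == "PD+OP"]["n_pores"].sum()
        assert n_assigned + counts.attrs["n_unassigned"] == 20


class TestCounts:
    def test_no_pores_zero_densities(self, two_cell_volume):
        vol, types = two_cell_volume
        ifaces = extract_interfaces(vol, types, min_area=0.0)
        counts = count_by_class([], ifaces)
        assert (counts["n_pores"] == 0).all()
        assert (counts["density_per_um2"] == 0.0).all()
        assert counts[counts.iface_class == "TP"]["total_area_um2"].iloc[0] == 1.0

    def test_density_arithmetic(self, flat_wall_volume):
        vol, types = flat_wall_volume(2, 1, types=("TC", "PC"))  # wall area 2
        ifaces = extract_interfaces(vol, types, min_area=0.0)
        pores = pores_from_annotations(
            pd.DataFrame(
                {
                    "pore_id": [1, 2, 3],
                    "cz": [2.0, 2.0, 2.0],
                    "cy": [0.5, 1.5, 0.5],
                    "cx": [0.5, 0.5, 0.4],
                    "diameter": [1.0, 1.0, 1.0],
                    "kind": ["unset"] * 3,
                }
            )
        )
        classify_pores(pores, threshold=0.2)
        assign_pores(pores, ifaces)
        counts = count_by_class(pores, ifaces)
        row = counts[(counts.iface_class == "TP") & (counts.kind_set == "OP")].iloc[0]
        assert row["n_pores"] == 3
        assert row["density_per_um2"] == pytest.approx(1.5)

    def test_pd_plus_op_additivity(self):
        rng = np.random.default_rng(9)
        from wallpore.synthetic_tissue import TissueSpec, generate_tissue

        spec = TissueSpec(
            shape=(32, 32, 32), spacing=(0.5, 0.5, 0.5), n_cells=8, seed=17
        )
        cells, _, gt = generate_tissue(spec, paint=False)
        ifaces = extract_interfaces(cells, gt.cell_types, min_area=0.0)
        pores = pores_from_annotations(
            gt.pores[["pore_id", "cz", "cy", "cx", "diameter", "kind"]]
        )
        classify_pores(pores)
        assign_pores(pores, ifaces)
        counts = count_by_class(pores, ifaces).set_index(["iface_class", "kind_set"])
        for cls in ("TT", "TP", "PP"):
            assert (
                counts.loc[(cls, "PD+OP"), "n_pores"]
                == counts.loc[(cls, "PD"), "n_pores"] + counts.loc[(cls, "OP"), "n_pores"]
            )

    def test_classification_agrees_with_ground_truth(self):
        from wallpore.synthetic_tissue import TissueSpec, generate_tissue

        spec = TissueSpec(
            shape=(32, 32, 32), spacing=(0.5, 0.5, 0.5), n_cells=8, seed=23
        )
        _, _, gt = generate_tissue(spec, paint=False)
        pores = pores_from_annotations(
            gt.pores[["pore_id", "cz", "cy", "cx", "diameter", "kind"]].assign(kind="unset")
        )
        classify_pores(pores, threshold=0.2)
        got = {p.pore_id: p.kind for p in pores}
        for r in gt.pores.itertuples():
            assert got[int(r.pore_id)] == r.kind
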