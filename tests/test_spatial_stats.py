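"""Nearest-neighbor spacing tables, box summaries, directional t tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wallpore.pore_mapping import PoreRecord
from wallpore.spatial_stats import (
    box_summary,
    compare_groups,
    nn_distances,
    nn_spacing_analysis,
)
from wallpore.volume_io import ValidationError


def pore(pid, z, y, x, kind="OP", interface=(1, 2), iface_class="TT"):
    return PoreRecord(
        pore_id=pid,
        centroid=(z, y, x),
        volume=1.0,
        eq_diameter=1.0,
        kind=kind,
        interface=interface,
        iface_class=iface_class,
    )


class TestNNDistances:
    def test_mutual_pair(self):
        pores = [pore(1, 0, 0, 0), pore(2, 0, 0, 3.0)]
        table = nn_distances(pores, kind_set="OP")
        assert len(table) == 2
        assert (table["nn_distance_um"] == 3.0).all()

    def test_single_pore_excluded(self):
        assert len(nn_distances([pore(1, 0, 0, 0)], kind_set="OP")) == 0

    def test_collinear_hand_example(self):
        pores = [pore(1, 0, 0, 0), pore(2, 0, 0, 1.0), pore(3, 0, 0, 5.0)]
        table = nn_distances(pores, kind_set="OP")
        assert sorted(table["nn_distance_um"]) == [1.0, 1.0, 4.0]

    def test_kind_set_restriction(self):
        pores = [
            pore(1, 0, 0, 0, kind="OP"),
            pore(2, 0, 0, 1.0, kind="PD"),
            pore(3, 0, 0, 5.0, kind="OP"),
        ]
        op_only = nn_distances(pores, kind_set="OP")
        assert sorted(op_only["nn_distance_um"]) == [5.0, 5.0]
        combined = nn_distances(pores, kind_set="PD+OP")
        assert sorted(combined["nn_distance_um"]) == [1.0, 1.0, 4.0]

    def test_distances_within_interface_only(self):
        pores = [
            pore(1, 0, 0, 0, interface=(1, 2)),
            pore(2, 0, 0, 0.5, interface=(3, 4), iface_class="PP"),
            pore(3, 0, 0, 9.0, interface=(1, 2)),
            pore(4, 0, 0, 9.2, interface=(3, 4), iface_class="PP"),
        ]
        table = nn_distances(pores, kind_set="OP")
        by_iface = table.groupby(["cell_a", "cell_b"])["nn_distance_um"].unique()
        assert list(by_iface[(1, 2)]) == [9.0]
        assert list(by_iface[(3, 4)]) == [pytest.approx(8.7)]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        pores = []
        pid = 0
        for iface, n in [((1, 2), 30), ((2, 3), 120), ((3, 4), 250)]:
            for _ in range(n):
                pid += 1
                z, y, x = rng.uniform(0, 50, size=3)
                pores.append(pore(pid, z, y, x, interface=iface))
        table = nn_distances(pores, kind_set="OP").set_index("pore_id")
        by_iface = {}
        for p in pores:
            by_iface.setdefault(p.interface, []).append(p)
        for members in by_iface.values():
            pts = np.array([p.centroid for p in members])
            for i, p in enumerate(members):
                d = np.delete(np.linalg.norm(pts - pts[i], axis=1), i).min()
                assert table.loc[p.pore_id, "nn_distance_um"] == pytest.approx(d)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        pores = [
            pore(i + 1, *rng.uniform(0, 10, size=3)) for i in range(40)
        ]
        scaled = [
            PoreRecord(
                pore_id=p.pore_id,
                centroid=tuple(3.0 * c for c in p.centroid),
                volume=p.volume,
                eq_diameter=p.eq_diameter,
                kind=p.kind,
                interface=p.interface,
                iface_class=p.iface_class,
            )
            for p in pores
        ]
        d1 = nn_distances(pores, kind_set="OP")["nn_distance_um"].to_numpy()
        d2 = nn_distances(scaled, kind_set="OP")["nn_distance_um"].to_numpy()
        assert np.allclose(d2, 3.0 * d1)


class TestBoxSummary:
    def test_single_value(self):
        b = box_summary([5.0])
        assert b.median == b.q1 == b.q3 == 5.0
        assert b.whisker_low == b.whisker_high == 5.0
        assert b.outliers == ()

    def test_outlier_flagged(self):
        b = box_summary([1, 2, 3, 4, 100])
        assert b.outliers == (100.0,)
        assert b.whisker_high == 4.0
        assert b.whisker_low == 1.0

    def test_quartile_order_invariant(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            v = rng.normal(size=rng.integers(1, 30))
            b = box_summary(v)
            assert b.q1 <= b.median <= b.q3
            iqr = b.q3 - b.q1
            assert all(
                o < b.q1 - 1.5 * iqr or o > b.q3 + 1.5 * iqr for o in b.outliers
            )
            assert b.whisker_low >= b.q1 - 1.5 * iqr
            assert b.whisker_high <= b.q3 + 1.5 * iqr

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            box_summary([])


class TestCompareGroups:
    def test_identical_samples_symmetric(self):
        r = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == pytest.approx(0.0)
        assert r.p_one_tailed == pytest.approx(0.5)
        assert r.significance_code == "ns"

    def test_hand_computed_pooled_t(self):
        """Textbook pooled-variance computation reproduced to 6 decimals."""
        a = np.array([2.0, 2.0, 2.1])
        b = np.array([1.0, 1.1, 1.0])
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        p_hand = stats.t.sf(t_hand, a.size + b.size - 2)
        r = compare_groups(a, b)
        assert r.t_statistic == pytest.approx(t_hand, abs=1e-6)
        assert r.p_one_tailed == pytest.approx(p_hand, abs=1e-6)
        assert r.degrees_of_freedom == 4
        assert r.significance_code == "**"

    def test_degenerate_zero_variance(self):
        r = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert r.p_one_tailed == 0.5
        assert r.significance_code == "ns"

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([1.0], [1.0, 2.0])

    def test_type_i_calibration(self):
        """Rejection rate at the 0.05 level ≈ 0.05 for iid null samples."""
        rng = np.random.default_rng(7)
        n_sim = 4000
        rej = 0
        for _ in range(n_sim):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            rej += compare_groups(a, b).p_one_tailed < 0.05
        rate = rej / n_sim
        assert abs(rate - 0.05) < 0.012

    def test_scale_invariance_of_t(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(2, 1, 10), rng.normal(1, 1, 12)
        r1 = compare_groups(a, b)
        r2 = compare_groups(7.0 * a, 7.0 * b)
        assert r2.t_statistic == pytest.approx(r1.t_statistic)
        assert r2.p_one_tailed == pytest.approx(r1.p_one_tailed)


class TestSpacingAnalysis:
    def _table(self, rng, means):
        rows = []
        iface_id = 0
        for cls, mu in means.items():
            for _ in range(12):  # interfaces per class
                iface_id += 1
                for _ in range(6):  # pores per interface
                    rows.append(
                        {
                            "group": "cv1",
                            "iface_class": cls,
                            "cell_a": iface_id,
                            "cell_b": iface_id + 1000,
                            "pore_id": len(rows) + 1,
                            "kind_set": "OP",
                            "nn_distance_um": rng.normal(mu, 0.3),
                        }
                    )
        return pd.DataFrame(rows)

    def test_direction_detected(self):
        rng = np.random.default_rng(9)
        table = self._table(rng, {"TT": 3.0, "TP": 3.5, "PP": 9.0})
        res = nn_spacing_analysis(table)
        entry = res[("cv1", "OP")]
        assert entry["contrasts"]["PP>TT"].significance_code in ("*", "**")
        assert entry["contrasts"]["PP>TP"].significance_code in ("*", "**")
        assert entry["boxes"]["PP"].median > entry["boxes"]["TT"].median

    def test_only_pp_no_contrasts(self):
        rng = np.random.default_rng(10)
        table = self._table(rng, {"PP": 5.0})
        res = nn_spacing_analysis(table)
        assert res[("cv1", "OP")]["contrasts"] == {}

    def test_per_interface_mean_unit(self):
        rng = np.random.default_rng(11)
        table = self._table(rng, {"TT": 3.0, "PP": 9.0})
        res = nn_spacing_analysis(table, unit="per-interface-mean")
        r = res[("cv1", "OP")]["contrasts"]["PP>TT"]
        assert r.n_a == 12 and r.n_b == 12  # one observation per interface

    def test_poisson_closed_form_mean(self):
        """Edge-corrected mean NN on a large Poisson wall ≈ 1/(2√λ)."""
        lam, side = 0.01, 300.0
        rng = np.random.default_rng(12)
        means = []
        for _ in range(10):
            n = rng.poisson(lam * side * side)
            ys, xs = rng.uniform(0, side, n), rng.uniform(0, side, n)
            pores = [
                pore(i + 1, 0.0, ys[i], xs[i]) for i in range(n)
            ]
            table = nn_distances(pores, kind_set="OP")
            pos = {p.pore_id: p.centroid for p in pores}
            margin = 2 * 1 / (2 * np.sqrt(lam))
            keep = [
                d
                for pid, d in zip(table["pore_id"], table["nn_distance_um"])
                if margin <= pos[pid][1] <= side - margin
                and margin <= pos[pid][2] <= side - margin
            ]
            means.append(np.mean(keep))
        assert np.mean(means) == pytest.approx(1 / (2 * np.sqrt(lam)), rel=0.03)
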