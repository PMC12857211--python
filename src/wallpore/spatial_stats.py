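"""Nearest-neighbor pore-spacing statistics and directional group tests.

Nearest-neighbor (NN) distances are computed *within* a single interface
— spacing between pores on unrelated walls is biologically meaningless —
and pooled by interface class afterwards. Distances are 3D Euclidean
between centroids in physical units; interfaces with fewer than two
eligible pores contribute nothing.

Group contrasts use the pooled-variance (Student's) two-sample t test,
one-tailed in a stated direction, with significance codes * (p < 0.05)
and ** (p < 0.01). For a planar Poisson process of intensity λ the mean
NN distance is 1/(2·√λ), which anchors the simulation checks.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from wallpore.pore_mapping import PoreRecord
from wallpore.volume_io import ValidationError

__all__ = [
    "BoxSummary",
    "DirectionalTestResult",
    "nn_distances",
    "box_summary",
    "compare_groups",
    "nn_spacing_analysis",
]

logger = logging.getLogger(__name__)

KIND_SETS = {"OP": ("OP",), "PD+OP": ("PD", "OP")}


@dataclasses.dataclass(frozen=True)
class BoxSummary:
    """Tukey box-and-whisker summary of one sample.

    Whiskers are the extreme values excluding outliers; outliers lie
    outside [q1 − 1.5·IQR, q3 + 1.5·IQR]. Quartiles use linear
    interpolation between order statistics.
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    n: int


@dataclasses.dataclass(frozen=True)
class DirectionalTestResult:
    """One-tailed two-sample Student's t result."""

    t_statistic: float
    degrees_of_freedom: int
    p_one_tailed: float
    direction: str  # "a>b"
    significance_code: str  # ns | * | **
    n_a: int
    n_b: int


def nn_distances(
    pores: list[PoreRecord],
    kind_set: str = "OP",
    group: str = "all",
) -> pd.DataFrame:
    """Within-interface nearest-neighbor distance table.

    Parameters
    ----------
    pores
        Assigned pore records (kind set, interface set).
    kind_set
        ``"OP"`` (open pores only) or ``"PD+OP"`` (all pores combined).
    group
        Label (e.g. cultivar) written into every row.

    Returns
    -------
    One row per eligible pore: (group, iface_class, cell_a, cell_b,
    pore_id, nn_distance_um). A pore is eligible when its interface has
    ≥ 2 pores of the kind set.
    """
    if kind_set not in KIND_SETS:
        raise ValidationError(f"kind_set must be one of {list(KIND_SETS)}")
    kinds = KIND_SETS[kind_set]

    by_iface: dict[tuple[int, int], list[PoreRecord]] = {}
    for p in pores:
        if p.interface is None or p.kind not in kinds:
            continue
        by_iface.setdefault(p.interface, []).append(p)

    rows = []
    for pair in sorted(by_iface):
        members = by_iface[pair]
        if len(members) < 2:
            continue
        pts = np.array([p.centroid for p in members])
        if len(members) <= 200:
            diff = pts[:, None, :] - pts[None, :, :]
            dist = np.sqrt((diff**2).sum(axis=-1))
            np.fill_diagonal(dist, np.inf)
            nn = dist.min(axis=1)
        else:
            d, _ = cKDTree(pts).query(pts, k=2)
            nn = d[:, 1]
        iface_class = members[0].iface_class
        for p, dd in zip(members, nn):
            rows.append(
                {
                    "group": group,
                    "iface_class": iface_class,
                    "cell_a": pair[0],
                    "cell_b": pair[1],
                    "pore_id": p.pore_id,
                    "kind_set": kind_set,
                    "nn_distance_um": float(dd),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "iface_class", "cell_a", "cell_b",
            "pore_id", "kind_set", "nn_distance_um",
        ],
    )


def box_summary(values) -> BoxSummary:
    """Five-number box summary with 1.5·IQR outlier flagging."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("box_summary needs at least one value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    inliers = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inliers.min()),
        whisker_high=float(inliers.max()),
        outliers=tuple(sorted(float(x) for x in outliers)),
        n=int(v.size),
    )


def _significance_code(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(a, b, direction: str = "a>b", welch: bool = False) -> DirectionalTestResult:
    """One-tailed two-sample t test that group ``a`` exceeds group ``b``.

    Pooled-variance Student's t by default (df = n_a + n_b − 2); Welch's
    unequal-variance form behind the ``welch`` flag. Degenerate input
    with zero pooled variance and equal means yields p = 0.5 by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if direction != "a>b":
        raise ValidationError("direction must be 'a>b'; swap the arguments instead")
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")

    df = a.size + b.size - 2
    if not welch and a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            logger.info("zero pooled variance with equal means: p = 0.5 by convention")
            return DirectionalTestResult(0.0, df, 0.5, direction, "ns", a.size, b.size)
        t = np.inf if a.mean() > b.mean() else -np.inf
        p = 0.0 if t > 0 else 1.0
        return DirectionalTestResult(
            float(t), df, p, direction, _significance_code(p), a.size, b.size
        )

    res = stats.ttest_ind(a, b, equal_var=not welch, alternative="greater")
    df = float(res.df) if welch else df
    return DirectionalTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=df,
        p_one_tailed=float(res.pvalue),
        direction=direction,
        significance_code=_significance_code(float(res.pvalue)),
        n_a=a.size,
        n_b=b.size,
    )


def nn_spacing_analysis(
    table: pd.DataFrame,
    unit: str = "per-pore",
    welch: bool = False,
) -> dict:
    """Per-group spacing analysis: box summaries and PP-vs-TC contrasts.

    For each group label and kind set in the NN table, computes a
    ``BoxSummary`` per interface class and one-tailed tests of the
    hypothesis that PC–PC (PP) spacing exceeds TT and TP spacing — open
    pores are enriched at tannin-cell walls, so their spacing should be
    widest where no TC is involved.

    ``unit`` selects the observation entering the t test: each NN
    distance (``"per-pore"``, default) or each interface's mean distance
    (``"per-interface-mean"``).
    """
    if unit not in ("per-pore", "per-interface-mean"):
        raise ValidationError(f"unknown unit of observation {unit!r}")
    out: dict = {}
    for (group, kind_set), sub in table.groupby(["group", "kind_set"], sort=True):
        entry: dict = {"boxes": {}, "contrasts": {}}
        samples: dict[str, np.ndarray] = {}
        for cls, cls_sub in sub.groupby("iface_class", sort=True):
            if unit == "per-pore":
                vals = cls_sub["nn_distance_um"].to_numpy()
            else:
                vals = (
                    cls_sub.groupby(["cell_a", "cell_b"])["nn_distance_um"]
                    .mean()
                    .to_numpy()
                )
            samples[cls] = vals
            entry["boxes"][cls] = box_summary(vals)
        for other in ("TT", "TP"):
            name = f"PP>{other}"
            if "PP" not in samples or other not in samples:
                continue
            if samples["PP"].size < 2 or samples[other].size < 2:
                logger.info(
                    "group %s %s: contrast %s skipped (fewer than 2 distances)",
                    group, kind_set, name,
                )
                continue
            entry["contrasts"][name] = compare_groups(
                samples["PP"], samples[other], direction="a>b", welch=welch
            )
        out[(group, kind_set)] = entry
    if not out:
        logger.warning("empty NN table: nothing to analyze")
    return out


def analysis_to_frame(results: dict) -> pd.DataFrame:
    """Flatten ``nn_spacing_analysis`` output to a tidy contrast table."""
    rows = []
    for (group, kind_set), entry in results.items():
        for name, r in entry["contrasts"].items():
            rows.append(
                {
                    "group": group,
                    "kind_set": kind_set,
                    "contrast": name,
                    "t": r.t_statistic,
                    "df": r.degrees_of_freedom,
                    "p_one_tailed": r.p_one_tailed,
                    "code": r.significance_code,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["group", "kind_set", "contrast", "t", "df", "p_one_tailed", "code", "n_a", "n_b"],
    )
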