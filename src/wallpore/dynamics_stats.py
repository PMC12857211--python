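"""Multi-group comparisons for time-course measurements.

Implements the reporting style standard in horticultural time courses:
one-way ANOVA followed by Tukey's honestly-significant-difference test
over all group pairs (Tukey–Kramer for unbalanced designs), summarized
as a compact letter display in which two groups share a letter iff they
are not significantly different at level α. Groups are typically
cultivar × sampling-date cells; the caller names the grouping factor.

Also provides the correlation utility used to relate tannin-cell number
to soluble proanthocyanidin content.
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from wallpore.volume_io import ValidationError

__all__ = ["TukeyResult", "tukey_hsd", "compact_letter_display", "association"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class TukeyResult:
    """All-pairs Tukey HSD outcome.

    ``pairwise`` has one row per unordered group pair (group_i, group_j,
    mean_diff, q, p_adjusted); ``letters`` maps each group to its letter
    string; ``balanced`` is False when the Tukey–Kramer correction for
    unequal group sizes was applied.
    """

    pairwise: pd.DataFrame
    letters: dict[str, str]
    alpha: float
    ms_error: float
    df_error: int
    balanced: bool


def _anova_mse(groups: dict[str, np.ndarray]) -> tuple[float, int]:
    """Within-group mean square and its degrees of freedom."""
    sse = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df = sum(v.size - 1 for v in groups.values())
    return float(sse / df) if df > 0 else 0.0, df


def tukey_hsd(table: pd.DataFrame, alpha: float = 0.05) -> TukeyResult:
    """Tukey's HSD over a long-format measurement table.

    Parameters
    ----------
    table
        Measurement table with ``group`` and ``value`` columns.
    alpha
        Family-wise significance level in (0, 1).

    Notes
    -----
    The studentized-range statistic for pair (i, j) is
    ``q = |x̄_i − x̄_j| / sqrt(MSE/2 · (1/n_i + 1/n_j))`` with the ANOVA
    within-group mean square MSE; the harmonic-mean form reduces to the
    balanced formula when all n are equal. Groups with a single
    replicate are excluded with a warning. Letters are assigned as a
    minimal clique cover of the sharing graph with groups ordered by
    descending mean, so reports are deterministic.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    groups: dict[str, np.ndarray] = {}
    for g, sub in table.groupby("group", sort=True):
        v = sub["value"].to_numpy(dtype=float)
        if v.size < 2:
            logger.warning("group %r has a single replicate; excluded from HSD", g)
            continue
        groups[str(g)] = v
    if len(groups) < 2:
        raise ValidationError("Tukey HSD needs >= 2 groups with >= 2 replicates each")

    mse, df_err = _anova_mse(groups)
    names = sorted(groups)
    sizes = {g: groups[g].size for g in names}
    means = {g: float(groups[g].mean()) for g in names}
    balanced = len(set(sizes.values())) == 1
    k = len(names)

    rows = []
    for gi, gj in combinations(names, 2):
        diff = means[gi] - means[gj]
        se = np.sqrt(mse / 2.0 * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        if se == 0.0:
            q = 0.0 if diff == 0 else np.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_err))
        rows.append(
            {"group_i": gi, "group_j": gj, "mean_diff": diff, "q": float(q), "p_adjusted": p}
        )
    pairwise = pd.DataFrame(rows)

    distinct = {
        frozenset((r["group_i"], r["group_j"]))
        for r in rows
        if r["p_adjusted"] < alpha
    }
    letters = compact_letter_display(names, means, distinct)
    if not balanced:
        logger.info("unbalanced design: Tukey-Kramer (harmonic-mean) correction applied")
    return TukeyResult(
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
        ms_error=mse,
        df_error=df_err,
        balanced=balanced,
    )


def compact_letter_display(
    names: list[str],
    means: dict[str, float],
    distinct: set[frozenset],
) -> dict[str, str]:
    """Minimal compact letter display.

    Two groups share a letter iff their pair is *not* in ``distinct``.
    Letter columns are cliques of the sharing graph; the display is the
    smallest set of maximal cliques covering every group and every
    sharing pair (exact search; greedy set-cover fallback when the
    sharing graph has very many maximal cliques). Letters are issued in
    descending-mean order, so reports are deterministic.
    """
    import networkx as nx

    order = sorted(names, key=lambda g: (-means[g], g))
    share = nx.Graph()
    share.add_nodes_from(names)
    for gi, gj in combinations(sorted(names), 2):
        if frozenset((gi, gj)) not in distinct:
            share.add_edge(gi, gj)
    cliques = [frozenset(c) for c in nx.find_cliques(share)]
    cliques.sort(key=lambda c: (len(c), sorted(c)))  # deterministic

    need_pairs = {frozenset(e) for e in share.edges}
    need_nodes = set(names)

    def covers(cols) -> bool:
        nodes = set().union(*cols) if cols else set()
        if nodes != need_nodes:
            return False
        return all(any(p <= c for c in cols) for p in need_pairs)

    chosen = None
    if len(cliques) <= 18:
        for r in range(1, len(cliques) + 1):
            for cols in combinations(cliques, r):
                if covers(cols):
                    chosen = list(cols)
                    break
            if chosen is not None:
                break
    if chosen is None:  # greedy fallback: cover remaining pairs and nodes
        remaining_pairs = set(need_pairs)
        remaining_nodes = set(need_nodes)
        chosen = []
        while remaining_pairs or remaining_nodes:
            best = max(
                cliques,
                key=lambda c: (
                    len([p for p in remaining_pairs if p <= c])
                    + len(c & remaining_nodes),
                    sorted(c),
                ),
            )
            chosen.append(best)
            remaining_pairs -= {p for p in remaining_pairs if p <= best}
            remaining_nodes -= best

    # deterministic letter order: columns sorted by their best-ranked member
    rank = {g: i for i, g in enumerate(order)}
    chosen.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for letter, col in zip(alphabet, chosen):
        for g in order:
            if g in col:
                out[g] += letter
    return out


def association(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation between two measurement vectors.

    Returns ``(coefficient, two-tailed p)``; ``method`` is ``"pearson"``
    (default) or ``"spearman"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("association needs equal-length vectors of >= 3 values")
    if x.var() == 0.0 or y.var() == 0.0:
        raise ValidationError("zero variance: correlation undefined")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)
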