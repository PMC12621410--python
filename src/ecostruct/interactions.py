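"""Permutation-test analysis of pairwise cell-cell interaction / avoidance.

Two cells interact when their centroids are within a 6 µm radius.  For an
ordered phenotype pair (A, B) the statistic is the mean number of B-type
neighbours per A-type cell in the ROI.  Cell positions (and hence the
adjacency graph) stay fixed while phenotype labels are shuffled within the
ROI; one-sided permutation p-values with the add-one correction
``p = (1 + #{perm >= obs}) / (1 + n_perm)`` test for interaction (observed
high) and avoidance (observed low).  A pair is called at ``alpha`` (default
0.01).

Group contrasts compare the per-ROI statistic between two ROI groups with
Welch t-tests and report log2 fold changes with a small pseudo-count; only
pairs with p < 0.05 carry the ``shown`` flag, and the top-differential
ranking among shown pairs orders them by |log2 fold change|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import ttest_ind

from .data_model import CellTable
from .errors import ParameterError


def neighbor_graph(cells: CellTable, radius_um: float = 6.0) -> dict:
    """Per-ROI directed edge arrays ``(ei, ej)`` of the <= radius adjacency.

    Every undirected edge between distinct cells appears in both directions;
    there are no self-edges.  Indices are positional within the ROI subset
    (row order of the cell table restricted to the ROI).
    """
    if radius_um < 0:
        raise ParameterError("radius_um must be >= 0")
    graphs = {}
    for roi, idx in cells.by_roi():
        pts = cells.df.iloc[idx][["x", "y"]].to_numpy(float)
        tree = cKDTree(pts)
        pairs = tree.query_pairs(radius_um, output_type="ndarray")
        if len(pairs):
            ei = np.concatenate([pairs[:, 0], pairs[:, 1]])
            ej = np.concatenate([pairs[:, 1], pairs[:, 0]])
        else:
            ei = ej = np.empty(0, dtype=int)
        graphs[roi] = (ei, ej)
    return graphs


@dataclass
class InteractionResults:
    """Tidy per-ROI ordered-pair permutation results."""

    table: pd.DataFrame  # roi_id, from/to phenotype, observed_stat, p values, call
    undefined: pd.DataFrame  # ordered pairs skipped because a type is absent
    radius_um: float
    n_perm: int
    alpha: float


def permutation_test(
    cells: CellTable,
    radius_um: float = 6.0,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    phenotype_key: str = "phenotype",
) -> InteractionResults:
    """Permutation interaction/avoidance tests for every ordered phenotype
    pair present in each ROI.

    Pairs whose from- or to-type is absent from an ROI (but present in the
    cohort) are listed as undefined for that ROI rather than reported as 0.
    """
    if phenotype_key not in cells.df.columns:
        raise ParameterError(f"missing phenotype column {phenotype_key!r}")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    phen = cells.df[phenotype_key].astype(str).to_numpy()
    universe = sorted(pd.unique(phen))
    code = {p: i for i, p in enumerate(universe)}
    lab_all = np.array([code[p] for p in phen])
    T = len(universe)
    graphs = neighbor_graph(cells, radius_um)

    rows, undef = [], []
    for roi, idx in cells.by_roi():
        lab = lab_all[idx]
        present = np.unique(lab)
        n_by_type = np.bincount(lab, minlength=T).astype(float)
        ei, ej = graphs[roi]
        obs = np.bincount(lab[ei] * T + lab[ej], minlength=T * T).reshape(T, T) if len(ei) else np.zeros((T, T))
        ge = np.zeros((T, T), dtype=np.int64)
        le = np.zeros((T, T), dtype=np.int64)
        for _ in range(n_perm):
            perm = rng.permutation(len(lab))
            pl = lab[perm]
            if len(ei):
                cnt = np.bincount(pl[ei] * T + pl[ej], minlength=T * T).reshape(T, T)
            else:
                cnt = np.zeros((T, T), dtype=np.int64)
            ge += cnt >= obs
            le += cnt <= obs
        present_set = set(present.tolist())
        for a in range(T):
            for b in range(T):
                if a not in present_set or b not in present_set:
                    undef.append(
                        {"roi_id": roi, "from_phenotype": universe[a],
                         "to_phenotype": universe[b]}
                    )
                    continue
                p_int = (1 + ge[a, b]) / (1 + n_perm)
                p_avoid = (1 + le[a, b]) / (1 + n_perm)
                call = "ns"
                if p_int < alpha:
                    call = "interaction"
                elif p_avoid < alpha:
                    call = "avoidance"
                rows.append(
                    {
                        "roi_id": roi,
                        "from_phenotype": universe[a],
                        "to_phenotype": universe[b],
                        "observed_stat": obs[a, b] / n_by_type[a],
                        "p_interaction": p_int,
                        "p_avoidance": p_avoid,
                        "call": call,
                    }
                )
    table = pd.DataFrame(rows)
    if len(table):
        table["n_perm"] = n_perm
        table["radius_um"] = radius_um
    return InteractionResults(
        table=table,
        undefined=pd.DataFrame(undef, columns=["roi_id", "from_phenotype", "to_phenotype"]),
        radius_um=radius_um,
        n_perm=n_perm,
        alpha=alpha,
    )


def compare_groups(
    results: pd.DataFrame | InteractionResults,
    grouping: dict | pd.Series,
    group_a,
    group_b,
    eps: float = 0.01,
    alpha: float = 0.05,
    min_rois: int = 2,
) -> pd.DataFrame:
    """Welch t-test contrast of per-ROI interaction statistics between two
    ROI groups, per ordered pair.

    Returns one row per pair with group means, ``log2fc`` =
    log2((mean_a + eps) / (mean_b + eps)), the t-test p-value, the ``shown``
    flag (p < alpha) and ``rank`` by |log2fc| among shown pairs.
    """
    table = results.table if isinstance(results, InteractionResults) else results
    grouping = pd.Series(grouping)
    df = table.copy()
    df["group"] = df["roi_id"].map(grouping)
    out = []
    skipped = []
    for (fa, fb), sub in df.groupby(["from_phenotype", "to_phenotype"], sort=False):
        a = sub.loc[sub["group"] == group_a, "observed_stat"].to_numpy(float)
        b = sub.loc[sub["group"] == group_b, "observed_stat"].to_numpy(float)
        if len(a) < min_rois or len(b) < min_rois:
            skipped.append(f"{fa}->{fb}")
            continue
        log2fc = float(np.log2((a.mean() + eps) / (b.mean() + eps)))
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(ttest_ind(a, b, equal_var=False).pvalue)
        out.append(
            {
                "from_phenotype": fa,
                "to_phenotype": fb,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "log2fc": log2fc,
                "p": p,
                "shown": p < alpha,
            }
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} pairs excluded (fewer than {min_rois} ROIs in a group): "
            + ", ".join(skipped[:5])
            + ("..." if len(skipped) > 5 else ""),
            stacklevel=2,
        )
    comp = pd.DataFrame(out)
    if len(comp):
        shown = comp[comp["shown"]].copy()
        shown = shown.reindex(shown["log2fc"].abs().sort_values(ascending=False).index)
        comp["rank"] = np.nan
        comp.loc[shown.index, "rank"] = np.arange(1, len(shown) + 1)
    return comp
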