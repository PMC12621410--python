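"""Cellular-neighbourhood (CN) discovery from per-cell windows.

Each cell's *window* is the multiset of phenotypes around it - either its k
nearest neighbours (default k = 20, the headline configuration) or all
cells within a fixed radius.  Windows never cross ROI boundaries and by
default include the centre cell itself, which keeps isolated cells' rows
one-hot.  Window frequency rows are clustered with mini-batch k-means
(k = 10 by default, batch size 1024, seed 0) into recurring neighbourhood
archetypes; per-core prevalence is normalised to 100 %, z-scored across
cores, and a CN x phenotype enrichment matrix (column z-scores of per-CN
mean window frequencies) summarises what each neighbourhood is made of.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu
from sklearn.cluster import MiniBatchKMeans
from statsmodels.stats.multitest import multipletests

from .data_model import CellTable
from .errors import ParameterError, ValidationError


@dataclass
class WindowMatrix:
    """Per-cell phenotype counts/frequencies of each cell's spatial window."""

    counts: np.ndarray  # cells x phenotypes, non-negative integers
    phenotypes: list[str]
    window_mode: str  # "knn" or "radius"
    param: float
    include_center: bool

    @property
    def freqs(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.counts / totals
        return np.nan_to_num(f, nan=0.0)


def _knn_indices(pts: np.ndarray, order: np.ndarray, k: int) -> list[np.ndarray]:
    """k nearest neighbours per point, excluding self; exact ties at the
    k-th distance broken by ascending cell order (``order``)."""
    n = len(pts)
    k_eff = min(k, n - 1)
    tree = cKDTree(pts)
    pad = min(n, k_eff + 6)  # headroom so boundary ties can be re-sorted
    dist, idx = tree.query(pts, k=pad)
    out = []
    for i in range(n):
        d, j = dist[i], idx[i]
        keep = j != i
        d, j = d[keep], j[keep]
        sel = np.lexsort((order[j], d))[:k_eff]
        out.append(j[sel])
    return out


def build_windows(
    cells: CellTable,
    mode: str = "knn",
    param: float = 20,
    include_center: bool = True,
    phenotype_key: str = "phenotype",
) -> WindowMatrix:
    """Count each cell's window phenotypes, per ROI."""
    if mode not in ("knn", "radius"):
        raise ParameterError(f"unknown window mode {mode!r}")
    if param <= 0:
        raise ParameterError("window parameter must be positive")
    if phenotype_key not in cells.df.columns:
        raise ValidationError(f"missing phenotype column {phenotype_key!r}")
    phen = cells.df[phenotype_key].astype(str).to_numpy()
    phenotypes = sorted(pd.unique(phen))
    code = {p: i for i, p in enumerate(phenotypes)}
    lab = np.array([code[p] for p in phen])
    counts = np.zeros((len(cells), len(phenotypes)), dtype=np.int64)
    for _, idx in cells.by_roi():
        pts = cells.df.iloc[idx][["x", "y"]].to_numpy(float)
        order = cells.df.iloc[idx]["cell_id"].to_numpy()
        order = np.argsort(np.argsort(order, kind="stable"), kind="stable")
        local_lab = lab[idx]
        if mode == "knn":
            neigh = _knn_indices(pts, order, int(param))
        else:
            tree = cKDTree(pts)
            balls = tree.query_ball_point(pts, r=float(param))
            neigh = [np.array([j for j in b if j != i], dtype=int) for i, b in enumerate(balls)]
        for i, nb in enumerate(neigh):
            row = np.bincount(local_lab[nb], minlength=len(phenotypes))
            if include_center:
                row[local_lab[i]] += 1
            counts[idx[i]] = row
    return WindowMatrix(counts, phenotypes, mode, float(param), include_center)


def cluster_windows(
    win: WindowMatrix, k: int = 10, batch_size: int = 1024, seed: int = 0
) -> np.ndarray:
    """Mini-batch k-means on window frequency rows; deterministic given
    (data, k, batch_size, seed).  CN labels are 1-based (CN1..CNk)."""
    X = win.freqs
    distinct = np.unique(X, axis=0)
    if len(distinct) < k:
        raise ParameterError(
            f"only {len(distinct)} distinct window rows; choose k <= that (got k={k})"
        )
    km = MiniBatchKMeans(
        n_clusters=k,
        batch_size=batch_size,
        random_state=seed,
        n_init=3,
        max_iter=100,
    )
    return km.fit_predict(X) + 1


@dataclass
class CNResult:
    """Prevalence, z-scores and enrichment of discovered neighbourhoods."""

    labels: np.ndarray  # per-cell CN id (1-based)
    prevalence: pd.DataFrame  # core x CN, percentages summing to 100
    prevalence_z: pd.DataFrame  # z-scored across cores, per CN
    enrichment: pd.DataFrame  # CN x phenotype column z-scores
    group_tests: pd.DataFrame | None = None


def cn_prevalence_and_enrichment(
    labels: np.ndarray,
    win: WindowMatrix,
    cores: np.ndarray,
    grouping: dict | pd.Series | None = None,
    alpha: float = 0.05,
) -> CNResult:
    """Per-core CN prevalence (sums to 100 %), cross-core z-scores, and the
    CN x phenotype enrichment matrix; optional group comparisons of
    prevalence via rank-sum tests (BH-adjusted per CN family)."""
    labels = np.asarray(labels)
    cores = np.asarray(cores)
    cn_ids = np.unique(labels)
    core_ids = pd.unique(cores)
    rows = []
    for core in core_ids:
        mask = cores == core
        if mask.sum() == 0:
            warnings.warn(f"core {core!r} has no cells; omitted", stacklevel=2)
            continue
        counts = pd.Series(labels[mask]).value_counts()
        prev = np.array([counts.get(c, 0) for c in cn_ids], float)
        prev = prev / prev.sum() * 100.0
        # exact normalisation: fold the float residual into the largest entry
        prev[prev.argmax()] += 100.0 - prev.sum()
        rows.append(pd.Series(prev, index=[f"CN{c}" for c in cn_ids], name=core))
    prevalence = pd.DataFrame(rows)
    sd = prevalence.std(axis=0, ddof=1)
    mean = prevalence.mean(axis=0)
    z = (prevalence - mean).div(sd.where(sd > 0, 1.0), axis=1)
    z.loc[:, sd == 0] = 0.0

    mean_freqs = pd.DataFrame(
        [win.freqs[labels == c].mean(axis=0) for c in cn_ids],
        index=[f"CN{c}" for c in cn_ids],
        columns=win.phenotypes,
    )
    col_sd = mean_freqs.std(axis=0, ddof=1)
    enrich = (mean_freqs - mean_freqs.mean(axis=0)).div(col_sd.where(col_sd > 0, 1.0), axis=1)
    enrich.loc[:, col_sd == 0] = 0.0

    group_tests = None
    if grouping is not None:
        grouping = pd.Series(grouping)
        groups = prevalence.index.map(grouping)
        tests = []
        for cn in prevalence.columns:
            fam = []
            names = pd.unique(groups.dropna())
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a = prevalence.loc[groups == names[i], cn].to_numpy()
                    b = prevalence.loc[groups == names[j], cn].to_numpy()
                    if len(a) < 2 or len(b) < 2:
                        continue
                    if np.ptp(np.concatenate([a, b])) == 0:
                        p = 1.0
                    else:
                        p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
                    fam.append(
                        {
                            "cn": cn,
                            "group_a": names[i],
                            "group_b": names[j],
                            "mean_a": a.mean(),
                            "mean_b": b.mean(),
                            "p": p,
                        }
                    )
            if fam:
                adj = multipletests([r["p"] for r in fam], method="fdr_bh")[1]
                for r, q in zip(fam, adj):
                    r["p_adj"] = q
                    r["significant"] = q < alpha
                tests.extend(fam)
        group_tests = pd.DataFrame(tests)
    return CNResult(labels, prevalence, z, enrich, group_tests)
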