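"""Tissue-region detection as marker-positive cell patches.

Three region classes are detected from positivity for a defining marker or
lineage: epithelial (pan-cytokeratin), fibrotic (collagen-1) and immune
(CD45).  A patch is a connected component of positive cells under a
single-linkage spatial graph (edge whenever two positive cells are within
``max_dist_um``), kept only if it has at least ``min_cells`` members.
Because single-linkage components are maximal, any two surviving patches of
the same class are already more than ``max_dist_um`` apart - the merge of
adjacent same-class regions is implicit in the construction.

Patches are then dilated by a margin (default 20 µm, about two cell
diameters): every cell within the margin of any member cell is captured,
and each cell is assigned the region class of the expansion containing it,
with a configurable priority order resolving overlaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .data_model import REGION_CLASSES, CellTable
from .errors import ParameterError


@dataclass
class Patch:
    """One connected marker-positive region within an ROI."""

    patch_id: str
    roi_id: str
    region_class: str
    member_index: np.ndarray  # positional indices into the cell table
    member_cells: set = field(default_factory=set)  # (roi_id, cell_id) pairs
    expanded_index: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.member_index)


def positivity_from_labels(cells: CellTable, phenotypes: list[str],
                           phenotype_key: str = "phenotype") -> np.ndarray:
    """Positivity mask from annotated lineage labels (deterministic gate)."""
    return cells.df[phenotype_key].isin(phenotypes).to_numpy()


def positivity_from_marker(cells: CellTable, marker: str, quantile: float = 0.75) -> np.ndarray:
    """Positivity mask from a marker gate at a cohort-wide quantile."""
    x = cells.df[marker].to_numpy(float)
    return x > np.quantile(x, quantile)


def detect_patches(
    cells: CellTable,
    positivity: np.ndarray,
    region_class: str,
    min_cells: int = 20,
    max_dist_um: float = 20.0,
) -> list[Patch]:
    """Connected components of positive cells under <= ``max_dist_um``
    single linkage, per ROI; components below ``min_cells`` are discarded."""
    if min_cells < 1:
        raise ParameterError("min_cells must be >= 1")
    if max_dist_um < 0:
        raise ParameterError("max_dist_um must be >= 0")
    positivity = np.asarray(positivity, bool)
    if len(positivity) != len(cells):
        raise ParameterError("positivity mask must align with the cell table")
    patches: list[Patch] = []
    counter = 0
    for roi, idx in cells.by_roi():
        pos_idx = idx[positivity[idx]]
        if len(pos_idx) == 0:
            continue
        pts = cells.df.iloc[pos_idx][["x", "y"]].to_numpy(float)
        tree = cKDTree(pts)
        pairs = tree.query_pairs(max_dist_um, output_type="ndarray")
        n = len(pos_idx)
        if len(pairs):
            adj = coo_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
            )
        else:
            adj = coo_matrix((n, n))
        n_comp, comp = connected_components(adj, directed=False)
        for c in range(n_comp):
            members = pos_idx[comp == c]
            if len(members) < min_cells:
                continue
            counter += 1
            sub = cells.df.iloc[members]
            patches.append(
                Patch(
                    patch_id=f"{region_class}_{counter:04d}",
                    roi_id=roi,
                    region_class=region_class,
                    member_index=members,
                    member_cells=set(zip(sub["roi_id"], sub["cell_id"])),
                )
            )
    return patches


def expand_and_assign(
    patches: list[Patch],
    cells: CellTable,
    margin_um: float = 20.0,
    priority: tuple[str, ...] = ("epithelial", "immune", "fibrotic"),
) -> CellTable:
    """Dilate patches by ``margin_um`` and assign every cell a region.

    A cell inside several classes' expansions gets the highest-priority
    class and an ``region_overlap`` flag; cells outside every expansion get
    ``"none"``.  Fills each patch's ``expanded_index``.
    """
    unknown = set(priority) - set(REGION_CLASSES)
    if unknown:
        raise ParameterError(f"unknown region classes in priority: {sorted(unknown)}")
    covered = {cls: np.zeros(len(cells), bool) for cls in priority}
    roi_indices = dict(cells.by_roi())
    for patch in patches:
        if patch.region_class not in covered:
            raise ParameterError(
                f"patch class {patch.region_class!r} missing from priority order"
            )
        idx = roi_indices[patch.roi_id]
        pts = cells.df.iloc[idx][["x", "y"]].to_numpy(float)
        members = cells.df.iloc[patch.member_index][["x", "y"]].to_numpy(float)
        tree = cKDTree(members)
        dist, _ = tree.query(pts, k=1)
        inside = idx[dist <= margin_um]
        patch.expanded_index = inside
        covered[patch.region_class][inside] = True
    region = np.full(len(cells), "none", dtype=object)
    hits = np.zeros(len(cells), int)
    for cls in reversed(priority):  # apply highest priority last so it wins
        region[covered[cls]] = cls
        hits += covered[cls]
    overlap = hits > 1
    return cells.with_columns(region=region, region_overlap=overlap)


def region_composition(
    cells: CellTable,
    group_key: str,
    phenotype_key: str = "phenotype",
    region_key: str = "region",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype frequencies per (region, group) and pairwise group tests.

    Frequencies are computed per (region, ROI) so they sum to one over
    phenotypes; groups are compared per region and phenotype with two-sided
    rank-sum tests on the per-ROI frequencies, Benjamini-Hochberg adjusted
    within each (region, phenotype) family of pairwise comparisons.
    """
    df = cells.df
    for col in (group_key, phenotype_key, region_key):
        if col not in df.columns:
            raise ParameterError(f"missing column {col!r}")
    # per-(region, ROI) frequency vectors over all phenotypes (absent -> 0)
    counts = (
        df.groupby([region_key, "roi_id", group_key], sort=False, observed=True)[phenotype_key]
        .value_counts()
        .unstack(fill_value=0)
    )
    freqs = counts.div(counts.sum(axis=1), axis=0)
    freqs.columns.name = None
    long = freqs.reset_index().melt(
        id_vars=[region_key, "roi_id", group_key], var_name=phenotype_key, value_name="freq"
    )
    tests = []
    for (region, phen), sub in long.groupby([region_key, phenotype_key], sort=False):
        wide = sub.pivot_table(index="roi_id", columns=group_key, values="freq",
                               aggfunc="first", observed=True)
        groups = list(wide.columns)
        fam = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = wide[groups[i]].dropna().to_numpy()
                b = wide[groups[j]].dropna().to_numpy()
                if len(a) == 0 or len(b) == 0:
                    warnings.warn(
                        f"region {region!r} phenotype {phen!r}: empty group, row omitted",
                        stacklevel=2,
                    )
                    continue
                if np.ptp(np.concatenate([a, b])) == 0:
                    p = 1.0  # all observations identical
                else:
                    p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
                fam.append(
                    {
                        "region": region,
                        "phenotype": phen,
                        "group_a": groups[i],
                        "group_b": groups[j],
                        "mean_a": a.mean(),
                        "mean_b": b.mean(),
                        "p": p,
                    }
                )
        if fam:
            pvals = [r["p"] for r in fam]
            adj = multipletests(pvals, method="fdr_bh")[1]
            for r, q in zip(fam, adj):
                r["p_adj"] = q
                r["significant"] = q < alpha
            tests.extend(fam)
    freq_table = (
        long.groupby([region_key, group_key, phenotype_key], sort=False, observed=True)["freq"]
        .mean()
        .rename("mean_freq")
        .reset_index()
    )
    return freq_table, pd.DataFrame(tests)
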