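"""Intensity transformation, batch alignment, phenotype clustering and
signature-based annotation.

Raw per-channel ion counts are heavy-tailed; the standard cytometry recipe
applied here is: clip extreme values at a high quantile, compress with the
inverse hyperbolic sine ``asinh(x / cofactor)`` (cofactor 5 by convention),
then min-max scale each channel to [0, 1] across the whole cohort.

Batch alignment is deliberately simple and fully reproducible: per channel,
every batch's mean is shifted onto the global mean.  This removes additive
batch offsets exactly while preserving within-batch rank order.

Phenotype discovery follows the two-stage scheme common in IMC studies:
build a k-nearest-neighbour graph on lineage markers, partition it with
modularity-maximising (Leiden) community detection, then optionally
re-cluster each major group on a refined marker set.  Because manual
heatmap-guided annotation is not reproducible, clusters are annotated
automatically by cosine similarity against an editable signature table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .data_model import CellTable
from .errors import ConfigError, ParameterError, ValidationError


def asinh_cofactor(values: np.ndarray, cofactor: float) -> np.ndarray:
    """``asinh(x / cofactor)`` - the pre-scaling compression step."""
    if cofactor <= 0:
        raise ParameterError("cofactor must be positive")
    return np.arcsinh(np.asarray(values, float) / cofactor)


def transform_intensities(
    cells: CellTable, cofactor: float = 5.0, clip_quantile: float = 0.999
) -> CellTable:
    """Clip, asinh-compress and min-max scale every panel channel.

    Quantiles, minima and maxima are computed across the whole cohort, so
    the transform is a single monotone map per channel (below the clip
    point) shared by all cells.
    """
    if cofactor <= 0:
        raise ParameterError("cofactor must be positive")
    if not 0.5 < clip_quantile <= 1.0:
        raise ParameterError("clip_quantile must be in (0.5, 1]")
    df = cells.df.copy()
    for m in cells.panel.markers:
        x = df[m].to_numpy(float)
        hi = np.quantile(x, clip_quantile)
        x = np.minimum(x, hi)
        x = asinh_cofactor(x, cofactor)
        lo, hi = x.min(), x.max()
        df[m] = (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)
    return CellTable(df, cells.panel, raw=False)


def correct_batches(cells: CellTable, batch_key: str = "patient_id") -> CellTable:
    """Equalise per-channel batch means (each batch mean -> global mean)."""
    if batch_key not in cells.df.columns:
        raise ParameterError(f"unknown batch column {batch_key!r}")
    df = cells.df.copy()
    sizes = df.groupby(batch_key, sort=False).size()
    singletons = list(sizes.index[sizes == 1])
    if singletons:
        warnings.warn(
            f"batches with a single cell (mean estimated from one point): {singletons}",
            stacklevel=2,
        )
    markers = cells.panel.markers
    global_means = df[markers].mean()
    batch_means = df.groupby(batch_key, sort=False)[markers].transform("mean")
    df[markers] = df[markers] - batch_means + global_means
    return CellTable(df, cells.panel, raw=False)


def cluster_phenotypes(
    cells: CellTable,
    markers: list[str] | None = None,
    k_neighbors: int = 30,
    resolution: float = 1.0,
    target_k: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a kNN graph of marker space.

    Returns integer cluster ids (0-based) per cell, deterministic given
    ``seed``.  If ``target_k`` is given, the resolution parameter is tuned
    by bisection on a log scale until the partition has ``target_k``
    communities (or the closest achievable count).
    """
    if markers is None:
        markers = cells.panel.lineage_markers
    X = cells.df[markers].to_numpy(float)
    n = len(X)
    if k_neighbors >= n:
        raise ParameterError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    if k_neighbors <= 0:
        raise ParameterError("k_neighbors must be positive")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    src = np.repeat(np.arange(n), k_neighbors)
    dst = idx[:, 1:].ravel()
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())), directed=False)
    g.simplify()

    def partition(res: float) -> np.ndarray:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res,
            seed=seed,
            n_iterations=2,
        )
        return np.asarray(part.membership)

    if target_k is None:
        return partition(resolution)

    lo, hi = 1e-3, 50.0
    best, best_gap = None, np.inf
    for _ in range(25):
        mid = np.sqrt(lo * hi)
        lab = partition(mid)
        k = lab.max() + 1
        gap = abs(k - target_k)
        if gap < best_gap:
            best, best_gap = lab, gap
        if k == target_k:
            return lab
        if k < target_k:
            lo = mid
        else:
            hi = mid
    return best


def recluster_subgroups(
    cells: CellTable,
    labels: np.ndarray,
    marker_map: dict,
    k_neighbors: int = 30,
    resolution: float = 1.0,
    target_k: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Second clustering stage: isolate each major group and re-cluster it
    on its refined marker set.  ``marker_map`` maps a major label to the
    marker list used for its re-clustering; groups not listed keep a single
    sub-cluster.  Returns string labels ``"<major>.<sub>"``.
    """
    out = np.array([f"{l}.0" for l in labels], dtype=object)
    for major, markers in marker_map.items():
        member = np.flatnonzero(labels == major)
        if len(member) <= k_neighbors + 1:
            continue
        sub = CellTable(cells.df.iloc[member].reset_index(drop=True), cells.panel, raw=cells.raw)
        sub_lab = cluster_phenotypes(
            sub, markers=markers, k_neighbors=k_neighbors, resolution=resolution,
            target_k=target_k, seed=seed,
        )
        out[member] = [f"{major}.{s}" for s in sub_lab]
    return out


@dataclass
class SignatureTable:
    """Expected relative lineage-marker weights per phenotype (rows =
    phenotype names, columns = markers, entries >= 0)."""

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(float)
        if (w < 0).any():
            raise ValidationError("signature weights must be non-negative")
        if (w.max(axis=1) <= 0).any():
            empty = list(self.weights.index[w.max(axis=1) <= 0])
            raise ValidationError(f"signatures without any positive weight: {empty}")
        if self.weights.index.duplicated().any():
            raise ValidationError("duplicate phenotype names in signature table")

    @classmethod
    def from_csv(cls, path) -> "SignatureTable":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.weights.to_csv(path)


def cluster_profiles(
    cells: CellTable, labels: np.ndarray, markers: list[str] | None = None
) -> pd.DataFrame:
    """Mean marker vector per cluster (cluster x marker)."""
    if markers is None:
        markers = cells.panel.lineage_markers
    df = cells.df[markers].copy()
    df["_cluster"] = labels
    return df.groupby("_cluster", sort=True).mean()


def annotate_clusters(
    profiles: pd.DataFrame,
    signatures: SignatureTable,
    similarity_floor: float = 0.2,
) -> pd.DataFrame:
    """Label each cluster with the maximally cosine-similar signature.

    Ties are broken towards the lexicographically first phenotype name and
    flagged; a best similarity below ``similarity_floor`` maps to
    ``"other"``.  Returns a frame indexed by cluster with columns
    ``phenotype``, ``similarity`` and ``tie``.
    """
    shared = [m for m in signatures.weights.columns if m in profiles.columns]
    if not shared:
        raise ConfigError("no marker overlap between cluster profiles and signatures")
    P = profiles[shared].to_numpy(float)
    S = signatures.weights[shared].to_numpy(float)
    names = np.array(sorted(signatures.weights.index))
    order = [list(signatures.weights.index).index(n) for n in names]
    S = S[order]
    pn = np.linalg.norm(P, axis=1, keepdims=True)
    sn = np.linalg.norm(S, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (P @ S.T) / (pn * sn.T)
    cos = np.nan_to_num(cos, nan=0.0)
    rows = []
    for i, cluster in enumerate(profiles.index):
        best = cos[i].max()
        winners = names[np.isclose(cos[i], best, rtol=0, atol=1e-12)]
        phen = winners[0] if best >= similarity_floor else "other"
        rows.append(
            {
                "cluster": cluster,
                "phenotype": phen,
                "similarity": float(best),
                "tie": len(winners) > 1,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def assign_phenotypes(
    cells: CellTable,
    signatures: SignatureTable,
    markers: list[str] | None = None,
    k_neighbors: int = 30,
    resolution: float = 1.0,
    target_k: int | None = None,
    seed: int = 0,
    similarity_floor: float = 0.2,
) -> CellTable:
    """Cluster on lineage markers and annotate; adds a ``phenotype`` column."""
    labels = cluster_phenotypes(
        cells,
        markers=markers,
        k_neighbors=k_neighbors,
        resolution=resolution,
        target_k=target_k,
        seed=seed,
    )
    profiles = cluster_profiles(cells, labels, markers=markers)
    mapping = annotate_clusters(profiles, signatures, similarity_floor=similarity_floor)
    phen = mapping["phenotype"].reindex(labels).to_numpy()
    return cells.with_columns(phenotype=phen, cluster=labels)
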