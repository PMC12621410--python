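"""Non-negative matrix factorisation of composition data into cellular
programs.

A non-negative matrix ``V`` (features x samples; by default cell-type
frequencies per ROI, optionally per-ROI mean marker intensities) is
factorised as ``V ~ W H`` with ``W >= 0`` (features x k program loadings)
and ``H >= 0`` (k x samples program activities), minimising the Frobenius
reconstruction error with Lee-Seung multiplicative updates.  The update
rule guarantees a non-increasing error sequence, which the fitter records
per iteration.  After convergence each column of ``W`` is normalised to sum
to one with the scale absorbed into ``H``, so loadings are comparable
across programs.

The number of programs is selected by consensus-clustering stability:
for each candidate rank the factorisation is restarted from random
initialisations, samples are co-clustered by their dominant program, and
the cophenetic correlation of the consensus matrix measures how stable the
sample partition is across restarts.  The chosen rank is the largest k in
the contiguous run of stable ranks (cophenetic >= 0.95) starting at the
smallest candidate; i.i.d.-noise inputs yield no stable rank and are
flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .data_model import CellTable
from .errors import ParameterError, ValidationError

_EPS = 1e-12


@dataclass
class CompositionMatrix:
    """Non-negative features x samples matrix with identifiers."""

    V: np.ndarray
    features: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, float)
        if self.V.ndim != 2:
            raise ValidationError("V must be a 2-D matrix")
        if not np.isfinite(self.V).all() or (self.V < 0).any():
            raise ValidationError("V entries must be finite and non-negative")
        if (self.V.sum(axis=0) == 0).any():
            dead = [s for s, c in zip(self.samples, self.V.sum(axis=0)) if c == 0]
            raise ValidationError(f"all-zero sample columns: {dead}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.V, index=self.features, columns=self.samples)


def build_composition(
    cells: CellTable,
    feature_mode: str = "cell_type_frequency",
    phenotype_key: str = "phenotype",
    markers: list[str] | None = None,
    min_row_mean: float = 0.0,
) -> CompositionMatrix:
    """Per-ROI composition matrix.

    ``cell_type_frequency``: V[i, j] = frequency of phenotype i in ROI j
    (columns sum to 1).  ``marker_mean``: per-ROI mean transformed marker
    intensity, with low-signal rows (mean below ``min_row_mean``) removed.
    """
    if feature_mode == "cell_type_frequency":
        if phenotype_key not in cells.df.columns:
            raise ValidationError(f"missing phenotype column {phenotype_key!r}")
        counts = (
            cells.df.groupby("roi_id", sort=False)[phenotype_key]
            .value_counts()
            .unstack(fill_value=0)
            .T
        )
        empty = [c for c in counts.columns if counts[c].sum() == 0]
        if empty:
            warnings.warn(f"empty ROIs dropped: {empty}", stacklevel=2)
            counts = counts.drop(columns=empty)
        freqs = counts / counts.sum(axis=0)
        return CompositionMatrix(
            freqs.to_numpy(float), list(freqs.index), list(freqs.columns)
        )
    if feature_mode == "marker_mean":
        markers = markers or cells.panel.protein_markers
        means = cells.df.groupby("roi_id", sort=False)[markers].mean().T
        keep = means.mean(axis=1) >= min_row_mean
        dropped = list(means.index[~keep])
        if dropped:
            warnings.warn(f"low-signal feature rows removed: {dropped}", stacklevel=2)
        means = means[keep]
        return CompositionMatrix(means.to_numpy(float), list(means.index), list(means.columns))
    raise ParameterError(f"unknown feature_mode {feature_mode!r}")


@dataclass
class FactorModel:
    """Result of one NMF fit (W column-normalised, scale in H)."""

    W: np.ndarray
    H: np.ndarray
    k: int
    reconstruction_error: float
    error_trace: np.ndarray
    iterations: int
    converged: bool
    features: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)


def _nndsvd(V: np.ndarray, k: int, variant: str = "nndsvda") -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialisation (the 'a' variant fills zeros
    with the matrix mean so multiplicative updates cannot get stuck)."""
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    m, n = V.shape
    W = np.zeros((m, k))
    H = np.zeros((k, n))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            if sigma > 0:
                W[:, j] = np.sqrt(S[j] * sigma) * up / n_up
                H[j, :] = np.sqrt(S[j] * sigma) * vp / n_vp
        else:
            sigma = n_un * n_vn
            W[:, j] = np.sqrt(S[j] * sigma) * un / n_un
            H[j, :] = np.sqrt(S[j] * sigma) * vn / n_vn
    if variant == "nndsvda":
        avg = V.mean()
        W[W == 0] = avg
        H[H == 0] = avg
    return W, H


def nmf_fit(
    V: CompositionMatrix | np.ndarray,
    k: int,
    init: str = "nndsvd",
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> FactorModel:
    """Lee-Seung multiplicative-update NMF with Frobenius objective.

    Stops when the relative change of the Frobenius error falls below
    ``tol`` or after ``max_iter`` iterations; deterministic given
    ``(init, seed)``.
    """
    if isinstance(V, CompositionMatrix):
        features, samples, A = V.features, V.samples, V.V
    else:
        A = np.asarray(V, float)
        features = [f"f{i}" for i in range(A.shape[0])]
        samples = [f"s{j}" for j in range(A.shape[1])]
    if A.size == 0 or A.max() == 0:
        raise ParameterError("V must be non-zero")
    if not 1 <= k < min(A.shape):
        raise ParameterError(f"k must satisfy 1 <= k < min(dim V) (got k={k}, V {A.shape})")
    rng = np.random.default_rng(seed)
    if init == "nndsvd":
        W, H = _nndsvd(A, k)
    elif init == "random":
        scale = np.sqrt(A.mean() / k)
        W = scale * rng.uniform(size=(A.shape[0], k))
        H = scale * rng.uniform(size=(k, A.shape[1]))
    else:
        raise ParameterError(f"unknown init {init!r}")

    errors = [float(np.linalg.norm(A - W @ H))]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ A) / (W.T @ W @ H + _EPS)
        W *= (A @ H.T) / (W @ (H @ H.T) + _EPS)
        err = float(np.linalg.norm(A - W @ H))
        errors.append(err)
        prev = errors[-2]
        if prev > 0 and abs(prev - err) / prev < tol:
            converged = True
            break
    # scale convention: W columns sum to 1, scale absorbed into H
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    return FactorModel(
        W=W,
        H=H,
        k=k,
        reconstruction_error=errors[-1],
        error_trace=np.array(errors),
        iterations=it,
        converged=converged,
        features=features,
        samples=samples,
    )


@dataclass
class RankSelection:
    chosen_k: int
    diagnostics: pd.DataFrame  # k, best_error, cophenetic
    stable: bool


def select_rank(
    V: CompositionMatrix | np.ndarray,
    k_range: range | list[int],
    n_restarts: int = 10,
    seed: int = 0,
    stability_threshold: float = 0.95,
    drop_tol: float = 0.002,
    max_iter: int = 500,
) -> RankSelection:
    """Choose the factorisation rank by cophenetic consensus stability.

    Candidate ranks are scanned upward; the chosen rank is the largest k
    whose cophenetic coefficient is still >= ``stability_threshold`` before
    the coefficient first falls by more than ``drop_tol`` - the point where
    extra programs stop partitioning samples consistently."""
    if n_restarts < 2:
        raise ParameterError("n_restarts must be >= 2 for a stability estimate")
    A = V.V if isinstance(V, CompositionMatrix) else np.asarray(V, float)
    n_samples = A.shape[1]
    ks = sorted(k_range)
    if any(k < 1 or k >= min(A.shape) for k in ks):
        raise ParameterError("k_range outside the valid rank range")
    ss = np.random.SeedSequence(seed)
    rows = []
    for k in ks:
        consensus = np.zeros((n_samples, n_samples))
        best_err = np.inf
        for child in ss.spawn(n_restarts):
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            model = nmf_fit(A, k, init="random", seed=sub_seed, max_iter=max_iter)
            best_err = min(best_err, model.reconstruction_error)
            dominant = model.H.argmax(axis=0)
            consensus += dominant[:, None] == dominant[None, :]
        consensus /= n_restarts
        # dispersion: 1 when every sample pair co-clusters always or never
        # across restarts; drops as soon as assignments become ambiguous
        dispersion = float(np.mean(4.0 * (consensus - 0.5) ** 2))
        if k == 1:
            coph = 1.0
        else:
            dist = squareform(1.0 - consensus, checks=False)
            if dist.max() == 0:
                coph = 1.0
            else:
                Z = linkage(dist, method="average")
                coph = float(cophenet(Z, dist)[0])
                if np.isnan(coph):
                    coph = 1.0
        rows.append(
            {"k": k, "best_error": best_err, "dispersion": dispersion, "cophenetic": coph}
        )
    diag = pd.DataFrame(rows)
    # walk candidate ranks upward while the consensus stays stable; stop at
    # the first drop of the stability statistic (ties towards smaller k)
    chosen = None
    prev = None
    for _, row in diag.iterrows():
        stab = row["dispersion"]
        if stab < stability_threshold:
            break
        if prev is not None and stab < prev - drop_tol:
            break
        chosen, prev = int(row["k"]), stab
    if chosen is not None:
        return RankSelection(chosen_k=chosen, diagnostics=diag, stable=True)
    warnings.warn("no stable rank found; returning the smallest candidate", stacklevel=2)
    return RankSelection(chosen_k=ks[0], diagnostics=diag, stable=False)


def program_activity_compare(
    model: FactorModel,
    grouping: dict | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise rank-sum comparison of per-sample program activity.

    Activities are H columns normalised to proportions per sample; p-values
    are BH-adjusted within each program's family of pairwise contrasts.
    """
    grouping = pd.Series(grouping)
    totals = model.H.sum(axis=0)
    totals[totals == 0] = 1.0
    act = model.H / totals  # k x samples, columns sum to 1
    groups = np.array([grouping.get(s) for s in model.samples])
    names = pd.unique(pd.Series(groups).dropna())
    rows = []
    for prog in range(model.k):
        fam = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a = act[prog, groups == names[i]]
                b = act[prog, groups == names[j]]
                if len(a) < 2 or len(b) < 2:
                    warnings.warn(
                        f"program {prog + 1}: group with <2 samples skipped", stacklevel=2
                    )
                    continue
                if np.ptp(np.concatenate([a, b])) == 0:
                    p = 1.0
                else:
                    p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
                fam.append(
                    {
                        "program": f"NMF{prog + 1}",
                        "group_a": names[i],
                        "group_b": names[j],
                        "mean_a": float(a.mean()),
                        "mean_b": float(b.mean()),
                        "effect": float(a.mean() - b.mean()),
                        "p": p,
                    }
                )
        if fam:
            adj = multipletests([r["p"] for r in fam], method="fdr_bh")[1]
            for r, q in zip(fam, adj):
                r["p_adj"] = q
                r["significant"] = q < alpha
            rows.extend(fam)
    return pd.DataFrame(rows)
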