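"""Per-ROI feature engineering, repeated random-forest importance analysis,
top-k models, and Kaplan-Meier survival comparison.

Three feature families are extracted per ROI: phenotype frequencies,
ordered-pair spatial interaction statistics (at the 6 µm radius), and mean
functional-marker expression within each phenotype.  A random-forest
classifier is fitted on repeated stratified 70/30 splits (by patient by
default, so ROIs of one patient never straddle the split); per repeat the
number of candidate variables per split is tuned on a small grid by
out-of-bag misclassification, feature importance is measured as mean
decrease accuracy (permutation importance on the validation split) and the
validation AUC is recorded (macro one-vs-rest for the four-class subtype
label).  Importances are averaged over repeats; the top-k features are then
re-evaluated with the same repeated-split protocol.

Survival uses the Kaplan-Meier product-limit estimator and the log-rank
test (via lifelines), with a median-split helper for feature-based
grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score

from .data_model import CellTable
from .errors import ParameterError, ValidationError
from .interactions import InteractionResults

FAMILIES = ("frequency", "interaction", "functional")


@dataclass
class FeatureTable:
    """Per-ROI feature matrix with family tags and patient mapping."""

    X: pd.DataFrame  # rows = ROIs
    families: pd.Series  # feature -> family tag ("frequency"/"interaction"/"functional")
    patients: pd.Series  # roi_id -> patient_id

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValidationError("feature table contains missing values")


def build_features(
    cells: CellTable,
    interactions: InteractionResults | pd.DataFrame,
    functional_markers: list[str] | None = None,
    phenotype_key: str = "phenotype",
) -> FeatureTable:
    """Assemble the three per-ROI feature families.

    Phenotypes absent from an ROI contribute frequency 0, zero interaction
    and marker features, and set that phenotype's missingness indicator
    (indicators are tagged with the family of the features they qualify,
    ``frequency``).
    """
    df = cells.df
    if phenotype_key not in df.columns:
        raise ValidationError(f"missing phenotype column {phenotype_key!r}")
    itab = interactions.table if isinstance(interactions, InteractionResults) else interactions
    functional_markers = functional_markers or cells.panel.functional_markers
    phenotypes = sorted(df[phenotype_key].astype(str).unique())
    rois = list(pd.unique(df["roi_id"]))
    missing_rois = set(rois) - set(itab["roi_id"].unique())
    if missing_rois:
        raise ParameterError(f"ROIs missing from interaction results: {sorted(missing_rois)}")

    freq = (
        df.groupby("roi_id", sort=False)[phenotype_key]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=phenotypes, fill_value=0.0)
        .reindex(rois)
    )
    freq.columns = [f"freq|{p}" for p in phenotypes]

    inter = itab.pivot_table(
        index="roi_id", columns=["from_phenotype", "to_phenotype"],
        values="observed_stat", aggfunc="first",
    )
    inter = inter.reindex(rois)
    full_cols = pd.MultiIndex.from_product([phenotypes, phenotypes])
    inter = inter.reindex(columns=full_cols)
    inter.columns = [f"int|{a}->{b}" for a, b in full_cols]
    inter = inter.fillna(0.0)

    fn = (
        df.groupby(["roi_id", phenotype_key], sort=False, observed=True)[functional_markers]
        .mean()
        .unstack(phenotype_key)
    )
    fn = fn.reindex(rois)
    fn_cols = pd.MultiIndex.from_product([functional_markers, phenotypes])
    fn = fn.reindex(columns=fn_cols)
    fn.columns = [f"fn|{p}|{m}" for m, p in fn_cols]
    fn = fn.fillna(0.0)

    present = (
        df.groupby("roi_id", sort=False)[phenotype_key]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=phenotypes, fill_value=0)
        .reindex(rois)
    )
    miss = (present == 0).astype(float)
    miss.columns = [f"miss|{p}" for p in phenotypes]

    X = pd.concat([freq, inter, fn, miss], axis=1)
    fams = {}
    for c in X.columns:
        if c.startswith("freq|") or c.startswith("miss|"):
            fams[c] = "frequency"
        elif c.startswith("int|"):
            fams[c] = "interaction"
        else:
            fams[c] = "functional"
    patients = df.groupby("roi_id", sort=False)["patient_id"].first().reindex(rois)
    return FeatureTable(X=X, families=pd.Series(fams), patients=patients)


@dataclass
class ImportanceTable:
    """Aggregated permutation importances and AUC over repeated splits."""

    importance: pd.DataFrame  # feature, mean_mda, sd_mda, rank
    aucs: np.ndarray  # per-repeat validation AUC
    n_repeats: int
    mean_auc: float
    pooled_auc: float  # AUC over all validation predictions pooled


def _split(rng, units: np.ndarray, unit_labels: np.ndarray, train_frac: float):
    """Stratified random split of units (patients or ROIs)."""
    train = []
    for cls in np.unique(unit_labels):
        members = units[unit_labels == cls]
        members = members[rng.permutation(len(members))]
        n_train = max(1, int(round(train_frac * len(members))))
        n_train = min(n_train, len(members) - 1) if len(members) > 1 else n_train
        train.extend(members[:n_train])
    train = set(train)
    return train


def _auc(y_true, proba, classes) -> float:
    if len(classes) == 2:
        return float(roc_auc_score((y_true == classes[1]).astype(int), proba[:, 1]))
    return float(
        roc_auc_score(y_true, proba, multi_class="ovr", average="macro", labels=list(classes))
    )


def repeated_rf(
    features: FeatureTable,
    labels: pd.Series,
    n_repeats: int = 1000,
    train_frac: float = 0.7,
    seed: int = 0,
    n_trees: int = 500,
    mtry_grid: list[int] | None = None,
    split_by: str = "patient",
    max_redraw_frac: float = 0.1,
) -> ImportanceTable:
    """Repeated stratified-split random-forest importance analysis.

    All randomness (splits, forests, importance permutations) derives from
    one master ``seed``.  A repeat whose training or validation split loses
    a class is re-drawn; more than ``max_redraw_frac`` re-draws aborts.
    """
    X = features.X
    y = labels.reindex(X.index)
    if y.isna().any():
        raise ParameterError("labels missing for some ROIs")
    y = y.astype(str)
    classes = np.array(sorted(y.unique()))
    if len(classes) < 2:
        raise ParameterError("need at least two classes")
    if split_by not in ("patient", "roi"):
        raise ParameterError("split_by must be 'patient' or 'roi'")
    p = X.shape[1]
    if mtry_grid is None:
        root = max(1, int(np.sqrt(p)))
        mtry_grid = sorted({max(1, root // 2), root, min(p, 2 * root)})
    rng = np.random.default_rng(seed)

    if split_by == "patient":
        units = features.patients.reindex(X.index)
        unit_ids = units.unique()
        unit_label = pd.Series(
            {u: y[units == u].iloc[0] for u in unit_ids}
        )  # patient label = label of its ROIs
    else:
        units = pd.Series(X.index, index=X.index)
        unit_ids = np.array(X.index)
        unit_label = y.copy()

    Xv = X.to_numpy(float)
    yv = y.to_numpy()
    mda_sum = np.zeros(p)
    mda_sq = np.zeros(p)
    aucs = np.empty(n_repeats)
    pooled_true, pooled_proba = [], []
    redraws = 0
    max_redraws = max(1, int(np.ceil(max_redraw_frac * n_repeats)))

    r = 0
    while r < n_repeats:
        train_units = _split(rng, np.asarray(unit_ids, object),
                             unit_label.loc[unit_ids].to_numpy(), train_frac)
        in_train = units.isin(train_units).to_numpy()
        y_tr, y_va = yv[in_train], yv[~in_train]
        if set(y_tr) != set(classes) or len(set(y_va)) < 2:
            redraws += 1
            if redraws > max_redraws:
                raise ValidationError(
                    "too many split re-draws: a class cannot be kept in both partitions"
                )
            continue
        X_tr, X_va = Xv[in_train], Xv[~in_train]
        best_model, best_oob = None, -np.inf
        for mtry in mtry_grid:
            model = RandomForestClassifier(
                n_estimators=n_trees,
                max_features=mtry,
                oob_score=True,
                bootstrap=True,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny forests: some OOB gaps
                model.fit(X_tr, y_tr)
            oob = getattr(model, "oob_score_", np.nan)
            if np.isnan(oob):
                oob = -np.inf
            if oob > best_oob:
                best_model, best_oob = model, oob
        base_acc = accuracy_score(y_va, best_model.predict(X_va))
        # mean decrease accuracy: one stacked predict over all p
        # single-feature permutations of the validation matrix
        n_va = len(y_va)
        stacked = np.tile(X_va, (p, 1))
        for j in range(p):
            block = slice(j * n_va, (j + 1) * n_va)
            stacked[block, j] = X_va[rng.permutation(n_va), j]
        preds = best_model.predict(stacked)
        for j in range(p):
            acc = accuracy_score(y_va, preds[j * n_va:(j + 1) * n_va])
            drop = base_acc - acc
            mda_sum[j] += drop
            mda_sq[j] += drop * drop
        proba = best_model.predict_proba(X_va)
        proba_full = np.zeros((len(y_va), len(classes)))
        for ci, cls in enumerate(classes):
            if cls in best_model.classes_:
                proba_full[:, ci] = proba[:, list(best_model.classes_).index(cls)]
        aucs[r] = _auc(y_va, proba_full, classes)
        pooled_true.append(y_va)
        pooled_proba.append(proba_full)
        r += 1

    mean_mda = mda_sum / n_repeats
    sd_mda = np.sqrt(np.maximum(mda_sq / n_repeats - mean_mda**2, 0.0))
    order = np.argsort(-mean_mda, kind="stable")
    rank = np.empty(p, int)
    rank[order] = np.arange(1, p + 1)
    imp = pd.DataFrame(
        {
            "feature": X.columns,
            "family": features.families.reindex(X.columns).to_numpy(),
            "mean_mda": mean_mda,
            "sd_mda": sd_mda,
            "rank": rank,
        }
    ).sort_values("rank").reset_index(drop=True)
    pooled = _auc(np.concatenate(pooled_true), np.vstack(pooled_proba), classes)
    return ImportanceTable(
        importance=imp,
        aucs=aucs,
        n_repeats=n_repeats,
        mean_auc=float(aucs.mean()),
        pooled_auc=float(pooled),
    )


@dataclass
class TopKResult:
    selected: list[str]
    mean_auc: float
    aucs: np.ndarray


def topk_model(
    features: FeatureTable,
    labels: pd.Series,
    importance: ImportanceTable,
    k: int = 5,
    n_repeats: int = 1000,
    seed: int = 0,
    **rf_kwargs,
) -> TopKResult:
    """Re-evaluate a model restricted to the top-k features by mean
    decrease accuracy, with the same repeated-split protocol."""
    ranked = importance.importance.sort_values("rank")["feature"].tolist()
    if k > len(ranked):
        warnings.warn(
            f"k={k} exceeds the {len(ranked)} available features; using all", stacklevel=2
        )
        k = len(ranked)
    chosen = set(ranked[:k])
    # keep the original column order so k >= p reproduces the full model
    selected = [c for c in features.X.columns if c in chosen]
    sub = FeatureTable(
        X=features.X[selected],
        families=features.families.reindex(selected),
        patients=features.patients,
    )
    res = repeated_rf(sub, labels, n_repeats=n_repeats, seed=seed, **rf_kwargs)
    return TopKResult(selected=selected, mean_auc=res.mean_auc, aucs=res.aucs)


@dataclass
class KMResult:
    curves: dict  # group -> DataFrame(time, survival)
    statistic: float
    p_value: float


def median_split(values: pd.Series) -> pd.Series:
    """Dichotomise a feature at its median ('high' vs 'low')."""
    med = values.median()
    return pd.Series(np.where(values > med, "high", "low"), index=values.index)


def km_logrank(records: pd.DataFrame, group_key: str = "group") -> KMResult:
    """Kaplan-Meier curves per group and the log-rank test.

    ``records`` needs ``time`` (PFS months), ``event`` (1 = progression)
    and a group column.  Two groups use the standard two-sample log-rank
    statistic; more use its multivariate generalisation.
    """
    for col in ("time", "event", group_key):
        if col not in records.columns:
            raise ParameterError(f"missing column {col!r}")
    if (records["time"] < 0).any():
        raise ValidationError("times must be non-negative")
    if not records["event"].isin([0, 1]).all():
        raise ValidationError("event must be 0/1")
    groups = list(pd.unique(records[group_key]))
    curves = {}
    for g in groups:
        sub = records[records[group_key] == g]
        if len(sub) and (sub["time"] == 0).all() and sub["event"].any():
            raise ValidationError(f"group {g!r} has all-zero event times")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
        )
    if len(groups) == 2:
        a = records[records[group_key] == groups[0]]
        b = records[records[group_key] == groups[1]]
        res = logrank_test(a["time"], b["time"], a["event"], b["event"])
        stat, p = float(res.test_statistic), float(res.p_value)
    else:
        res = multivariate_logrank_test(records["time"], records[group_key], records["event"])
        stat, p = float(res.test_statistic), float(res.p_value)
    if np.isnan(stat):
        stat, p = 0.0, 1.0  # degenerate: no events or identical groups
    return KMResult(curves=curves, statistic=stat, p_value=p)
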