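"""Synthetic tissue cohorts with known ground truth.

The generator emulates the statistical structure a spatial IMC study of a
four-subtype endometrial-carcinoma cohort assumes: 4 molecular subtypes x
10 patients x 2 ROIs (80 ROIs), on the order of 10^4 cells per ROI, a
41-plex panel, 10 major phenotypes, spatially clustered niches, planted
cell-cell attractions, subtype-specific composition and functional-marker
effects, per-patient batch shifts, and recurrence / progression-free
survival drawn from a logistic / exponential outcome model.

Niches are laid down as a Thomas-style cluster process: Poisson parent
points per niche, Gaussian offspring around each parent, phenotypes drawn
from the niche's composition vector.  Attractions are injected afterwards
by relocating a stated fraction of target-type cells to within a small
radius of randomly chosen source-type cells, so spatial structure is the
only thing that changes - marginal composition is preserved.

Everything is a deterministic function of ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .data_model import SUBTYPES, CellTable, CohortMetadata, MarkerPanel
from .errors import ConfigError, ParameterError

PHENOTYPES = (
    "T_cell",
    "B_cell",
    "NK_cell",
    "Myeloid",
    "Endothelial",
    "Epithelial",
    "Fibroblast",
    "Stromal",
    "CD90_pos",
    "other",
)

# mean log-intensity of each phenotype's defining lineage markers; every
# other channel sits at background.  Values are natural-log means of a
# log-normal intensity model.
_POSITIVE = 3.0
_BACKGROUND = 0.0

_SIGNATURE_MARKERS: dict[str, tuple[str, ...]] = {
    "T_cell": ("CD45", "CD3", "CD4", "CD8", "CD45RO"),
    "B_cell": ("CD45", "CD20", "CD38", "HLA-DR"),
    "NK_cell": ("CD45", "CD56", "CD57", "CD16", "GranzymeB"),
    "Myeloid": ("CD45", "CD68", "CD11c", "CD11b", "CD14", "S100A9", "CD163"),
    "Endothelial": ("CD31", "CD105"),
    "Epithelial": ("E-cadherin", "panCK"),
    "Fibroblast": ("Collagen1", "aSMA"),
    "Stromal": ("Vimentin", "CD127"),
    "CD90_pos": ("CD90", "CD105", "Vimentin"),
    "other": (),
}

# optional fine states within a major phenotype: (name, probability,
# {functional marker: extra log-mean}).  Ground truth keeps both labels.
_FINE_VARIANTS: dict[str, list[tuple[str, float, dict[str, float]]]] = {
    "T_cell": [
        ("Treg", 0.15, {"PD-1": 1.5}),
        ("proliferating_T", 0.15, {"Ki67": 2.0, "CXCR4": 1.5}),
    ],
    "Myeloid": [
        ("M1", 0.25, {"Ki67": 1.5, "CXCR4": 1.5, "TNFa": 1.5}),
        ("M2", 0.25, {"CXCR4": 1.0}),
    ],
    "Endothelial": [("proliferating_endothelial", 0.2, {"Ki67": 2.0})],
}


class NicheSpec(NamedTuple):
    """One niche of the Thomas cluster process."""

    niche_id: str
    composition: dict[str, float]  # phenotype -> probability, sums to 1
    parents_per_mm2: float
    offspring_mean: float
    offspring_sd_um: float


class AttractionSpec(NamedTuple):
    """Planted attraction: relocate ``excess_fraction`` of B cells to within
    ``radius_um`` of random A cells."""

    source: str  # phenotype A
    target: str  # phenotype B
    radius_um: float
    excess_fraction: float
    recurrence_linked: bool = False  # excess varies with patient outcome risk


def default_signatures(markers: Sequence[str] | None = None) -> pd.DataFrame:
    """Phenotype x marker matrix of mean log-intensities."""
    if markers is None:
        markers = MarkerPanel.default().markers
    sig = pd.DataFrame(_BACKGROUND, index=list(PHENOTYPES), columns=list(markers))
    for phen, pos in _SIGNATURE_MARKERS.items():
        for m in pos:
            if m in sig.columns:
                sig.loc[phen, m] = _POSITIVE
    for dna in ("DNA1", "DNA2"):
        if dna in sig.columns:
            sig[dna] = _POSITIVE  # every nucleated cell
    return sig


def signature_table(baseline: float = 0.1):
    """Reference :class:`~ecostruct.preprocess.SignatureTable` matching the
    generator's phenotypes.

    Defining lineage markers get weight 1, all other lineage markers the
    small ``baseline`` weight; the catch-all ``other`` row is uniform at the
    baseline, so featureless cluster profiles annotate as ``other``.
    """
    from .preprocess import SignatureTable

    lineage = MarkerPanel.default().lineage_markers
    w = pd.DataFrame(baseline, index=list(PHENOTYPES), columns=lineage)
    for phen, pos in _SIGNATURE_MARKERS.items():
        for m in pos:
            if m in w.columns:
                w.loc[phen, m] = 1.0
    return SignatureTable(w)


def default_niches() -> list[NicheSpec]:
    """Five niche archetypes: tumour nests, immune hubs, fibrotic tracts,
    vascular niches and mixed stroma."""
    return [
        NicheSpec(
            "epithelial_nest",
            {"Epithelial": 0.80, "Stromal": 0.10, "other": 0.10},
            6.0, 500.0, 20.0,
        ),
        NicheSpec(
            "immune_hub",
            {"T_cell": 0.40, "B_cell": 0.20, "NK_cell": 0.10, "Myeloid": 0.20, "other": 0.10},
            4.0, 500.0, 20.0,
        ),
        NicheSpec(
            "fibrotic_tract",
            {"Fibroblast": 0.65, "Stromal": 0.15, "CD90_pos": 0.10, "other": 0.10},
            4.0, 500.0, 20.0,
        ),
        NicheSpec(
            "vascular_niche",
            {"Endothelial": 0.50, "CD90_pos": 0.20, "Myeloid": 0.15, "Stromal": 0.15},
            3.0, 500.0, 20.0,
        ),
        NicheSpec(
            "mixed_stroma",
            {"Stromal": 0.50, "other": 0.30, "Epithelial": 0.10, "T_cell": 0.10},
            3.0, 500.0, 20.0,
        ),
    ]


def default_subtype_effects() -> dict[str, dict]:
    """Per-subtype multipliers on niche parent intensities and additive
    shifts on functional-marker log-means.

    The hypermutated / MSI-high subtypes carry stronger immune hubs, the
    copy-number-high subtype a stronger vascular niche, and the
    copy-number-low subtype more epithelial / fibrotic tissue - the
    composition contrasts the group tests are expected to detect.
    """
    return {
        "POLE": {"niche_weights": {"immune_hub": 2.0}, "functional_shift": {"CXCR4": 0.5}},
        "MSI-H": {"niche_weights": {"immune_hub": 1.6}, "functional_shift": {"PD-L1": 0.5}},
        "CNH": {"niche_weights": {"vascular_niche": 2.0}, "functional_shift": {"HIF1a": 0.5}},
        "CNL": {
            "niche_weights": {"epithelial_nest": 1.5, "fibrotic_tract": 1.5, "immune_hub": 0.5},
            "functional_shift": {},
        },
    }


def default_attractions() -> list[AttractionSpec]:
    """One constitutive vascular-myeloid attraction and one
    recurrence-linked attraction (endothelial-like towards macrophage-like
    cells), mirroring the kind of pairs spatial interaction tests flag."""
    return [
        AttractionSpec("Endothelial", "Myeloid", 5.0, 0.5, recurrence_linked=False),
        AttractionSpec("CD90_pos", "Myeloid", 5.0, 0.4, recurrence_linked=True),
    ]


@dataclass
class OutcomeModel:
    """Logistic recurrence model plus exponential PFS hazard.

    The linear predictor combines standardised planted patient-level
    features: the patient's frequency of ``freq_phenotype`` and the
    patient's realised excess of the recurrence-linked attraction.
    """

    intercept: float = 0.0
    beta_freq: float = 1.5
    freq_phenotype: str = "CD90_pos"
    beta_attraction: float = 1.5
    base_hazard: float = 0.02  # events per month at linear predictor 0
    hazard_scale: float = 0.8  # hazard multiplier exp(scale * lp)
    followup_months: float = 40.0


@dataclass
class SimConfig:
    """Full description of one synthetic cohort."""

    n_subtypes: int = 4
    patients_per_subtype: int = 10
    rois_per_patient: int = 2
    roi_size_um: tuple[float, float] = (1000.0, 1000.0)
    signatures: pd.DataFrame = field(default_factory=default_signatures)
    niches: list[NicheSpec] = field(default_factory=default_niches)
    attractions: list[AttractionSpec] = field(default_factory=default_attractions)
    subtype_effects: dict = field(default_factory=default_subtype_effects)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    fine_variants: dict = field(default_factory=lambda: dict(_FINE_VARIANTS))
    noise_sd: float = 0.35  # log-normal sigma of marker intensities
    batch_sd: float = 0.4  # sd of per-(patient, channel) additive raw shifts
    patient_niche_jitter_sd: float = 0.35  # log-normal sd of per-patient niche weights
    seed: int = 0

    def validate(self) -> None:
        if self.n_subtypes < 1 or self.n_subtypes > len(SUBTYPES):
            raise ConfigError(f"n_subtypes must be in 1..{len(SUBTYPES)}")
        if min(self.roi_size_um) <= 0:
            raise ConfigError("roi_size_um must be positive")
        for spec in self.niches:
            total = sum(spec.composition.values())
            if any(v < 0 for v in spec.composition.values()) or not math.isclose(
                total, 1.0, abs_tol=1e-9
            ):
                raise ConfigError(
                    f"niche {spec.niche_id!r} composition must be non-negative and sum to 1 "
                    f"(got {total})"
                )
            unknown = set(spec.composition) - set(self.signatures.index)
            if unknown:
                raise ConfigError(f"niche {spec.niche_id!r} uses unknown phenotypes {unknown}")
        for att in self.attractions:
            if not 0 <= att.excess_fraction <= 1:
                raise ConfigError("attraction excess_fraction must be in [0, 1]")
            if att.radius_um < 0:
                raise ConfigError("attraction radius_um must be >= 0")
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise ConfigError("noise_sd and batch_sd must be >= 0")


def small_config(seed: int = 0, cells_per_roi: float = 1500.0, **overrides) -> SimConfig:
    """A scaled-down cohort (same structure, fewer/smaller ROIs) for tests
    and examples.  ``cells_per_roi`` rescales offspring means jointly."""
    cfg = SimConfig(seed=seed)
    base_total = sum(
        n.parents_per_mm2 * n.offspring_mean for n in cfg.niches
    )  # expected cells per mm^2 ROI under defaults
    factor = cells_per_roi / base_total
    cfg.niches = [n._replace(offspring_mean=n.offspring_mean * factor) for n in cfg.niches]
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@dataclass
class GroundTruth:
    """Planted truth aligned 1:1 with the generated cell table."""

    cells: pd.DataFrame  # roi_id, cell_id, phenotype, fine_phenotype, niche
    roi_composition: pd.DataFrame  # roi_id x phenotype true sampling frequencies
    attractions: list[AttractionSpec]
    patient_truth: pd.DataFrame  # patient_id, linear predictor + planted features

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def _sample_roi(rng, cfg: SimConfig, niche_mult: dict[str, float]):
    """Thomas process for one ROI; returns x, y, phenotype idx, niche id."""
    width, height = cfg.roi_size_um
    area_mm2 = width * height / 1e6
    phen_index = {p: i for i, p in enumerate(cfg.signatures.index)}
    xs, ys, phen, niche = [], [], [], []
    for spec in cfg.niches:
        lam = spec.parents_per_mm2 * area_mm2 * niche_mult.get(spec.niche_id, 1.0)
        n_parents = rng.poisson(lam)
        comp_names = list(spec.composition)
        comp_p = np.array([spec.composition[c] for c in comp_names])
        comp_idx = np.array([phen_index[c] for c in comp_names])
        for _ in range(n_parents):
            px, py = rng.uniform(0, width), rng.uniform(0, height)
            n_off = rng.poisson(spec.offspring_mean)
            if n_off == 0:
                continue
            ox = np.clip(rng.normal(px, spec.offspring_sd_um, n_off), 0, width)
            oy = np.clip(rng.normal(py, spec.offspring_sd_um, n_off), 0, height)
            labels = comp_idx[rng.choice(len(comp_names), size=n_off, p=comp_p)]
            xs.append(ox)
            ys.append(oy)
            phen.append(labels)
            niche.append(np.full(n_off, spec.niche_id, dtype=object))
    if not xs:
        return (np.empty(0), np.empty(0), np.empty(0, int), np.empty(0, object))
    return (
        np.concatenate(xs),
        np.concatenate(ys),
        np.concatenate(phen),
        np.concatenate(niche),
    )


def _inject_attraction(rng, x, y, phen_idx, niche, phen_names, att: AttractionSpec,
                       excess: float):
    """Relocate a fraction of target cells next to random source cells.

    A relocated cell now physically resides in its anchor's niche, so its
    ground-truth niche label follows it."""
    if excess <= 0 or att.radius_um <= 0:
        return
    src = np.flatnonzero(phen_idx == phen_names.index(att.source))
    tgt = np.flatnonzero(phen_idx == phen_names.index(att.target))
    if len(src) == 0 or len(tgt) == 0:
        return
    n_move = int(round(excess * len(tgt)))
    if n_move == 0:
        return
    moved = rng.choice(tgt, size=n_move, replace=False)
    anchors = rng.choice(src, size=n_move, replace=True)
    # uniform placement in the disk of radius radius_um around the anchor
    r = att.radius_um * np.sqrt(rng.uniform(size=n_move))
    theta = rng.uniform(0, 2 * np.pi, size=n_move)
    x[moved] = x[anchors] + r * np.cos(theta)
    y[moved] = y[anchors] + r * np.sin(theta)
    niche[moved] = niche[anchors]


def simulate_cohort(config: SimConfig) -> tuple[CellTable, CohortMetadata, GroundTruth]:
    """Generate a full synthetic cohort.

    Returns the cell table (raw intensities), the patient metadata with
    recurrence and PFS outcomes, and the aligned ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = MarkerPanel(
        pd.DataFrame(
            {
                "marker_name": list(config.signatures.columns),
                "channel_tag": [
                    dict(
                        zip(
                            MarkerPanel.default().markers,
                            MarkerPanel.default().table["channel_tag"],
                        )
                    ).get(m, "NA")
                    for m in config.signatures.columns
                ],
                "class": [
                    dict(
                        zip(MarkerPanel.default().markers, MarkerPanel.default().table["class"])
                    ).get(m, "lineage")
                    for m in config.signatures.columns
                ],
            }
        )
    )
    phen_names = list(config.signatures.index)
    sig = config.signatures.to_numpy(float)
    markers = list(config.signatures.columns)
    subtypes = SUBTYPES[: config.n_subtypes]

    cell_frames, truth_frames, roi_comp_rows = [], [], []
    patient_rows = []

    for s_idx, subtype in enumerate(subtypes):
        eff = config.subtype_effects.get(subtype, {})
        base_mult = dict(eff.get("niche_weights", {}))
        fshift = eff.get("functional_shift", {})
        for p_idx in range(config.patients_per_subtype):
            patient_id = f"{subtype}_P{p_idx + 1:02d}"
            # per-patient niche random effects (log-normal jitter)
            niche_mult = {
                spec.niche_id: base_mult.get(spec.niche_id, 1.0)
                * float(np.exp(rng.normal(0, config.patient_niche_jitter_sd)))
                for spec in config.niches
            }
            # per-patient realised excess of recurrence-linked attractions
            patient_excess = {}
            for att in config.attractions:
                if att.recurrence_linked:
                    patient_excess[att] = float(
                        np.clip(rng.uniform(0, 2 * att.excess_fraction), 0, 1)
                    )
                else:
                    patient_excess[att] = att.excess_fraction
            # per-(patient, channel) additive batch shifts on raw intensities
            batch_shift = rng.normal(0, config.batch_sd, size=len(markers))

            for r_idx in range(config.rois_per_patient):
                roi_id = f"{patient_id}_R{r_idx + 1}"
                x, y, phen_idx, niche = _sample_roi(rng, config, niche_mult)
                for att in config.attractions:
                    _inject_attraction(
                        rng, x, y, phen_idx, niche, phen_names, att, patient_excess[att]
                    )
                n = len(x)
                mu = sig[phen_idx]  # n x markers log-means
                mu = mu + np.array([fshift.get(m, 0.0) for m in markers])[None, :]
                fine = np.array([phen_names[i] for i in phen_idx], dtype=object)
                # fine functional states within major phenotypes
                for major, variants in config.fine_variants.items():
                    if major not in phen_names:
                        continue
                    members = np.flatnonzero(phen_idx == phen_names.index(major))
                    if len(members) == 0:
                        continue
                    probs = [v[1] for v in variants]
                    rest = 1.0 - sum(probs)
                    draw = rng.choice(len(variants) + 1, size=len(members), p=probs + [rest])
                    for v_i, (vname, _, boosts) in enumerate(variants):
                        chosen = members[draw == v_i]
                        if len(chosen) == 0:
                            continue
                        fine[chosen] = f"{major}.{vname}"
                        for m, b in boosts.items():
                            if m in markers:
                                mu[chosen, markers.index(m)] += b
                if config.noise_sd > 0:
                    logs = rng.normal(mu, config.noise_sd)
                else:
                    logs = mu
                inten = np.exp(logs)
                if config.noise_sd > 0 or config.batch_sd > 0:
                    inten = np.maximum(inten + batch_shift[None, :], 0.0)
                frame = pd.DataFrame(
                    {
                        "cell_id": np.arange(1, n + 1),
                        "roi_id": roi_id,
                        "patient_id": patient_id,
                        "x": np.round(x, 3),
                        "y": np.round(y, 3),
                    }
                )
                for j, m in enumerate(markers):
                    frame[m] = np.round(inten[:, j], 4)
                cell_frames.append(frame)
                truth_frames.append(
                    pd.DataFrame(
                        {
                            "roi_id": roi_id,
                            "cell_id": np.arange(1, n + 1),
                            "phenotype": [phen_names[i] for i in phen_idx],
                            "fine_phenotype": fine,
                            "niche": niche,
                        }
                    )
                )
                comp = np.bincount(phen_idx, minlength=len(phen_names)).astype(float)
                comp = comp / max(comp.sum(), 1.0)
                roi_comp_rows.append(pd.Series(comp, index=phen_names, name=roi_id))

            patient_rows.append(
                {
                    "patient_id": patient_id,
                    "subtype": subtype,
                    "niche_mult": niche_mult,
                    "attraction_excess": {
                        f"{a.source}->{a.target}": e for a, e in patient_excess.items()
                    },
                    "recurrence_linked_excess": next(
                        (e for a, e in patient_excess.items() if a.recurrence_linked), 0.0
                    ),
                }
            )

    cells_df = pd.concat(cell_frames, ignore_index=True)
    truth_df = pd.concat(truth_frames, ignore_index=True)

    # patient-level planted features and outcomes
    om = config.outcome
    pat = pd.DataFrame(patient_rows)
    freq_feature = []
    for p in pat["patient_id"]:
        t = truth_df[truth_df["roi_id"].str.startswith(p + "_R")]
        freq_feature.append((t["phenotype"] == om.freq_phenotype).mean())
    pat["freq_feature"] = freq_feature
    z_freq = _standardise(pat["freq_feature"].to_numpy())
    z_att = _standardise(pat["recurrence_linked_excess"].to_numpy())
    lp = om.intercept + om.beta_freq * z_freq + om.beta_attraction * z_att
    pat["linear_predictor"] = lp
    prob = 1.0 / (1.0 + np.exp(-lp))
    recurrence = (rng.uniform(size=len(pat)) < prob).astype(int)
    hazard = om.base_hazard * np.exp(om.hazard_scale * lp)
    t_event = rng.exponential(1.0 / np.maximum(hazard, 1e-12))
    c_time = rng.uniform(0, om.followup_months, size=len(pat))
    pfs = np.minimum(t_event, c_time)
    event = (t_event <= c_time).astype(int)

    cohort = CohortMetadata(
        pd.DataFrame(
            {
                "patient_id": pat["patient_id"],
                "subtype": pat["subtype"],
                "recurrence": recurrence,
                "pfs_months": np.round(pfs, 3),
                "event": event,
            }
        )
    )
    truth = GroundTruth(
        cells=truth_df,
        roi_composition=pd.DataFrame(roi_comp_rows),
        attractions=list(config.attractions),
        patient_truth=pat[
            ["patient_id", "subtype", "freq_feature", "recurrence_linked_excess",
             "linear_predictor"]
        ].copy(),
    )
    return CellTable(cells_df, panel), cohort, truth


def _standardise(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


class InteractionExcess(NamedTuple):
    excess: float
    observed: float
    baseline: float
    baseline_sd: float  # spread of the shuffle-null statistic
    baseline_se: float  # standard error of the null mean
    defined: bool


def planted_interaction_check(
    cells: CellTable,
    truth: GroundTruth,
    pair: tuple[str, str],
    radius_um: float,
    n_shuffle: int = 200,
    seed: int = 0,
) -> InteractionExcess:
    """Brute-force oracle for planted attractions.

    For the ordered phenotype pair ``(A, B)`` computes the observed mean
    number of B neighbours per A cell within ``radius_um`` (pooled over
    ROIs), minus the mean of the same statistic over ``n_shuffle`` label
    shuffles within each ROI.  Distances come from full pairwise brute
    force, independent of the package's KD-tree neighbour search.
    """
    if radius_um < 0:
        raise ParameterError("radius_um must be >= 0")
    if radius_um == 0:
        # a zero radius admits no neighbour pairs (coincident centroids are
        # segmentation artefacts, not interactions)
        return InteractionExcess(0.0, 0.0, 0.0, 0.0, 0.0, True)
    rng = np.random.default_rng(seed)
    a_name, b_name = pair
    labels_all = truth.cells.set_index(["roi_id", "cell_id"])["phenotype"]
    obs_num = obs_den = 0.0
    shuffle_stats = np.zeros(n_shuffle)
    shuffle_den = 0.0
    defined = False
    for roi, idx in cells.by_roi():
        sub = cells.df.iloc[idx]
        lab = labels_all.loc[list(zip(sub["roi_id"], sub["cell_id"]))].to_numpy()
        is_a, is_b = lab == a_name, lab == b_name
        n_a = int(is_a.sum())
        if n_a == 0 or not is_b.any():
            continue
        defined = True
        pts = sub[["x", "y"]].to_numpy(float)
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        adj = (d <= radius_um) & ~np.eye(len(pts), dtype=bool)
        obs_num += adj[is_a][:, is_b].sum()
        obs_den += n_a
        for s in range(n_shuffle):
            perm = rng.permutation(len(lab))
            pa, pb = is_a[perm], is_b[perm]
            shuffle_stats[s] += adj[pa][:, pb].sum()
        shuffle_den += n_a
    if not defined:
        return InteractionExcess(math.nan, math.nan, math.nan, math.nan, math.nan, False)
    observed = obs_num / obs_den
    baseline_draws = shuffle_stats / shuffle_den
    baseline = float(baseline_draws.mean())
    sd = float(baseline_draws.std(ddof=1))
    se = sd / math.sqrt(n_shuffle)
    return InteractionExcess(observed - baseline, observed, baseline, sd, se, True)
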