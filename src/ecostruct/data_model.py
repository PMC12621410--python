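"""Core data containers for segmented IMC single-cell tables.

The on-disk interchange format is plain comma-separated text with a header:
``cells.csv`` (one row per segmented cell), ``cohort.csv`` (one row per
patient) and ``panel.csv`` (one row per antibody channel).  Coordinates are
continuous micrometres with the origin at the top-left of each ROI; at the
instrument's ~1 µm resolution one pixel corresponds to one micrometre, so
micrometres are the only unit the package stores.

Cell identity is scoped to its ROI (segmentation masks are per image);
the global identifier of a cell is the ``(roi_id, cell_id)`` pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

MANDATORY_CELL_COLUMNS = ("cell_id", "roi_id", "patient_id", "x", "y")
OPTIONAL_CELL_COLUMNS = ("phenotype", "region", "cn")

#: canonical molecular-subtype labels of the endometrial-carcinoma cohort
SUBTYPES = ("POLE", "MSI-H", "CNH", "CNL")

REGION_CLASSES = ("epithelial", "fibrotic", "immune")

MARKER_CLASSES = ("lineage", "functional", "dna")

# 39 protein markers (lineage + functional) plus two iridium DNA
# intercalator channels, mirroring a 41-plex endometrial-cancer panel.
_DEFAULT_PANEL = [
    # lineage
    ("CD45", "Sm147", "lineage"),
    ("CD3", "Er170", "lineage"),
    ("CD4", "Gd156", "lineage"),
    ("CD8", "Dy162", "lineage"),
    ("FoxP3", "Gd155", "lineage"),
    ("CD127", "Gd157", "lineage"),
    ("CD45RO", "Yb173", "lineage"),
    ("CD45RA", "Nd143", "lineage"),
    ("CD38", "Nd144", "lineage"),
    ("CD16", "Nd146", "lineage"),
    ("CD20", "Dy161", "lineage"),
    ("CD57", "Yb171", "lineage"),
    ("CD56", "Yb176", "lineage"),
    ("GranzymeB", "Er167", "lineage"),
    ("CD25", "Tm169", "lineage"),
    ("E-cadherin", "Yb172", "lineage"),
    ("panCK", "Nd148", "lineage"),
    ("S100A9", "Nd145", "lineage"),
    ("CD11c", "Sm154", "lineage"),
    ("CD11b", "Nd150", "lineage"),
    ("CD14", "Sm149", "lineage"),
    ("CD15", "Dy164", "lineage"),
    ("CD68", "Tb159", "lineage"),
    ("CD163", "Sm152", "lineage"),
    ("HLA-DR", "Yb174", "lineage"),
    ("CD31", "Eu151", "lineage"),
    ("CD90", "Dy163", "lineage"),
    ("CD105", "Gd160", "lineage"),
    ("aSMA", "Pr141", "lineage"),
    ("Collagen1", "Tm168", "lineage"),
    ("Vimentin", "Nd142", "lineage"),
    # functional markers and immune checkpoints
    ("HIF1a", "Gd158", "functional"),
    ("Ki67", "Er168", "functional"),
    ("CXCR4", "Yb175", "functional"),
    ("SDF1", "Er166", "functional"),
    ("TNFa", "Lu175", "functional"),
    ("IL1b", "La139", "functional"),
    ("PD-L1", "Nd153", "functional"),
    ("PD-1", "Ho165", "functional"),
    # DNA intercalator
    ("DNA1", "Ir191", "dna"),
    ("DNA2", "Ir193", "dna"),
]


@dataclass
class MarkerPanel:
    """Antibody panel: marker names, metal channel tags, and marker class.

    ``class`` is one of ``lineage`` (cell-identity markers), ``functional``
    (activation / checkpoint markers) or ``dna`` (intercalator channels).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker_name", "channel_tag", "class"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"panel table missing columns: {sorted(missing)}")
        names = self.table["marker_name"]
        if names.duplicated().any():
            dupes = sorted(names[names.duplicated()].unique())
            raise ValidationError(f"duplicate marker names in panel: {dupes}")
        bad = set(self.table["class"]) - set(MARKER_CLASSES)
        if bad:
            raise ValidationError(f"unknown marker classes: {sorted(bad)}")
        if not (self.table["class"] == "lineage").any():
            raise ValidationError("panel must contain at least one lineage marker")

    @classmethod
    def default(cls) -> "MarkerPanel":
        """The 41-plex panel (39 protein markers + DNA) used throughout."""
        return cls(pd.DataFrame(_DEFAULT_PANEL, columns=["marker_name", "channel_tag", "class"]))

    @classmethod
    def from_csv(cls, path) -> "MarkerPanel":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def markers_of(self, *classes: str) -> list[str]:
        sel = self.table["class"].isin(classes)
        return list(self.table.loc[sel, "marker_name"])

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker_name"])

    @property
    def protein_markers(self) -> list[str]:
        return self.markers_of("lineage", "functional")

    @property
    def lineage_markers(self) -> list[str]:
        return self.markers_of("lineage")

    @property
    def functional_markers(self) -> list[str]:
        return self.markers_of("functional")


@dataclass
class CellTable:
    """A validated per-cell table with a panel describing intensity columns.

    The underlying frame always carries ``cell_id, roi_id, patient_id, x, y``
    and one intensity column per panel marker; ``phenotype``, ``region`` and
    ``cn`` columns appear as the pipeline annotates cells.  Extra columns are
    preserved untouched.
    """

    df: pd.DataFrame
    panel: MarkerPanel
    raw: bool = True  # intensities untransformed (must then be >= 0)

    def __post_init__(self) -> None:
        for col in MANDATORY_CELL_COLUMNS:
            if col not in self.df.columns:
                raise SchemaError(f"cell table missing mandatory column: {col!r}")
        for m in self.panel.markers:
            if m not in self.df.columns:
                raise SchemaError(f"cell table missing panel marker column: {m!r}")
        xy = self.df[["x", "y"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise ValidationError("cell coordinates must be finite")
        if self.raw:
            vals = self.df[self.panel.markers].to_numpy(float)
            if (vals < 0).any():
                bad = [m for m in self.panel.markers if (self.df[m] < 0).any()]
                raise ValidationError(f"negative raw intensities in channels: {bad}")
        dup = self.df.duplicated(subset=["roi_id", "cell_id"])
        if dup.any():
            pairs = self.df.loc[dup, ["roi_id", "cell_id"]].iloc[:3].to_records(index=False)
            raise ValidationError(f"duplicate (roi_id, cell_id) pairs, e.g. {list(pairs)}")
        n_pat = self.df.groupby("roi_id", sort=False)["patient_id"].nunique()
        if (n_pat > 1).any():
            raise ValidationError(
                f"ROIs mapped to multiple patients: {list(n_pat.index[n_pat > 1])}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def rois(self) -> list:
        return list(pd.unique(self.df["roi_id"]))

    @property
    def intensities(self) -> pd.DataFrame:
        return self.df[self.panel.markers]

    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(float)

    def by_roi(self):
        """Iterate ``(roi_id, positional index array)`` preserving row order."""
        for roi, idx in self.df.groupby("roi_id", sort=False).indices.items():
            yield roi, idx

    def with_columns(self, **cols) -> "CellTable":
        df = self.df.copy()
        for name, values in cols.items():
            df[name] = values
        return CellTable(df, self.panel, raw=self.raw)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class CohortMetadata:
    """Patient-level metadata: molecular subtype, recurrence and survival."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("patient_id", "subtype"):
            if col not in self.df.columns:
                raise SchemaError(f"cohort table missing column: {col!r}")
        self.df = self.df.copy()
        self.df["subtype"] = normalise_subtypes(self.df["subtype"])
        if self.df["patient_id"].duplicated().any():
            raise ValidationError("duplicate patient_id in cohort table")
        if "event" in self.df.columns and "pfs_months" not in self.df.columns:
            raise SchemaError("cohort has 'event' but no 'pfs_months' column")
        if "pfs_months" in self.df.columns:
            t = self.df["pfs_months"].to_numpy(float)
            if (t < 0).any():
                raise ValidationError("pfs_months must be non-negative")

    @property
    def patients(self) -> list:
        return list(self.df["patient_id"])

    def subtype_of(self) -> pd.Series:
        return self.df.set_index("patient_id")["subtype"]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def normalise_subtypes(values: pd.Series) -> pd.Series:
    """Map free-form subtype strings onto the four canonical labels.

    Matching is case-insensitive and ignores hyphens/underscores, so
    ``pole``, ``msih`` and ``MSI_H`` all normalise.  Anything outside the
    four-class set raises :class:`ValidationError`.
    """
    canon = {s.replace("-", "").upper(): s for s in SUBTYPES}
    out, bad = [], []
    for v in values:
        key = str(v).strip().replace("-", "").replace("_", "").upper()
        if key in canon:
            out.append(canon[key])
        else:
            bad.append(v)
    if bad:
        raise ValidationError(f"unknown molecular subtypes: {sorted(set(map(str, bad)))}")
    return pd.Series(out, index=values.index, name=values.name)


def load_cell_table(path, panel: MarkerPanel) -> CellTable:
    """Read ``cells.csv`` and validate it against *panel*.

    Unknown extra columns are preserved as annotations and row order is kept.
    """
    df = pd.read_csv(path)
    return CellTable(df, panel)


def load_cohort(path) -> CohortMetadata:
    return CohortMetadata(pd.read_csv(path))


def join_cohort(cells: CellTable, cohort: CohortMetadata) -> tuple[pd.DataFrame, list]:
    """Left-join patient metadata onto cells.

    Returns the joined frame and the list of patient ids present in the cell
    table but absent from the metadata; uncovered patients are reported (and
    warned about), never silently dropped.
    """
    meta = cohort.df.set_index("patient_id")
    joined = cells.df.join(meta, on="patient_id")
    missing = sorted(set(cells.df["patient_id"]) - set(cohort.patients))
    if missing:
        warnings.warn(f"patients without cohort metadata: {missing}", stacklevel=2)
    return joined, missing
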