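"""On-disk data model and typed readers/writers.

All tabular artifacts are TSV.  The abundance matrix is stored with
metabolites as rows and samples as columns (the dominant metabolomics
convention); an ``orientation`` flag accepts transposed input.  Missing
values are empty cells; the sentinels ``NA`` and ``ND`` are also accepted
on read.  Identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

MISSING_SENTINELS = {"", "NA", "ND", "NaN", "nan"}

SAMPLE_ROLES = ("experimental", "reference_serum", "reference_plasma", "blank")
GROUPS = ("control", "bodybuilding", "endurance", "sprint")
TIMEPOINTS = ("baseline", "post")

SUPERPATHWAYS = (
    "lipid",
    "amino_acid",
    "xenobiotics",
    "peptide",
    "nucleotide",
    "cofactors_and_vitamins",
    "carbohydrate",
    "energy",
    "unknown",
)


class SchemaError(ValueError):
    """An input violates a structural invariant (duplicate ids, bad enum...)."""


class ParseError(ValueError):
    """A cell could not be parsed; message names the offending row/column."""


# ---------------------------------------------------------------------------
# IonCountMatrix
# ---------------------------------------------------------------------------


class IonCountMatrix:
    """Metabolite x sample abundance grid with an explicit missing mask.

    Parameters
    ----------
    values
        DataFrame indexed by metabolite id with sample-id columns.  NaN
        encodes a missing measurement.
    log_scale
        False for raw ion counts (all present values must be >= 0),
        True after log2 transformation.
    """

    def __init__(self, values: pd.DataFrame, log_scale: bool = False):
        values = values.astype(float)
        self.values = values
        self.log_scale = bool(log_scale)
        self.validate()

    # -- basic views -------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the measurement is missing."""
        return self.values.isna()

    def missing_fraction(self) -> float:
        return float(self.values.isna().to_numpy().mean())

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise SchemaError(f"duplicated metabolite ids: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise SchemaError(f"duplicated sample ids: {dups}")
        if not self.log_scale:
            vals = self.values.to_numpy()
            if np.nanmin(vals, initial=np.inf) < 0:
                raise SchemaError("negative abundance in a raw ion-count matrix")

    # -- convenience -------------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "IonCountMatrix":
        return IonCountMatrix(self.values.loc[:, list(sample_ids)], self.log_scale)

    def subset_metabolites(self, metabolite_ids: Sequence[str]) -> "IonCountMatrix":
        return IonCountMatrix(self.values.loc[list(metabolite_ids)], self.log_scale)

    def copy(self) -> "IonCountMatrix":
        return IonCountMatrix(self.values.copy(), self.log_scale)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_m, n_s = self.shape
        scale = "log2" if self.log_scale else "ion counts"
        return f"IonCountMatrix({n_m} metabolites x {n_s} samples, {scale})"


# ---------------------------------------------------------------------------
# SampleMeta
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SampleMeta:
    """Per-sample metadata: role, subject, group, timepoint, batch.

    ``df`` columns: sample_id, subject_id, role, group, timepoint, batch.
    Empty string means not applicable (e.g. no subject for reference wells).
    """

    df: pd.DataFrame

    COLUMNS = ("sample_id", "subject_id", "role", "group", "timepoint", "batch")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"samples table missing column '{col}'")
            df[col] = df[col].fillna("").astype(str)
        self.df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if df["sample_id"].duplicated().any():
            raise SchemaError("duplicated sample_id in samples table")
        bad_role = set(df["role"]) - set(SAMPLE_ROLES)
        if bad_role:
            raise SchemaError(f"unknown sample role(s): {sorted(bad_role)}")
        exp = df[df["role"] == "experimental"]
        for col in ("subject_id", "group", "timepoint"):
            if (exp[col] == "").any():
                raise SchemaError(f"experimental sample with empty {col}")
        bad_group = set(exp["group"]) - set(GROUPS)
        if bad_group:
            raise SchemaError(f"unknown group(s): {sorted(bad_group)}")
        bad_tp = set(exp["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise SchemaError(f"unknown timepoint(s): {sorted(bad_tp)}")
        if exp.duplicated(subset=["subject_id", "timepoint"]).any():
            raise SchemaError("duplicate (subject_id, timepoint) pair")
        # every batch with experimental samples needs >= 2 reference serum wells
        for batch, sub in df.groupby("batch"):
            if (sub["role"] == "experimental").any():
                n_ref = int((sub["role"] == "reference_serum").sum())
                if n_ref < 2:
                    raise SchemaError(
                        f"batch '{batch}' has {n_ref} reference_serum wells; "
                        "need >= 2 for batch-median normalization"
                    )

    # -- selectors ---------------------------------------------------------
    def experimental(self) -> pd.DataFrame:
        return self.df[self.df["role"] == "experimental"]

    def sample_ids(self, role: str | None = None, timepoint: str | None = None) -> list[str]:
        df = self.df
        if role is not None:
            df = df[df["role"] == role]
        if timepoint is not None:
            df = df[df["timepoint"] == timepoint]
        return df["sample_id"].tolist()

    def batch_of(self) -> pd.Series:
        return self.df.set_index("sample_id")["batch"]

    def group_of(self) -> pd.Series:
        exp = self.experimental()
        return exp.set_index("sample_id")["group"]

    def subject_of(self) -> pd.Series:
        exp = self.experimental()
        return exp.set_index("sample_id")["subject_id"]


# ---------------------------------------------------------------------------
# TraitTable & MetaboliteAnnotation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TraitTable:
    """Per-subject numeric traits; NaN allowed for missing measurements."""

    df: pd.DataFrame  # indexed by subject_id, one column per trait

    def __post_init__(self) -> None:
        df = self.df
        if df.index.duplicated().any():
            raise SchemaError("duplicated subject_id in traits table")
        df = df.astype(float)
        vals = df.to_numpy()
        if np.isinf(vals).any():
            raise SchemaError("non-finite trait value")
        self.df = df

    @property
    def trait_names(self) -> list[str]:
        return list(self.df.columns)


@dataclasses.dataclass
class MetaboliteAnnotation:
    """Metabolite identity: name, super/subpathway, external database ids."""

    df: pd.DataFrame  # indexed by metabolite_id

    COLUMNS = ("name", "superpathway", "subpathway", "hmdb", "pubchem")

    def __post_init__(self) -> None:
        df = self.df.copy()
        if df.index.duplicated().any():
            raise SchemaError("duplicated metabolite_id in annotation table")
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = ""
            df[col] = df[col].fillna("").astype(str)
        bad = set(df["superpathway"]) - set(SUPERPATHWAYS) - {""}
        if bad:
            raise SchemaError(f"unknown superpathway value(s): {sorted(bad)}")
        self.df = df.loc[:, list(self.COLUMNS)]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _parse_numeric_frame(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Parse string cells to floats; sentinels become NaN; name bad cells."""
    out = np.empty(df.shape, dtype=float)
    arr = df.to_numpy()
    for j, col in enumerate(df.columns):
        for i in range(df.shape[0]):
            tok = arr[i, j].strip()
            if tok in MISSING_SENTINELS:
                out[i, j] = np.nan
                continue
            try:
                out[i, j] = float(tok)
            except ValueError as exc:
                raise ParseError(
                    f"{what}: malformed numeric cell '{tok}' at row "
                    f"'{df.index[i]}', column '{col}'"
                ) from exc
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def read_matrix(
    path,
    orientation: Literal["metabolites_as_rows", "samples_as_rows"] = "metabolites_as_rows",
    log_scale: bool = False,
) -> IonCountMatrix:
    """Read an abundance matrix from TSV (first column = row ids)."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: need one id column plus >= 1 data column")
    raw = raw.set_index(raw.columns[0])
    values = _parse_numeric_frame(raw, str(path))
    if orientation == "samples_as_rows":
        values = values.T
    elif orientation != "metabolites_as_rows":
        raise ValueError(f"unknown orientation '{orientation}'")
    return IonCountMatrix(values, log_scale=log_scale)


def write_matrix(matrix: IonCountMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "metabolite_id"
    # %.17g guarantees float64 round-trips bit-identically
    df.to_csv(path, sep="\t", float_format="%.17g", na_rep="")


def read_samples(path) -> SampleMeta:
    return SampleMeta(_read_tsv(path))


def write_samples(meta: SampleMeta, path) -> None:
    meta.df.to_csv(path, sep="\t", index=False)


def read_traits(path) -> TraitTable:
    raw = _read_tsv(path)
    if raw.columns[0] != "subject_id":
        raise SchemaError("traits table must start with a 'subject_id' column")
    raw = raw.set_index("subject_id")
    return TraitTable(_parse_numeric_frame(raw, str(path)))


def write_traits(traits: TraitTable, path) -> None:
    df = traits.df.copy()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", float_format="%.10g", na_rep="")


def read_annotation(path) -> MetaboliteAnnotation:
    raw = _read_tsv(path)
    if raw.columns[0] != "metabolite_id":
        raise SchemaError("annotation table must start with 'metabolite_id'")
    return MetaboliteAnnotation(raw.set_index("metabolite_id"))


def write_annotation(ann: MetaboliteAnnotation, path) -> None:
    df = ann.df.copy()
    df.index.name = "metabolite_id"
    df.to_csv(path, sep="\t", index=True)


def write_table(records: pd.DataFrame, path) -> None:
    """Write a result table with a stable column order and fixed precision."""
    records.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)


# ---------------------------------------------------------------------------
# MetaboLights metabolite-assignment-file (MAF) dialect
# ---------------------------------------------------------------------------

#: identification columns of the MAF dialect mapped to annotation fields
_MAF_ID_COLUMNS = {
    "database_identifier": None,
    "chemical_formula": None,
    "smiles": None,
    "inchi": None,
    "metabolite_identification": "name",
    "superpathway": "superpathway",
    "subpathway": "subpathway",
    "hmdb": "hmdb",
    "pubchem": "pubchem",
    "mass_to_charge": None,
    "retention_time": None,
}

_MAF_MANDATORY = ("database_identifier", "metabolite_identification")


def read_maf(path) -> tuple[IonCountMatrix, MetaboliteAnnotation]:
    """Read a MetaboLights metabolite assignment file.

    Identification columns (those named in the MAF dialect) populate the
    annotation; every remaining column is treated as a per-sample abundance
    column.  Unparseable abundance cells (e.g. ``ND``) become missing.
    """
    raw = _read_tsv(path)
    cols_lower = {c.lower(): c for c in raw.columns}
    for mand in _MAF_MANDATORY:
        if mand not in cols_lower:
            raise ParseError(f"{path}: missing mandatory MAF header '{mand}'")

    id_col = cols_lower["database_identifier"]
    ids = raw[id_col].astype(str)
    if ids.duplicated().any():
        raise SchemaError("duplicated database_identifier in MAF")

    known = {c for c in raw.columns if c.lower() in _MAF_ID_COLUMNS}
    sample_cols = [c for c in raw.columns if c not in known]

    ann = pd.DataFrame(index=pd.Index(ids, name="metabolite_id"))
    for maf_col, field in _MAF_ID_COLUMNS.items():
        if field is not None and maf_col in cols_lower:
            ann[field] = raw[cols_lower[maf_col]].to_numpy()
    annotation = MetaboliteAnnotation(ann)

    ab = raw.loc[:, sample_cols].copy()
    ab.index = pd.Index(ids, name="metabolite_id")
    values = np.full(ab.shape, np.nan)
    arr = ab.to_numpy()
    for j in range(ab.shape[1]):
        for i in range(ab.shape[0]):
            tok = str(arr[i, j]).strip()
            if tok in MISSING_SENTINELS:
                continue
            try:
                values[i, j] = float(tok)
            except ValueError:
                continue  # non-numeric token = not detected
    matrix = IonCountMatrix(pd.DataFrame(values, index=ab.index, columns=sample_cols))
    return matrix, annotation
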