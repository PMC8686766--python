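"""Core data containers and file I/O.

The pipeline's unit of analysis is the *probe* (an aptamer reagent measuring
one or occasionally several proteins); abundance is recorded in relative
fluorescence units (RFU, positive reals) and analysed on the log2 scale.
All tabular formats are TSV (tab-separated, UTF-8, header row); CSV is
accepted on read by delimiter sniffing. Protein sets use the standard GMT
dialect (name, description, tab-separated members).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CELLULAR_LOCATIONS = (
    "nucleus",
    "cytoplasm",
    "plasma membrane",
    "extracellular space",
    "other",
)
DISEASES = ("COPD", "asthma")
SEXES = ("F", "M")

# Columns of the clinical table; all but subject_id/disease are optional.
CLINICAL_NUMERIC = (
    "age",
    "bmi",
    "pack_years",
    "blood_eos",
    "sputum_eos",
    "fev1_l",
    "fev1_pct",
    "kco_pct",
    "dlco_pct",
    "ics_dose",
    "storage_days",
    "exac_time",
)


class DataError(ValueError):
    """Raised when a file or container violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = sorted(set(ids[ids.duplicated()]))
        raise DataError(f"duplicate {what}: {dups}")


@dataclass
class ProteomeMatrix:
    """Probe x subject RFU matrix.

    ``values`` is a DataFrame indexed by probe id with subject ids as
    columns.  ``log_transformed`` records whether values are log2 RFU.
    """

    values: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe id")
        _check_unique(self.values.columns, "subject id")
        if self.values.isna().any().any():
            raise DataError("proteome matrix contains missing values")
        if not self.log_transformed and (self.values.to_numpy() <= 0).any():
            raise DataError("RFU values must be positive on the raw scale")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ProbeAnnotation:
    """Per-probe annotation: protein symbol(s), UniProt id(s), cellular
    location (fixed five-term vocabulary) and a QC pass flag.

    ``table`` is indexed by probe id; ``protein_symbols`` and ``uniprot``
    hold tuples so multi-protein probes carry every symbol they measure.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "probe id")
        required = {"protein_symbols", "uniprot", "cellular_location", "qc_pass"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataError(f"annotation missing columns: {sorted(missing)}")
        bad_loc = set(self.table["cellular_location"]) - set(CELLULAR_LOCATIONS)
        if bad_loc:
            raise DataError(f"unknown cellular location(s): {sorted(bad_loc)}")
        for pid, syms in self.table["protein_symbols"].items():
            if not isinstance(syms, tuple) or len(syms) == 0:
                raise DataError(f"probe {pid}: protein_symbols must be a non-empty tuple")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def symbols_for(self, probe_id: str) -> tuple[str, ...]:
        return self.table.loc[probe_id, "protein_symbols"]

    def symbol_map(self) -> dict[str, tuple[str, ...]]:
        """probe id -> protein symbols, for set-membership mapping."""
        return dict(self.table["protein_symbols"])


@dataclass
class ClinicalTable:
    """Per-subject covariates plus optional longitudinal visits and
    time-to-first-exacerbation data.

    ``subjects`` is indexed by subject id; missing optional fields are NaN
    (absent, never imputed).  ``visits`` has columns subject_id,
    time_years, kco, fev1 with strictly increasing times per subject.
    """

    subjects: pd.DataFrame
    visits: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["subject_id", "time_years", "kco", "fev1"]
        )
    )

    def __post_init__(self) -> None:
        _check_unique(self.subjects.index, "subject id")
        if "disease" not in self.subjects.columns:
            raise DataError("clinical table requires a disease column")
        bad = set(self.subjects["disease"].dropna()) - set(DISEASES)
        if bad:
            raise DataError(f"unknown disease label: {sorted(bad)}")
        if "sex" in self.subjects.columns:
            bad_sex = set(self.subjects["sex"].dropna()) - set(SEXES)
            if bad_sex:
                raise DataError(f"unknown sex code: {sorted(bad_sex)}")
        for col in ("exac_time",):
            if col in self.subjects.columns:
                vals = self.subjects[col].dropna()
                if (vals < 0).any():
                    raise DataError(f"{col} must be non-negative")
        if len(self.visits):
            if (self.visits["time_years"] < 0).any():
                raise DataError("visit times must be non-negative")
            for sid, grp in self.visits.groupby("subject_id"):
                t = grp["time_years"].to_numpy()
                if not (np.diff(t) > 0).all():
                    raise DataError(
                        f"visit times for subject {sid} must be strictly increasing"
                    )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects.index)


@dataclass
class ProteinSetCollection:
    """Named, non-empty sets of protein symbols (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise DataError(f"protein set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class TissueExpression:
    """Gene x tissue expression matrix (GeneAtlas-style atlas)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "tissue")
        if self.values.isna().any().any():
            raise DataError("tissue expression matrix contains missing values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MarkerList:
    """Ordered list of unique protein symbols (e.g. exosomal markers)."""

    symbols: list[str]

    def __post_init__(self) -> None:
        _check_unique(self.symbols, "marker symbol")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first or "," not in first else ","


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sniff_sep(path), index_col=0)


def read_proteome(matrix_path, annotation_path) -> tuple[ProteomeMatrix, ProbeAnnotation]:
    """Read an RFU matrix (first column probe ids, header subject ids) and
    its probe annotation, aligned; probes without annotation are an error.
    """
    df = _read_table(matrix_path)
    _check_unique(df.index, "probe id")
    _check_unique(df.columns, "subject id")
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        r, c = rows[0], cols[0]
        raise DataError(
            f"missing value at probe {df.index[r]!r}, subject {df.columns[c]!r}"
        )
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise DataError(f"non-numeric RFU column(s): {non_numeric}")
    ann = read_annotation(annotation_path)
    missing = [p for p in df.index if p not in ann.table.index]
    if missing:
        raise DataError(f"probes absent from annotation: {missing}")
    ann = ProbeAnnotation(ann.table.loc[df.index])
    return ProteomeMatrix(df.astype(float)), ann


def write_proteome(matrix: ProteomeMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


def read_annotation(path) -> ProbeAnnotation:
    df = _read_table(path)
    df = df.copy()
    for col in ("protein_symbols", "uniprot"):
        df[col] = [tuple(str(v).split(";")) if not pd.isna(v) else () for v in df[col]]
    df["qc_pass"] = df["qc_pass"].astype(bool)
    return ProbeAnnotation(df)


def write_annotation(ann: ProbeAnnotation, path) -> None:
    df = ann.table.copy()
    for col in ("protein_symbols", "uniprot"):
        df[col] = [";".join(v) for v in df[col]]
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


_VISIT_FIELD_SEP = "|"
_VISIT_SEP = ";"


def _encode_visits(grp: pd.DataFrame) -> str:
    parts = []
    for _, row in grp.iterrows():
        parts.append(
            _VISIT_FIELD_SEP.join(
                repr(float(row[c])) if not pd.isna(row[c]) else ""
                for c in ("time_years", "kco", "fev1")
            )
        )
    return _VISIT_SEP.join(parts)


def read_clinical(path) -> ClinicalTable:
    """Read the per-subject clinical table.

    Required columns: subject_id (first), disease.  Longitudinal visits, if
    present, are encoded in a ``visits`` column as
    ``time|kco|fev1;time|kco|fev1;...``.
    """
    df = _read_table(path)
    df.index = df.index.astype(str)
    if "disease" not in df.columns:
        raise DataError("clinical table requires a disease column")
    for col in CLINICAL_NUMERIC:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise DataError(f"non-numeric value in column {col!r}: {exc}") from exc
    visit_rows = []
    if "visits" in df.columns:
        for sid, enc in df["visits"].items():
            if pd.isna(enc) or enc == "":
                continue
            for part in str(enc).split(_VISIT_SEP):
                fields = part.split(_VISIT_FIELD_SEP)
                if len(fields) != 3:
                    raise DataError(f"malformed visit entry for subject {sid}: {part!r}")
                t, kco, fev1 = (float(f) if f != "" else math.nan for f in fields)
                visit_rows.append({"subject_id": sid, "time_years": t, "kco": kco, "fev1": fev1})
        df = df.drop(columns=["visits"])
    if "ocs_use" in df.columns:
        df["ocs_use"] = df["ocs_use"].map(
            lambda v: v if pd.isna(v) else bool(v) if isinstance(v, (bool, np.bool_)) else str(v).lower() in ("true", "1")
        )
    if "exac_event" in df.columns:
        df["exac_event"] = df["exac_event"].map(
            lambda v: v if pd.isna(v) else str(v).lower() in ("true", "1")
        )
    visits = pd.DataFrame(visit_rows, columns=["subject_id", "time_years", "kco", "fev1"])
    return ClinicalTable(df, visits)


def write_clinical(clinical: ClinicalTable, path) -> None:
    df = clinical.subjects.copy()
    if len(clinical.visits):
        enc = clinical.visits.groupby("subject_id", sort=False).apply(
            _encode_visits, include_groups=False
        )
        df["visits"] = df.index.map(enc)
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")


def read_gmt(path) -> ProteinSetCollection:
    """Read a GMT protein-set file: name <tab> description <tab> members..."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise DataError(f"duplicate set name {name!r} (line {lineno})")
            if not members:
                raise DataError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return ProteinSetCollection(sets, descriptions)


def write_gmt(collection: ProteinSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = sorted(collection[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_marker_list(path) -> MarkerList:
    """One protein symbol per line; an empty file is a valid empty list."""
    with open(path, "r", encoding="utf-8") as fh:
        symbols = [line.strip() for line in fh if line.strip()]
    return MarkerList(symbols)


def write_marker_list(markers: MarkerList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sym in markers:
            fh.write(sym + "\n")


def read_tissue_matrix(path) -> TissueExpression:
    df = _read_table(path)
    return TissueExpression(df.astype(float))


def write_tissue_matrix(tissue: TissueExpression, path) -> None:
    df = tissue.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as TSV with stable column order and full
    float precision (Python repr round-trips float64 exactly)."""
    df.to_csv(path, sep="\t")
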