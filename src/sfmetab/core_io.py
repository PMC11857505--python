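"""Domain types for labelled metabolite-bin matrices and tabular readers/writers.

A *bin matrix* is a samples × bins intensity table: rows are patients, columns
are NMR metabolite bins labelled with a metabolite name and the ppm center of
the integrated chemical-shift interval. Every sample carries a diagnosis label
from {OA, RA}. The global class-code convention is OA → 0, RA → 1.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABELS = ("OA", "RA")
#: global class coding used by every downstream stage
CLASS_CODE = {"OA": 0, "RA": 1}

# column label of the form "L-Glutamine [2.4482]" -> name + ppm center
_BIN_LABEL_RE = re.compile(r"^\s*(?P<name>.*?)\s*\[\s*(?P<ppm>[-+0-9.eE]+)\s*\]\s*$")

# metadata columns of a MetaboLights metabolite-assignment file that are
# never sample intensity columns
_MAF_META_COLUMNS = {
    "database_identifier", "chemical_formula", "smiles", "inchi",
    "metabolite_identification", "mass_to_charge", "fragmentation",
    "modifications", "charge", "retention_time", "taxid", "species",
    "database", "database_version", "reliability", "uri", "search_engine",
    "search_engine_score", "smallmolecule_abundance_sub",
    "smallmolecule_abundance_stdev_sub", "smallmolecule_abundance_std_error_sub",
    "chemical_shift", "multiplicity",
}


@dataclass(frozen=True)
class BinInfo:
    """One metabolite bin: opaque id, metabolite name, ppm bin center."""

    bin_id: str
    metabolite_name: str = "unknown"
    ppm_center: float = math.nan

    @classmethod
    def from_label(cls, label: str) -> "BinInfo":
        """Parse a column label like ``"L-Glutamine [2.4482]"``.

        Labels without the bracketed ppm center keep the whole label as the
        metabolite name and a NaN ppm center.
        """
        m = _BIN_LABEL_RE.match(label)
        if m:
            try:
                return cls(bin_id=label, metabolite_name=m.group("name") or "unknown",
                           ppm_center=float(m.group("ppm")))
            except ValueError:
                pass
        return cls(bin_id=label, metabolite_name=label or "unknown")

    @property
    def label(self) -> str:
        if math.isfinite(self.ppm_center):
            return f"{self.metabolite_name} [{self.ppm_center:.4f}]"
        return self.metabolite_name


@dataclass(frozen=True)
class ClassSummary:
    n_OA: int
    n_RA: int

    def __post_init__(self) -> None:
        if self.n_OA < 1 or self.n_RA < 1:
            raise ValueError("both classes must be represented")


@dataclass
class BinMatrix:
    """Samples × bins intensity matrix with diagnosis labels and bin metadata.

    Invariants: no missing values, both classes present, unique bin ids,
    consistent dimensions. Enforced on construction via :meth:`validate`.
    """

    values: np.ndarray
    sample_ids: list[str]
    labels: list[str]
    bins: list[BinInfo]
    dropped_bins: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n, p = self.values.shape
        if n != len(self.sample_ids) or n != len(self.labels):
            raise ValueError("row count must match sample_ids and labels")
        if p != len(self.bins):
            raise ValueError("column count must match bin metadata")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("bin matrix contains missing or non-finite values")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if len({b.bin_id for b in self.bins}) != p:
            raise ValueError("bin_id values must be unique")
        self.class_summary()  # raises if a class is absent

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_ids(self) -> list[str]:
        return [b.bin_id for b in self.bins]

    @property
    def y(self) -> np.ndarray:
        """Class codes (OA=0, RA=1), one per sample."""
        return np.array([CLASS_CODE[l] for l in self.labels], dtype=int)

    def class_summary(self) -> ClassSummary:
        return ClassSummary(n_OA=self.labels.count("OA"), n_RA=self.labels.count("RA"))

    def select_bins(self, bin_ids: list[str]) -> "BinMatrix":
        """Column subset, preserving the requested order."""
        index = {b.bin_id: j for j, b in enumerate(self.bins)}
        cols = [index[b] for b in bin_ids]
        return BinMatrix(values=self.values[:, cols], sample_ids=list(self.sample_ids),
                         labels=list(self.labels), bins=[self.bins[j] for j in cols])

    def drop_bins(self, bin_ids: set[str]) -> "BinMatrix":
        keep = [b.bin_id for b in self.bins if b.bin_id not in bin_ids]
        return self.select_bins(keep)

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"),
                          columns=[b.bin_id for b in self.bins])
        df.insert(0, label_column, self.labels)
        return df


def _clean_columns(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop feature columns lacking sufficient information: any missing
    entry, unparsable numeric content, or zero variance."""
    dropped: list[str] = []
    keep: dict[str, pd.Series] = {}
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        if series.isna().any():
            dropped.append(col)
            continue
        if series.nunique() <= 1:
            dropped.append(col)
            continue
        keep[col] = series.astype(float)
    if dropped:
        logger.warning("dropped %d column(s) lacking sufficient information: %s",
                       len(dropped), dropped)
    return pd.DataFrame(keep, index=df.index), dropped


def _normalize_label(value: object) -> str:
    text = str(value).strip().upper()
    if text in LABELS:
        return text
    raise ValueError(f"label {value!r} not mappable to OA/RA")


def read_bin_table(path: str, label_column: str = "label", delimiter: str | None = None) -> BinMatrix:
    """Read a delimited samples × bins table with a diagnosis label column.

    Feature columns with any missing value, non-numeric content, or zero
    variance are dropped (and recorded in ``BinMatrix.dropped_bins``).
    The delimiter is auto-detected unless given explicitly.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c",
                     index_col=0)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels = [_normalize_label(v) for v in df[label_column]]
    features = df.drop(columns=[label_column])
    cleaned, dropped = _clean_columns(features)
    if cleaned.shape[1] == 0:
        raise ValueError("no usable bin columns after cleaning")
    bins = [BinInfo.from_label(str(c)) for c in cleaned.columns]
    return BinMatrix(values=cleaned.to_numpy(dtype=float),
                     sample_ids=[str(s) for s in df.index],
                     labels=labels, bins=bins, dropped_bins=dropped)


def write_bin_table(matrix: BinMatrix, path: str, label_column: str = "label") -> None:
    """Write a bin matrix as a TSV that :func:`read_bin_table` round-trips."""
    matrix.to_frame(label_column).to_csv(path, sep="\t", float_format="%.12g")


def read_maf(path: str, sample_ids: list[str] | None = None,
             labels: dict[str, str] | None = None) -> BinMatrix | pd.DataFrame:
    """Read a MetaboLights metabolite-assignment file (MAF).

    The MAF dialect is tab-separated with one row per metabolite bin and one
    column per sample; rows are transposed into the samples × bins
    orientation used everywhere else. Metabolite names come from the
    ``metabolite_identification`` column (parsed as ``"name [ppm]"`` when it
    carries a bracketed bin center, otherwise a ``chemical_shift`` column is
    consulted for the ppm value).

    The MAF itself carries no diagnosis labels; pass ``labels`` (mapping
    sample id → OA/RA) to obtain a :class:`BinMatrix`, otherwise a plain
    samples × bins DataFrame is returned.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    name_col = "metabolite_identification"
    if name_col not in df.columns:
        raise ValueError(f"MAF is missing the {name_col!r} column")

    candidates = [c for c in df.columns if c.lower() not in _MAF_META_COLUMNS]
    if sample_ids is None:
        sample_ids = candidates
    missing = [s for s in sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"MAF is missing sample column(s): {missing}")
    if not sample_ids:
        raise ValueError("MAF has no sample columns")

    shift_col = df["chemical_shift"] if "chemical_shift" in df.columns else None
    bins: list[BinInfo] = []
    seen: set[str] = set()
    rows = np.empty((len(df), len(sample_ids)), dtype=float)
    for i, (_, row) in enumerate(df.iterrows()):
        info = BinInfo.from_label(str(row[name_col]))
        if not math.isfinite(info.ppm_center) and shift_col is not None:
            try:
                info = BinInfo(bin_id=info.bin_id, metabolite_name=info.metabolite_name,
                               ppm_center=float(shift_col.iloc[i]))
            except (TypeError, ValueError):
                pass
        bin_id = info.label
        if bin_id in seen:
            raise ValueError(f"duplicate bin identifier {bin_id!r} in MAF")
        seen.add(bin_id)
        bins.append(BinInfo(bin_id=bin_id, metabolite_name=info.metabolite_name,
                            ppm_center=info.ppm_center))
        for j, s in enumerate(sample_ids):
            cell = row[s]
            try:
                rows[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(f"non-numeric intensity {cell!r} in MAF row "
                                 f"{i} ({bin_id}), sample {s!r}") from None

    table = pd.DataFrame(rows.T, index=pd.Index(sample_ids, name="sample_id"),
                         columns=[b.bin_id for b in bins])
    if labels is None:
        return table
    missing_labels = [s for s in sample_ids if s not in labels]
    if missing_labels:
        raise ValueError(f"no label supplied for sample(s): {missing_labels}")
    return BinMatrix(values=table.to_numpy(), sample_ids=list(sample_ids),
                     labels=[_normalize_label(labels[s]) for s in sample_ids], bins=bins)
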