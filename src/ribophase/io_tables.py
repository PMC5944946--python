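"""Readers, writers and validation for OTU count tables and companion tables.

Formats are plain tab-separated text: OTU tables (samples as rows, OTUs as
columns; the mothur ``.shared`` dialect is also accepted), a taxonomy table
(OTU -> supergroup / group / closest relative / % identity), a sample
manifest linking each library to its sampling date, molecule (rDNA or rRNA)
and date-pair, and an environmental table (date x named variables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MOLECULES = ("rDNA", "rRNA")

#: Controlled supergroup vocabulary: the eight eukaryotic super-groups
#: observed in coastal 18S surveys, plus Metazoa (flagged for removal) and
#: a catch-all for unassignable OTUs.
SUPERGROUPS = (
    "Alveolata",
    "Amoebozoa",
    "Apusozoa",
    "Archaeplastida",
    "Hacrobia",
    "Opisthokonta",
    "Rhizaria",
    "Stramenopiles",
    "Metazoa",
    "unclassified",
)


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(ValueError):
    """Parsed content violates an invariant of its domain type."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Sample x OTU count matrix with optional per-sample date and molecule.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, samples as rows, OTUs as columns.
    dates
        Optional per-sample sampling dates (index aligned with ``counts``).
    molecule
        Optional per-sample molecule label, one of ``rDNA``/``rRNA``.
    """

    counts: pd.DataFrame
    dates: pd.Series | None = None
    molecule: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self, require_positive_rows: bool = False) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("counts must be finite")
            if not np.all(arr == np.floor(arr)):
                raise ValidationError("counts must be integers")
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValidationError("counts must be non-negative")
        if require_positive_rows and c.shape[0]:
            zero = c.index[c.sum(axis=1) == 0].tolist()
            if zero:
                raise ValidationError(f"samples with zero total reads: {zero}")
        for name, s in (("dates", self.dates), ("molecule", self.molecule)):
            if s is not None and not s.index.equals(c.index):
                raise ValidationError(f"{name} index does not match sample ids")
        if self.molecule is not None:
            bad = set(self.molecule.unique()) - set(MOLECULES)
            if bad:
                raise ValidationError(f"unknown molecule labels: {sorted(bad)}")
            if self.dates is not None:
                key = pd.MultiIndex.from_arrays([self.dates, self.molecule])
                if key.has_duplicates:
                    raise ValidationError("duplicate (date, molecule) pair")

    # -- convenience ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def with_counts(self, counts: pd.DataFrame) -> "OtuTable":
        """New table with ``counts``, carrying metadata for surviving samples."""
        dates = self.dates.loc[counts.index] if self.dates is not None else None
        mol = self.molecule.loc[counts.index] if self.molecule is not None else None
        return OtuTable(counts, dates, mol)


@dataclass
class TaxonomyMap:
    """OTU -> (supergroup, group, closest relative, % identity, is_metazoa)."""

    table: pd.DataFrame  # indexed by otu_id

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate otu_id in taxonomy: {dups}")
        pct = t["pct_identity"].to_numpy(dtype=float)
        ok = np.isnan(pct) | ((pct >= 0) & (pct <= 100))
        if not ok.all():
            raise ValidationError("pct_identity outside [0, 100]")
        unknown = ~t["supergroup"].isin(SUPERGROUPS)
        if unknown.any():
            n = int(unknown.sum())
            logger.warning("%d OTUs with unknown supergroup mapped to 'unclassified'", n)
            self.table = t = t.copy()
            t.loc[unknown, "supergroup"] = "unclassified"
        if "is_metazoa" not in t.columns:
            self.table = t = t.assign(is_metazoa=t["supergroup"] == "Metazoa")

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.table.index

    def __getitem__(self, otu_id: str) -> pd.Series:
        return self.table.loc[otu_id]

    @property
    def otu_ids(self) -> list[str]:
        return list(self.table.index)

    def metazoa(self) -> list[str]:
        return list(self.table.index[self.table["is_metazoa"]])

    def group_of(self, otu_ids: Iterable[str]) -> pd.Series:
        return self.table.loc[list(otu_ids), "group"]


@dataclass
class PairedLibraries:
    """Date-matched rDNA/rRNA library pairs plus leftovers."""

    pairs: list[tuple[object, str, str]]  # (date, dna_sample, rna_sample)
    unpaired: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_otu_table(
    path,
    dialect: str = "tsv",
    manifest: pd.DataFrame | None = None,
    transposed: bool = False,
) -> OtuTable:
    """Read an OTU count table.

    ``dialect='tsv'`` expects a header row of OTU ids and a leading sample-id
    column; ``dialect='mothur_shared'`` expects the mothur ``.shared`` layout
    with leading ``label``/``Group``/``numOtus`` columns. With ``transposed``
    the TSV holds OTUs as rows and is flipped on read. If ``manifest`` is
    given, per-sample dates and molecule labels are attached from it.
    """
    if dialect not in ("tsv", "mothur_shared"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty or unreadable OTU table: {path}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"OTU table needs a sample column and >=1 OTU column: {path}")

    if dialect == "mothur_shared":
        expected = ["label", "Group", "numOtus"]
        if list(df.columns[:3]) != expected:
            raise FormatError(
                f"mothur .shared header must start with {expected}, got {list(df.columns[:3])}"
            )
        n_declared = df["numOtus"].astype(int)
        n_cols = df.shape[1] - 3
        if not (n_declared == n_cols).all():
            raise FormatError("numOtus column disagrees with the number of OTU columns")
        counts = df.iloc[:, 3:].copy()
        counts.index = pd.Index(df["Group"], name="sample_id")
    else:
        counts = df.iloc[:, 1:].copy()
        counts.index = pd.Index(df.iloc[:, 0], name="sample_id")
        if transposed:
            counts = counts.T
            counts.index.name = "sample_id"

    counts = _coerce_counts(counts)
    table = OtuTable(counts)
    table.validate(require_positive_rows=True)
    if manifest is not None:
        table = attach_manifest(table, manifest)
    return table


def _coerce_counts(counts: pd.DataFrame) -> pd.DataFrame:
    try:
        out = counts.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-integer count value: {exc}") from exc
    if out.size and out.to_numpy().min() < 0:
        raise ValidationError("negative count value")
    return out


def write_otu_table(table: OtuTable, path, dialect: str = "tsv") -> None:
    """Write counts as TSV; column order and sample order are preserved."""
    if dialect == "tsv":
        table.counts.to_csv(path, sep="\t", index_label="sample_id")
    elif dialect == "mothur_shared":
        out = table.counts.copy()
        out.insert(0, "numOtus", table.n_otus)
        out.insert(0, "Group", table.sample_ids)
        out.insert(0, "label", "0.03")
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def attach_manifest(table: OtuTable, manifest: pd.DataFrame) -> OtuTable:
    """Attach dates and molecule labels from a manifest by library id."""
    m = manifest.set_index("library_id") if "library_id" in manifest.columns else manifest
    missing = [s for s in table.sample_ids if s not in m.index]
    if missing:
        raise ValidationError(f"samples absent from manifest: {missing}")
    dates = pd.Series(m.loc[table.sample_ids, "date"].values, index=table.counts.index)
    mol = pd.Series(m.loc[table.sample_ids, "molecule"].values, index=table.counts.index)
    return OtuTable(table.counts, dates, mol)


def read_taxonomy(path) -> TaxonomyMap:
    """Read the taxonomy TSV (otu_id, supergroup, group, closest_relative,
    pct_identity). Unknown supergroups collapse to ``unclassified`` with a
    logged warning; ``is_metazoa`` is derived from the supergroup."""
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty taxonomy table: {path}") from exc
    required = ["otu_id", "supergroup", "group", "closest_relative", "pct_identity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"taxonomy table missing columns: {missing}")
    df = df.set_index("otu_id")
    return TaxonomyMap(df[required[1:]].copy())


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    cols = ["supergroup", "group", "closest_relative", "pct_identity"]
    tax.table[cols].to_csv(path, sep="\t", index_label="otu_id")


def read_manifest(path) -> pd.DataFrame:
    """Read the sample manifest (library_id, date, molecule, pair_id)."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={"library_id": str, "pair_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty manifest: {path}") from exc
    required = ["library_id", "date", "molecule", "pair_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    validate_manifest(df)
    return df


def validate_manifest(df: pd.DataFrame) -> None:
    bad = set(df["molecule"].unique()) - set(MOLECULES)
    if bad:
        raise ValidationError(f"unknown molecule labels in manifest: {sorted(bad)}")
    if df["library_id"].duplicated().any():
        raise ValidationError("duplicate library_id in manifest")
    counts = df.groupby(["pair_id", "molecule"]).size()
    if (counts > 1).any():
        offenders = counts[counts > 1].index.get_level_values(0).unique().tolist()
        raise ValidationError(f"pair_id maps to two libraries of the same molecule: {offenders}")
    for mol, sub in df.groupby("molecule"):
        if sub["date"].duplicated().any():
            raise ValidationError(f"duplicate dates within molecule {mol}")


def write_manifest(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False)


#: Environmental variables allowed to be negative (temperature in Celsius;
#: pH never is but is not a concentration; PCA scores handled elsewhere).
_SIGNED_ENV = {"T"}


def read_env_table(path) -> pd.DataFrame:
    """Read the environmental table (date-indexed, numeric columns).

    Missing values stay as NA; they are never imputed here. Concentrations
    and coefficients must be non-negative where present.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty environmental table: {path}") from exc
    if "date" not in df.columns:
        raise FormatError("environmental table needs a 'date' column")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    df = df.set_index("date")
    df = df.apply(pd.to_numeric)
    arr = df.to_numpy(dtype=float)
    if arr.size and np.isinf(arr).any():
        raise ValidationError("non-finite environmental value")
    for col in df.columns:
        if col in _SIGNED_ENV:
            continue
        v = df[col].dropna()
        if len(v) and (v < 0).any():
            raise ValidationError(f"negative value in environmental variable {col!r}")
    return df


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------


def pair_libraries(
    manifest: pd.DataFrame, dna: OtuTable, rna: OtuTable
) -> PairedLibraries:
    """Resolve date-matched rDNA/rRNA library pairs against two tables.

    Returns the list of (date, dna_sample, rna_sample) pairs whose two
    libraries are both present, plus the ids of unpaired libraries.
    """
    validate_manifest(manifest)
    dna_ids = set(dna.sample_ids)
    rna_ids = set(rna.sample_ids)
    pairs: list[tuple[object, str, str]] = []
    unpaired: list[str] = []
    for pair_id, sub in manifest.groupby("pair_id", sort=True):
        d = sub[sub["molecule"] == "rDNA"]
        r = sub[sub["molecule"] == "rRNA"]
        d_id = d["library_id"].iloc[0] if len(d) else None
        r_id = r["library_id"].iloc[0] if len(r) else None
        if d_id is not None and d_id not in dna_ids:
            d_id = None
        if r_id is not None and r_id not in rna_ids:
            r_id = None
        if d_id is not None and r_id is not None:
            pairs.append((sub["date"].iloc[0], d_id, r_id))
        else:
            unpaired.extend(x for x in (d_id, r_id) if x is not None)
    pairs.sort(key=lambda t: (pd.Timestamp(t[0]), t[1]))
    return PairedLibraries(pairs=pairs, unpaired=unpaired)
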