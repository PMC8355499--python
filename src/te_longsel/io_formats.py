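"""Typed readers and writers for every external table the pipeline touches.

All tables are UTF-8, tab-separated text.  Coordinates are 1-based and
inclusive everywhere in the package (:data:`COORDINATE_BASE`).  Missing
frequencies are written as the literal token ``NA`` (never ``.``).

The dialects are owned by this package rather than copied bit-for-bit from
the upstream tools whose output surfaces they model (per-position normalized
TE coverage in the style of DeviaTE, genomic insertion/frequency tables in
the style of PoPoolationTE2):

* coverage table columns: ``family``, ``sample``, ``pos``, ``insertions``
* insertion table columns: ``chrom``, ``pos``, ``family``, then one
  ``freq_<sample>`` column per declared population sample
* hierarchy table columns: ``name``, ``subclass``, ``class``, ``length``
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: All genomic and consensus coordinates in this package are 1-based,
#: inclusive at both ends.
COORDINATE_BASE = 1

#: Token used for a missing frequency in insertion tables.
NA_TOKEN = "NA"

SUBCLASSES = ("LTR", "non-LTR", "TIR", "other")
CLASSES = ("RNA", "DNA")

#: Subclasses that imply a class.  LTR/non-LTR retrotransposons replicate
#: through an RNA intermediate; TIR elements are cut-and-paste DNA
#: transposons.
_SUBCLASS_CLASS = {"LTR": "RNA", "non-LTR": "RNA", "TIR": "DNA"}


class TableFormatError(ValueError):
    """A file violated the package's table dialect or an invariant."""


@dataclass(frozen=True)
class TEFamily:
    """One transposable-element family of the consensus library.

    Parameters
    ----------
    name
        Unique family identifier (e.g. ``HeT-A``, ``copia``).
    subclass
        ``LTR``, ``non-LTR``, ``TIR`` or ``other``.
    te_class
        ``RNA`` or ``DNA``; must be consistent with the subclass.
    consensus_length
        Length of the consensus sequence in bp (> 0).
    """

    name: str
    subclass: str
    te_class: str
    consensus_length: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("family name must be nonempty")
        if self.subclass not in SUBCLASSES:
            raise ValueError(f"unknown subclass {self.subclass!r} for {self.name}")
        if self.te_class not in CLASSES:
            raise ValueError(f"unknown class {self.te_class!r} for {self.name}")
        implied = _SUBCLASS_CLASS.get(self.subclass)
        if implied is not None and implied != self.te_class:
            raise ValueError(
                f"family {self.name}: subclass {self.subclass} implies class "
                f"{implied}, got {self.te_class}"
            )
        if self.consensus_length <= 0:
            raise ValueError(f"family {self.name}: consensus_length must be > 0")


@dataclass(frozen=True)
class GeneInterval:
    """A gene span with 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError("chromosome must be nonempty")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")


@dataclass
class CoverageProfile:
    """Per-position normalized TE coverage: insertions per haploid genome.

    ``data`` holds one row per (family, sample, consensus position) with the
    normalized insertion estimate at that position.  Every referenced family
    must be declared in ``hierarchy``.
    """

    data: pd.DataFrame
    hierarchy: Mapping[str, TEFamily] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["family", "sample", "pos", "insertions"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"coverage table missing columns {missing}")
        df = self.data
        if (df["pos"] < COORDINATE_BASE).any():
            bad = df.index[df["pos"] < COORDINATE_BASE][0]
            raise TableFormatError(
                f"row {bad}: position must be >= {COORDINATE_BASE} (1-based)"
            )
        if (df["insertions"] < 0).any():
            bad = df.index[df["insertions"] < 0][0]
            raise TableFormatError(f"row {bad}: negative insertion estimate")
        if self.hierarchy:
            unknown = set(df["family"]) - set(self.hierarchy)
            if unknown:
                raise TableFormatError(
                    f"families not in hierarchy: {sorted(unknown)}"
                )
            for fam, sub in df.groupby("family", observed=True):
                length = self.hierarchy[fam].consensus_length
                if (sub["pos"] > length).any():
                    raise TableFormatError(
                        f"family {fam}: position beyond consensus length {length}"
                    )

    @property
    def families(self) -> list[str]:
        return sorted(self.data["family"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    def for_family(self, family: str) -> pd.DataFrame:
        return self.data[self.data["family"] == family]


@dataclass
class InsertionSiteTable:
    """Genomic TE insertion sites with per-population frequencies.

    ``data`` has columns ``chrom``, ``pos``, ``family`` and one
    ``freq_<sample>`` column per population; frequencies are in [0, 1] with
    NaN marking a site not observed in that population.
    """

    data: pd.DataFrame
    sample_names: Sequence[str]

    def __post_init__(self) -> None:
        for col in ("chrom", "pos", "family"):
            if col not in self.data.columns:
                raise TableFormatError(f"insertion table missing column {col!r}")
        for s in self.sample_names:
            col = f"freq_{s}"
            if col not in self.data.columns:
                raise TableFormatError(f"insertion table missing column {col!r}")
            vals = self.data[col]
            bad = vals.notna() & ((vals < 0) | (vals > 1))
            if bad.any():
                raise TableFormatError(
                    f"row {vals.index[bad][0]}: frequency outside [0, 1]"
                )
        if (self.data["pos"] < COORDINATE_BASE).any():
            raise TableFormatError(f"position must be >= {COORDINATE_BASE}")
        dup = self.data.duplicated(subset=["chrom", "pos", "family"])
        if dup.any():
            key = self.data.loc[dup.idxmax(), ["chrom", "pos", "family"]]
            raise TableFormatError(
                f"duplicate site ({key['chrom']}, {key['pos']}, {key['family']})"
            )

    @property
    def freq_columns(self) -> list[str]:
        return [f"freq_{s}" for s in self.sample_names]

    def frequencies(self) -> pd.DataFrame:
        """Frequency block indexed like ``data``, columns named by sample."""
        block = self.data[self.freq_columns].copy()
        block.columns = list(self.sample_names)
        return block


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"family": str}, na_values=[NA_TOKEN],
                         keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableFormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: header missing columns {missing}")
    return df


def read_te_hierarchy(path) -> list[TEFamily]:
    """Read a family -> subclass/class/length hierarchy table."""
    df = _read_tsv(path, ["name", "subclass", "class", "length"])
    families: list[TEFamily] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        if row["name"] in seen:
            raise TableFormatError(f"{path} line {i + 2}: duplicate family {row['name']!r}")
        seen.add(row["name"])
        try:
            families.append(
                TEFamily(
                    name=str(row["name"]),
                    subclass=str(row["subclass"]),
                    te_class=str(row["class"]),
                    consensus_length=int(row["length"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path} line {i + 2}: {exc}") from exc
    return families


def write_te_hierarchy(families: Iterable[TEFamily], path) -> None:
    records = [
        {"name": f.name, "subclass": f.subclass, "class": f.te_class,
         "length": f.consensus_length}
        for f in families
    ]
    write_results_table(records, path, sort_by=["name"])


def read_coverage_table(path, hierarchy: Iterable[TEFamily]) -> CoverageProfile:
    """Read a per-position normalized coverage table.

    Rows referring to families absent from ``hierarchy`` raise an error
    naming them; malformed numeric fields raise an error naming the line.
    """
    df = _read_tsv(path, ["family", "sample", "pos", "insertions"])
    for col, caster in (("pos", int), ("insertions", float)):
        try:
            df[col] = df[col].astype(caster)
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}: malformed {col!r} column: {exc}") from exc
    if (df["pos"] < COORDINATE_BASE).any():
        line = int(df.index[df["pos"] < COORDINATE_BASE][0]) + 2
        raise TableFormatError(f"{path} line {line}: position must be >= 1")
    if (df["insertions"] < 0).any():
        line = int(df.index[df["insertions"] < 0][0]) + 2
        raise TableFormatError(f"{path} line {line}: negative insertion estimate")
    hier = {f.name: f for f in hierarchy}
    unknown = sorted(set(df["family"]) - set(hier))
    if unknown:
        raise TableFormatError(f"{path}: families not in hierarchy: {unknown}")
    return CoverageProfile(data=df.reset_index(drop=True), hierarchy=hier)


def write_coverage_table(profile: CoverageProfile, path) -> None:
    write_results_table(profile.data, path, sort_by=["family", "sample", "pos"])


def read_insertion_table(path, samples: Sequence[str]) -> InsertionSiteTable:
    """Read an insertion site table with one ``freq_<sample>`` column per
    declared population sample."""
    cols = ["chrom", "pos", "family"] + [f"freq_{s}" for s in samples]
    df = _read_tsv(path, cols)
    try:
        df["pos"] = df["pos"].astype(int)
        for s in samples:
            df[f"freq_{s}"] = df[f"freq_{s}"].astype(float)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"{path}: malformed numeric column: {exc}") from exc
    return InsertionSiteTable(data=df.reset_index(drop=True), sample_names=list(samples))


def write_insertion_table(table: InsertionSiteTable, path) -> None:
    write_results_table(table.data, path, sort_by=["chrom", "pos", "family"])


def read_gene_intervals(path) -> list[GeneInterval]:
    """Read gene features from a GFF3 file (1-based inclusive, per standard).

    Only rows of feature type ``gene`` are used; the number of skipped
    non-gene rows is logged.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneInterval] = []
    skipped = 0
    for feat in db.all_features():
        if feat.featuretype != "gene":
            skipped += 1
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneInterval(
                gene_id=gene_id,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    if skipped:
        logger.info("read_gene_intervals: skipped %d non-gene feature rows", skipped)
    return genes


def write_gene_intervals(genes: Iterable[GeneInterval], path) -> None:
    """Write genes as a minimal GFF3 file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            fh.write(
                f"{g.chromosome}\tte_longsel\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_results_table(records, path, sort_by: Sequence[str] | None = None) -> None:
    """Write homogeneous records as a TSV with a header.

    Floats are formatted to 6 significant digits; row order is deterministic
    (sorted by ``sort_by``, defaulting to all non-float columns in order).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if records and not all(set(r) == set(records[0]) for r in records):
            raise TableFormatError("records are not homogeneous")
        df = pd.DataFrame(records)
    if sort_by is None:
        sort_by = [c for c in df.columns
                   if not pd.api.types.is_float_dtype(df[c])]
    if sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort")
    def _fmt(v):
        if isinstance(v, (float, np.floating)):
            return NA_TOKEN if math.isnan(v) else f"{v:.6g}"
        return v
    out = df.map(_fmt)
    out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)
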