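"""Readers, writers and validated in-memory containers.

All external representations are plain text: TSV for count matrices, insertion
tables, location tables and growth curves; GFF3 or TSV for gene annotation;
CSV for re-array (pipetting) plans; FASTQ for raw barcode amplicon reads.
Coordinates are 1-based inclusive everywhere (the GFF3 convention); tables are
tab-separated UTF-8 with ``#`` comment lines permitted.
"""

from __future__ import annotations

import csv
import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import PlanError, ValidationError
from .layout import WELL_POSITIONS, PoolLayout, well_index

_BARCODE_RE = re.compile(r"^[ACGT]+$")

LOCATION_STATUSES = ("definite", "high_confidence", "ambiguous", "absent")


# ---------------------------------------------------------------------------
# Contigs and gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contig:
    name: str
    length: int
    is_plasmid: bool = False


@dataclass(frozen=True)
class ContigRegistry:
    """Registry of replicons; distinguishes chromosome from plasmid/vector.

    Whether a contig counts as "plasmid/vector" (so that insertions on it mark
    a strain as *integrated*) is an explicit attribute here, never inferred
    from contig names.
    """

    contigs: tuple[Contig, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate contig names in registry")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.contigs)

    def __getitem__(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.contigs if not c.is_plasmid)

    @property
    def plasmids(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.contigs if c.is_plasmid)


@dataclass
class GeneAnnotation:
    """Gene coordinates, 1-based inclusive, used for coverage calling."""

    genes: pd.DataFrame  # columns: gene_id, contig, start, end, strand

    COLUMNS = ("gene_id", "contig", "start", "end", "strand")

    def __post_init__(self) -> None:
        df = self.genes.reset_index(drop=True)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] > df["end"]).any():
            bad = df.loc[df["start"] > df["end"], "gene_id"].iloc[0]
            raise ValidationError(f"gene {bad!r} has start > end")
        if (df["start"] < 1).any():
            raise ValidationError("gene coordinates must be 1-based (start >= 1)")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValidationError("gene strand must be '+' or '-'")
        self.genes = df

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene_id"].tolist()


def read_gene_annotation(path: str | Path, format: str = "auto") -> GeneAnnotation:
    """Read gene coordinates from GFF3 or a 5-column TSV.

    GFF3 coordinates are taken as 1-based inclusive per the standard, so both
    formats yield identical annotations for the same genes.
    """
    path = Path(path)
    if format == "auto":
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "tsv"
    if format == "gff3":
        return _read_annotation_gff3(path)
    if format == "tsv":
        df = _read_tsv(path)
        return GeneAnnotation(df)
    raise ValidationError(f"unknown annotation format: {format!r}")


def _read_annotation_gff3(path: Path) -> GeneAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        rows.append(
            {
                "gene_id": feat.id,
                "contig": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand if feat.strand in "+-" else "+",
            }
        )
    if not rows:
        raise ValidationError(f"no gene features in {path}")
    return GeneAnnotation(pd.DataFrame(rows))


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.genes.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Insertion tables
# ---------------------------------------------------------------------------

@dataclass
class InsertionTable:
    """Per-barcode transposon insertion sites with supporting read counts.

    ``position`` is the single 1-based junction coordinate of the insertion;
    strand is recorded but not used by the coverage rules.
    """

    records: pd.DataFrame  # columns: barcode, contig, position, strand, reads
    contigs: ContigRegistry

    COLUMNS = ("barcode", "contig", "position", "strand", "reads")

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"insertion table missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["position"] = df["position"].astype(int)
        df["reads"] = df["reads"].astype(int)
        if len(df):
            _validate_barcodes(df["barcode"])
            if (df["reads"] < 1).any():
                raise ValidationError("insertion read counts must be >= 1")
            if not df["strand"].isin(["+", "-"]).all():
                raise ValidationError("insertion strand must be '+' or '-'")
            for contig, sub in df.groupby("contig", sort=False):
                if contig not in self.contigs:
                    raise ValidationError(f"unregistered contig: {contig!r}")
                length = self.contigs[str(contig)].length
                pos = sub["position"]
                if (pos < 1).any() or (pos > length).any():
                    bad = pos[(pos < 1) | (pos > length)].iloc[0]
                    raise ValidationError(
                        f"position {bad} outside contig {contig!r} (length {length})"
                    )
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def barcodes(self) -> list[str]:
        return self.records["barcode"].drop_duplicates().tolist()


def read_insertion_table(path: str | Path, contigs: ContigRegistry) -> InsertionTable:
    return InsertionTable(_read_tsv(path), contigs)


def write_insertion_table(table: InsertionTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BarSeq count matrices
# ---------------------------------------------------------------------------

@dataclass
class BarSeqMatrix:
    """Read counts per (barcode, pool) for a plate-well pooled collection.

    Columns are ordered plate pools first (layout order) then well pools in
    row-major well order, so the two pooling axes can be sliced directly.
    """

    barcodes: list[str]
    layout: PoolLayout
    counts: np.ndarray  # shape (n_barcodes, n_plates + 96), non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.barcodes), self.layout.n_pools):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {self.layout.n_pools} pools"
            )
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count for barcode {self.barcodes[i]!r} "
                f"in pool {self.layout.pool_ids[j]!r}"
            )
        _validate_barcodes(pd.Series(self.barcodes))
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("duplicate barcode rows")
        self.counts = counts.astype(np.int64)

    @property
    def pool_totals(self) -> np.ndarray:
        """Per-pool total reads (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def plate_counts(self) -> np.ndarray:
        """View of the plate-pool columns, shape (n_barcodes, n_plates)."""
        return self.counts[:, : self.layout.n_plates]

    @property
    def well_counts(self) -> np.ndarray:
        """View of the well-pool columns, shape (n_barcodes, 96)."""
        return self.counts[:, self.layout.n_plates:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.barcodes, name="barcode"),
            columns=list(self.layout.pool_ids),
        )


def read_barseq_counts(path: str | Path, layout: PoolLayout) -> BarSeqMatrix:
    """Read a barcode x pool TSV whose header names must match the layout."""
    df = _read_tsv(path)
    if df.columns[0] != "barcode":
        raise ValidationError("first column of a BarSeq table must be 'barcode'")
    file_pools = list(df.columns[1:])
    expected = set(layout.pool_ids)
    unknown = [p for p in file_pools if p not in expected]
    if unknown:
        raise ValidationError(f"unknown pool columns: {unknown}")
    missing = [p for p in layout.pool_ids if p not in file_pools]
    if missing:
        raise ValidationError(f"missing pool columns: {missing}")
    df = df.set_index("barcode")
    counts = df.loc[:, list(layout.pool_ids)]
    bad = counts.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        row = bad.index[bad.isna().any(axis=1)][0]
        raise ValidationError(f"non-numeric count in row {row!r}")
    arr = bad.to_numpy()
    if (arr < 0).any():
        row = bad.index[(arr < 0).any(axis=1)][0]
        raise ValidationError(f"negative count in row {row!r}")
    return BarSeqMatrix(list(df.index), layout, arr.astype(np.int64))


def write_barseq_counts(matrix: BarSeqMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Location tables
# ---------------------------------------------------------------------------

@dataclass
class LocationTable:
    """Per-barcode placement within the collection with decode confidence.

    One row per (barcode, candidate well).  Definite barcodes carry
    confidence 1.0; ambiguous barcodes keep every candidate well with its
    marginal posterior so the re-array planner can transfer them; absent
    barcodes have no well (NA plate/well).
    """

    records: pd.DataFrame  # columns: barcode, plate, well, confidence, status

    COLUMNS = ("barcode", "plate", "well", "confidence", "status")

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"location table missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        if len(df):
            if not df["status"].isin(LOCATION_STATUSES).all():
                bad = df.loc[~df["status"].isin(LOCATION_STATUSES), "status"].iloc[0]
                raise ValidationError(f"unknown decode status: {bad!r}")
            placed = df["status"] != "absent"
            conf = df.loc[placed, "confidence"].astype(float)
            if ((conf < 0) | (conf > 1 + 1e-12)).any():
                raise ValidationError("confidence must lie in [0, 1]")
            if (df.loc[df["status"] == "definite", "confidence"] != 1.0).any():
                raise ValidationError("definite placements must have confidence 1")
            for w in df.loc[placed, "well"]:
                well_index(str(w))
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def located(self) -> pd.DataFrame:
        """Rows with a trusted placement (definite or high-confidence)."""
        return self.records[self.records["status"].isin(["definite", "high_confidence"])]


def read_location_table(path: str | Path) -> LocationTable:
    df = _read_tsv(path)
    df["plate"] = df["plate"].astype("Int64")
    return LocationTable(df)


def write_location_table(table: LocationTable, path: str | Path) -> None:
    out = table.records.copy()
    out["confidence"] = out["confidence"].map(
        lambda v: "" if pd.isna(v) else f"{float(v):.6g}"
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Re-array plans
# ---------------------------------------------------------------------------

REARRAY_COLUMNS = (
    "gene_id", "source_plate", "source_well",
    "dest_plate", "dest_well", "reason",
)
REARRAY_REASONS = ("representative", "ambiguous_candidate", "correction")


def validate_rearray_plan(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(REARRAY_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"re-array plan missing columns: {sorted(missing)}")
    df = records.loc[:, list(REARRAY_COLUMNS)].reset_index(drop=True).copy()
    if len(df):
        if not df["reason"].isin(REARRAY_REASONS).all():
            raise ValidationError("unknown selection reason in re-array plan")
        dest = df[["dest_plate", "dest_well"]].apply(tuple, axis=1)
        if dest.duplicated().any():
            clash = dest[dest.duplicated()].iloc[0]
            raise PlanError(f"destination collision at plate {clash[0]} well {clash[1]}")
        for w in pd.concat([df["source_well"], df["dest_well"]]):
            well_index(str(w))
    return df


def write_rearray_plan(records: pd.DataFrame, path: str | Path) -> None:
    """Write the pipetting pattern as CSV (liquid-handler import format)."""
    df = validate_rearray_plan(records)
    df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def read_rearray_plan(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"source_plate": int, "dest_plate": int})
    return validate_rearray_plan(df)


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

@dataclass
class GrowthCurve:
    plate: str
    well: str
    strain: str  # mutant id, wild-type control label, or "blank"
    time_h: np.ndarray
    od600: np.ndarray
    blank: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.shape != od.shape or t.ndim != 1:
            raise ValidationError("time and OD vectors must be equal-length 1-D")
        if len(t) and (np.diff(t) <= 0).any():
            raise ValidationError("time points must be strictly increasing")
        self.time_h, self.od600 = t, od


@dataclass
class GrowthCurveSet:
    curves: list[GrowthCurve]

    def __len__(self) -> int:
        return len(self.curves)

    def by_strain(self, label: str) -> list[GrowthCurve]:
        return [c for c in self.curves if c.strain == label]


def read_growth_curves(path: str | Path) -> GrowthCurveSet:
    """Read long-format plate-reader TSV: plate, well, strain, time_h, od600
    and optionally a per-well ``blank`` column."""
    df = _read_tsv(path)
    required = {"plate", "well", "strain", "time_h", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"growth table missing columns: {sorted(missing)}")
    curves = []
    for (plate, well), sub in df.groupby(["plate", "well"], sort=False):
        sub = sub.sort_values("time_h")
        strains = sub["strain"].unique()
        if len(strains) != 1:
            raise ValidationError(f"well {plate}/{well} has multiple strain labels")
        blank = float(sub["blank"].iloc[0]) if "blank" in sub.columns else 0.0
        curves.append(
            GrowthCurve(
                str(plate), str(well), str(strains[0]),
                sub["time_h"].to_numpy(float), sub["od600"].to_numpy(float),
                blank,
            )
        )
    return GrowthCurveSet(curves)


def write_growth_curves(curves: GrowthCurveSet, path: str | Path) -> None:
    rows = []
    for c in curves.curves:
        for t, od in zip(c.time_h, c.od600):
            rows.append((c.plate, c.well, c.strain, t, od, c.blank))
    pd.DataFrame(
        rows, columns=["plate", "well", "strain", "time_h", "od600", "blank"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ barcode counting
# ---------------------------------------------------------------------------

def count_barcodes_from_reads(
    path: str | Path,
    left_flank: str,
    right_flank: str,
    barcode_length: int,
) -> tuple[dict[str, int], float]:
    """Count barcodes between exact-match flanks in FASTQ reads.

    A read contributes iff it contains ``left_flank`` followed by exactly
    ``barcode_length`` bases followed by ``right_flank``.  No error
    correction or off-by-one clustering is attempted.  Returns the count map
    and the fraction of reads successfully parsed.
    """
    from Bio import SeqIO

    counts: dict[str, int] = {}
    n_total = n_parsed = 0
    for rec in SeqIO.parse(str(path), "fastq"):
        n_total += 1
        seq = str(rec.seq)
        start = seq.find(left_flank)
        if start < 0:
            continue
        bc_start = start + len(left_flank)
        bc_end = bc_start + barcode_length
        if seq[bc_end : bc_end + len(right_flank)] != right_flank:
            continue
        barcode = seq[bc_start:bc_end]
        if len(barcode) == barcode_length and _BARCODE_RE.match(barcode):
            counts[barcode] = counts.get(barcode, 0) + 1
            n_parsed += 1
    frac = n_parsed / n_total if n_total else 0.0
    return counts, frac


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype={"barcode": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc


def _validate_barcodes(series: pd.Series) -> None:
    if not len(series):
        return
    bad = series[~series.astype(str).str.match(_BARCODE_RE)]
    if len(bad):
        raise ValidationError(f"malformed barcode: {bad.iloc[0]!r}")
    lengths = series.astype(str).str.len()
    if lengths.nunique() > 1:
        raise ValidationError("barcodes must all share one fixed length")
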