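"""Gene coverage calling and re-array planning for a condensed collection.

An insertion disrupts a gene only if it falls in the middle 85 % of the open
reading frame — after the first 5 % and before the last 10 % — since very
early or very late insertions often leave a functional product.  With the
relative position f = (position - start) / gene length (measured from the
start codon regardless of strand), the eligibility band is 0.05 <= f < 0.90,
which on an integer coordinate grid contains exactly 85 % of positions.

For each covered gene, the re-array plan picks the single-insertion strain
whose insertion lies closest to the middle of the ORF.  Genes whose only
candidates decode ambiguously get all candidate wells from one source plate
transferred (the plate carrying the greatest posterior mass), to be resolved
by a quality-check sequencing round on the condensed collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .decode import DecodeResults
from .errors import PlanError
from .io import GeneAnnotation, InsertionTable, LocationTable, validate_rearray_plan
from .layout import WELL_POSITIONS, well_index

ELIGIBLE_LOW = 0.05
ELIGIBLE_HIGH = 0.90
DEFAULT_BLANK_WELLS = ("A1", "B1", "H12")


def relative_position(position: int, start: int, end: int, strand: str) -> float:
    """Relative position of an insertion in a gene, 0 at the start codon.

    ``(position - start) / length`` on the + strand and
    ``(end - position) / length`` on the - strand, with
    length = end - start + 1; always in [0, 1).
    """
    length = end - start + 1
    if strand == "-":
        return (end - position) / length
    return (position - start) / length


def is_eligible(fraction: float) -> bool:
    """Middle-85 % rule: after the first 5 % and before the last 10 %."""
    return ELIGIBLE_LOW <= fraction < ELIGIBLE_HIGH


def _gene_trees(annotation: GeneAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in annotation.genes.itertuples(index=False):
        # interval tree is half-open; genes are 1-based inclusive
        trees.setdefault(row.contig, IntervalTree()).addi(
            row.start, row.end + 1, (row.gene_id, row.start, row.end, row.strand)
        )
    return trees


def gene_hits(
    insertions: InsertionTable,
    annotation: GeneAnnotation,
    barcodes: set[str] | None = None,
) -> pd.DataFrame:
    """All (gene, barcode) hits with relative positions and eligibility.

    Insertions outside every gene produce no hit.  ``barcodes`` restricts
    the insertion table (typically to single-insertion barcodes).
    """
    trees = _gene_trees(annotation)
    df = insertions.records
    if barcodes is not None:
        df = df[df["barcode"].isin(barcodes)]
    rows = []
    for rec in df.itertuples(index=False):
        tree = trees.get(rec.contig)
        if tree is None:
            continue
        for iv in tree.at(rec.position):
            gene_id, start, end, strand = iv.data
            f = relative_position(rec.position, start, end, strand)
            rows.append((gene_id, rec.barcode, rec.position, f, is_eligible(f)))
    return pd.DataFrame(
        rows, columns=["gene_id", "barcode", "position", "fraction", "eligible"]
    )


def gene_coverage(
    barcodes: set[str],
    insertions: InsertionTable,
    annotation: GeneAnnotation,
) -> set[str]:
    """Genes disrupted by >= 1 eligible insertion from the given barcodes."""
    hits = gene_hits(insertions, annotation, barcodes)
    if not len(hits):
        return set()
    return set(hits.loc[hits["eligible"], "gene_id"])


def select_representative(candidates: pd.DataFrame) -> pd.Series:
    """Choose the candidate closest to the middle of the ORF.

    ``candidates`` needs columns fraction, plate, well.  Ties on
    |fraction - 0.5| break deterministically by lower plate index, then
    row-major well order.
    """
    if not len(candidates):
        raise PlanError("no eligible candidate to select from")
    ranked = candidates.assign(
        _dist=(candidates["fraction"] - 0.5).abs(),
        _widx=candidates["well"].map(well_index),
    ).sort_values(["_dist", "plate", "_widx"], kind="mergesort")
    return ranked.iloc[0].drop(["_dist", "_widx"])


@dataclass
class RearrayPlan:
    """Pipetting plan plus the coverage report it implies."""

    records: pd.DataFrame  # REARRAY_COLUMNS
    multi_only_genes: list[str]  # covered only by multi-insertion strains
    uncovered_genes: list[str]

    def __post_init__(self) -> None:
        self.records = validate_rearray_plan(self.records)

    @property
    def n_dest_plates(self) -> int:
        return int(self.records["dest_plate"].max()) if len(self.records) else 0


def plan_rearray(
    decode_results: DecodeResults,
    barcode_statuses: pd.DataFrame,
    insertions: InsertionTable,
    annotation: GeneAnnotation,
    *,
    blank_wells: tuple[str, ...] = DEFAULT_BLANK_WELLS,
    max_dest_plates: int | None = None,
) -> RearrayPlan:
    """Plan the condensed collection.

    For every gene with a located (definite / high-confidence)
    single-insertion candidate, one representative is transferred.  Genes
    whose only eligible candidates decode ambiguously get all candidate wells
    of the highest-posterior-mass plate transferred.  Destination wells fill
    row-major, skipping reserved blank/control positions.
    """
    locations = decode_results.location_table
    single_bcs = set(
        barcode_statuses.loc[barcode_statuses["status"] == "single", "barcode"]
    )
    hits = gene_hits(insertions, annotation, single_bcs)
    eligible = hits[hits["eligible"]] if len(hits) else hits

    located = locations.located()
    # barcodes co-resident with another located barcode are multi-barcode
    # multi-insertion strains (or contamination): never representatives
    occupancy = located.groupby(["plate", "well"])["barcode"].transform("size")
    located = located[occupancy == 1]
    located_wells = located.groupby("barcode")[["plate", "well"]].first()

    ambiguous = locations.records[locations.records["status"] == "ambiguous"]
    ambiguous_bcs = set(ambiguous["barcode"])

    dest_positions = [w for w in WELL_POSITIONS if w not in set(blank_wells)]
    per_plate = len(dest_positions)

    assignments: list[tuple[str, int, str, str]] = []  # gene, src plate, src well, reason
    multi_only: list[str] = []
    uncovered: list[str] = []

    multi_bcs = set(
        barcode_statuses.loc[barcode_statuses["status"] == "multi_site", "barcode"]
    )
    multi_hits = gene_hits(insertions, annotation, multi_bcs)
    multi_covered = (
        set(multi_hits.loc[multi_hits["eligible"], "gene_id"])
        if len(multi_hits) else set()
    )

    for gene_id in annotation.gene_ids:
        gene_elig = eligible[eligible["gene_id"] == gene_id] if len(eligible) else eligible
        located_cand = (
            gene_elig[gene_elig["barcode"].isin(located_wells.index)]
            if len(gene_elig) else gene_elig
        )
        if len(located_cand):
            cand = located_cand.merge(
                located_wells, left_on="barcode", right_index=True
            )
            chosen = select_representative(cand[["fraction", "plate", "well", "barcode"]])
            assignments.append(
                (gene_id, int(chosen["plate"]), str(chosen["well"]), "representative")
            )
            continue
        amb_cand = (
            gene_elig[gene_elig["barcode"].isin(ambiguous_bcs)]
            if len(gene_elig) else gene_elig
        )
        if len(amb_cand):
            # pick the ambiguous barcode whose insertion is most central
            bc = amb_cand.assign(_d=(amb_cand["fraction"] - 0.5).abs()) \
                         .sort_values("_d", kind="mergesort")["barcode"].iloc[0]
            mass = decode_results.plate_posterior_mass(bc)
            bc_rows = ambiguous[ambiguous["barcode"] == bc]
            if mass:
                src_plate = max(sorted(mass), key=lambda p: mass[p])
            else:  # unscored (n > max_n): fall back to the lowest plate
                src_plate = int(bc_rows["plate"].min())
            for w in sorted(
                bc_rows.loc[bc_rows["plate"] == src_plate, "well"], key=well_index
            ):
                assignments.append((gene_id, src_plate, str(w), "ambiguous_candidate"))
            continue
        if gene_id in multi_covered:
            multi_only.append(gene_id)
        else:
            uncovered.append(gene_id)

    rows = []
    for k, (gene_id, src_plate, src_well, reason) in enumerate(assignments):
        dest_plate = k // per_plate + 1
        dest_well = dest_positions[k % per_plate]
        rows.append((gene_id, src_plate, src_well, dest_plate, dest_well, reason))
    records = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "source_plate", "source_well",
            "dest_plate", "dest_well", "reason",
        ],
    )
    if max_dest_plates is not None and len(records):
        needed = int(records["dest_plate"].max())
        if needed > max_dest_plates:
            raise PlanError(
                f"destination capacity exceeded: {needed} plates required, "
                f"{max_dest_plates} available"
            )
    return RearrayPlan(records, multi_only, uncovered)
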