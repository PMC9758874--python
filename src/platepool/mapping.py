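"""Insertion-site filtering and multi-insertion strain classification.

Two complementary signals identify multi-insertion strains in a barcoded
ordered collection:

* **single-barcode multi-insertion** — one barcode associated with more than
  one insertion site in the barcode->site lookup table (repeated transposon
  transfer from one donor, so the copies share a barcode);
* **multi-barcode multi-insertion** — two or more distinctly barcoded
  insertions located in the same well of the collection (transfer from
  multiple donors), detectable only through co-residency in the decoded
  location table, never from the lookup table itself.

Before classification, insertion sites are cleaned with the minority-site
rule: per barcode, a site is kept only if its read count exceeds 25 % of the
barcode's most abundant site (spurious minority sites arise from e.g. PCR
chimeras).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ContigRegistry, InsertionTable, LocationTable
from .layout import WELL_POSITIONS

BARCODE_STATUSES = ("single", "multi_site", "integrated", "unmapped")
WELL_CLASSES = (
    "empty", "single_insertion", "single_barcode_multi",
    "multi_barcode_multi", "integrated", "unmapped",
)


# ---------------------------------------------------------------------------
# site merging and the 25 % filter
# ---------------------------------------------------------------------------

def merge_nearby_sites(table: InsertionTable, window: int = 3) -> InsertionTable:
    """Merge sites within ``window`` bp on the same contig per barcode.

    Junction mapping can scatter reads of one physical insertion over a few
    adjacent coordinates; merged sites sum their reads and keep the position
    of the best-supported member.
    """
    df = table.records
    if not len(df):
        return table
    out = []
    for (bc, contig), sub in df.groupby(["barcode", "contig"], sort=False):
        sub = sub.sort_values("position")
        positions = sub["position"].to_numpy()
        # new group wherever the gap to the previous site exceeds the window
        group = np.concatenate([[0], (np.diff(positions) > window).cumsum()])
        for _, grp in sub.groupby(group, sort=False):
            best = grp.loc[grp["reads"].idxmax()]
            out.append(
                (bc, contig, int(best["position"]), best["strand"],
                 int(grp["reads"].sum()))
            )
    merged = pd.DataFrame(out, columns=list(InsertionTable.COLUMNS))
    return InsertionTable(merged, table.contigs)


def filter_insertion_sites(table: InsertionTable, threshold: float = 0.25) -> InsertionTable:
    """Keep, per barcode, only sites with reads > ``threshold`` x max site.

    The most abundant site always survives (ties at the maximum all survive).
    Idempotent, and monotone: raising the threshold never adds sites.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must lie in (0, 1]")
    df = table.records
    if not len(df):
        return table
    max_reads = df.groupby("barcode")["reads"].transform("max")
    keep = (df["reads"] > threshold * max_reads) | (df["reads"] == max_reads)
    return InsertionTable(df[keep].reset_index(drop=True), table.contigs)


# ---------------------------------------------------------------------------
# barcode classification
# ---------------------------------------------------------------------------

def classify_barcodes(
    filtered: InsertionTable,
    barcodes: list[str] | None = None,
) -> pd.DataFrame:
    """Status per barcode from its filtered sites.

    Precedence when site kinds mix: integrated > multi_site > single (any
    surviving site on a plasmid/vector contig marks the strain as carrying an
    integrated copy of the delivery vector).  Barcodes listed in ``barcodes``
    but absent from the table are ``unmapped``.

    Returns a DataFrame with columns barcode, status, n_sites.
    """
    registry = filtered.contigs
    plasmids = set(registry.plasmids)
    df = filtered.records
    rows = []
    seen = set()
    if len(df):
        for bc, sub in df.groupby("barcode", sort=False):
            seen.add(bc)
            on_plasmid = sub["contig"].isin(plasmids).any()
            if on_plasmid:
                status = "integrated"
            elif len(sub) > 1:
                status = "multi_site"
            else:
                status = "single"
            rows.append((bc, status, len(sub)))
    if barcodes is not None:
        for bc in barcodes:
            if bc not in seen:
                rows.append((bc, "unmapped", 0))
    return pd.DataFrame(rows, columns=["barcode", "status", "n_sites"])


# ---------------------------------------------------------------------------
# well classification
# ---------------------------------------------------------------------------

def classify_wells(
    locations: LocationTable,
    barcode_statuses: pd.DataFrame,
    n_plates: int,
) -> pd.DataFrame:
    """Classify every well of the collection from its located residents.

    A well with >= 2 located barcodes is ``multi_barcode_multi`` regardless of
    the residents' own statuses (co-residency implies a multi-insertion genome
    or contamination either way).  A well with one located barcode inherits
    that barcode's status; wells with no located barcode are ``empty``.

    Only trusted placements (definite / high-confidence) count as residency.
    Returns a DataFrame with columns plate, well, classification, barcodes.
    """
    status_of = dict(
        zip(barcode_statuses["barcode"], barcode_statuses["status"])
    )
    located = locations.located()
    residents: dict[tuple[int, str], list[str]] = {}
    for _, row in located.iterrows():
        residents.setdefault((int(row["plate"]), str(row["well"])), []).append(
            str(row["barcode"])
        )
    bc_to_well = {
        "single": "single_insertion",
        "multi_site": "single_barcode_multi",
        "integrated": "integrated",
        "unmapped": "unmapped",
    }
    rows = []
    for p in range(n_plates):
        for w in WELL_POSITIONS:
            bcs = residents.get((p, w), [])
            if len(bcs) == 0:
                cls = "empty"
            elif len(bcs) >= 2:
                cls = "multi_barcode_multi"
            else:
                cls = bc_to_well[status_of.get(bcs[0], "unmapped")]
            rows.append((p, w, cls, ";".join(sorted(bcs))))
    return pd.DataFrame(rows, columns=["plate", "well", "classification", "barcodes"])


# ---------------------------------------------------------------------------
# collection statistics and assembly efficiency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssemblyStats:
    """Summary statistics of an assembled collection.

    ``bpw_fractions[k]`` is the fraction of wells holding ``k`` located
    barcode bins; ``f_single`` the fraction of located barcode bins whose
    barcode maps to a single defined chromosomal site; ``K`` the assembly
    efficiency estimate P(bpw = 1) x f_single, i.e. the probability that a
    sorted well yields a barcode usable for a condensed collection.
    ``fraction_useful_wells`` is the direct estimate from well classification.
    """

    n_wells: int
    bpw_fractions: dict[int, float]
    f_single: float  # fraction of bins in bpw = 1 wells with a single site
    fraction_useful_wells: float

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValidationError("collection has zero wells")
        total = sum(self.bpw_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("bpw fractions must sum to 1")
        if not 0 <= self.f_single <= 1:
            raise ValidationError("f_single must lie in [0, 1]")

    @property
    def K(self) -> float:
        """Assembly efficiency: P(bpw = 1) x f_single."""
        return self.bpw_fractions.get(1, 0.0) * self.f_single

    @property
    def K_direct(self) -> float:
        """Direct estimator: fraction of wells classified single_insertion."""
        return self.fraction_useful_wells


def collection_stats(
    well_statuses: pd.DataFrame,
    barcode_statuses: pd.DataFrame,
) -> AssemblyStats:
    """Compute bpw distribution, f_single and the useful-well fraction.

    ``f_single`` follows the sequential filtering that defines a useful well:
    first the well must hold exactly one barcode bin, then that barcode must
    map to a single defined chromosomal site — so it is the single-site
    fraction among bins in bpw = 1 wells.  (The marginal single-site fraction
    over all bins is biased upward by multi-barcode strains, whose bins are
    individually single-site but always co-resident.)
    """
    n_wells = len(well_statuses)
    if n_wells == 0:
        raise ValidationError("collection has zero wells")
    bpw = well_statuses["barcodes"].map(lambda s: 0 if not s else s.count(";") + 1)
    bpw_fractions = (bpw.value_counts(normalize=True)).to_dict()
    bpw_fractions = {int(k): float(v) for k, v in bpw_fractions.items()}

    status_of = dict(zip(barcode_statuses["barcode"], barcode_statuses["status"]))
    solo_bins = well_statuses.loc[bpw == 1, "barcodes"]
    if len(solo_bins):
        singles = sum(status_of.get(bc) == "single" for bc in solo_bins)
        f_single = singles / len(solo_bins)
    else:
        f_single = 0.0

    useful = (well_statuses["classification"] == "single_insertion").mean()
    return AssemblyStats(
        n_wells=n_wells,
        bpw_fractions=bpw_fractions,
        f_single=float(f_single),
        fraction_useful_wells=float(useful),
    )
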