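"""Ground-truthed synthetic pools, sorted collections and sequencing data.

Emulates the statistical structure of a barcoded transposon mutant library
being arrayed into an ordered collection:

* an initial pool of barcoded strains with log-normally biased abundances and
  a configurable mixture of strain classes (single-insertion, single-barcode
  multi-insertion, multi-barcode multi-insertion, vector-integrated, and
  unmapped);
* single-cell sorting into 96-well plates with empty-well failures;
* plate-well pooling and BarSeq read counting with per-well culture-abundance
  variation and multinomial sampling noise;
* an RB-TnSeq-style site-read table with an optional minority-site "chimera"
  rate to exercise the 25 %-of-maximum site filter downstream.

All stages draw from sub-streams derived deterministically from one seed, so
every artifact is bit-reproducible.  With ``exact_counts=True`` the BarSeq
matrix holds expected (noise-free) counts instead of multinomial draws; the
per-well abundance variation is kept even then because it is the signal the
probabilistic decoder relies on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SimulationError
from .io import BarSeqMatrix, Contig, ContigRegistry, GeneAnnotation, InsertionTable
from .layout import WELL_POSITIONS, PoolLayout

STRAIN_CLASSES = (
    "single", "single_barcode_multi", "multi_barcode_multi", "integrated", "unmapped",
)

# fixed per-stage RNG sub-stream keys
_STAGES = {"genome": 0, "pool": 1, "sort": 2, "barseq": 3, "rbtnseq": 4}


@dataclass(frozen=True)
class SimParams:
    """Knobs of the synthetic study.

    Defaults emulate the statistical regime the pipeline is designed for:
    ~58 % single-insertion strains with single-barcode multi-insertion the
    most common defect class, a log-normally biased pool, and a few percent
    of sort failures.
    """

    seed: int
    n_genes: int = 200
    gene_length: int = 900
    intergenic_gap: int = 100
    n_strains: int = 1000
    abundance_sigma: float = 1.0
    p_sbmi: float = 0.20
    p_mbmi: float = 0.12
    p_integrated: float = 0.04
    p_unmapped: float = 0.06
    empty_well_p: float = 0.05
    reads_per_pool: int = 200_000
    well_noise_sigma: float = 0.5
    chimera_rate: float = 0.0
    chimera_rel_depth: float = 0.1
    barcode_length: int = 20
    barcodes_per_multi: int = 2
    insertions_per_sbmi: int = 2
    rbtnseq_total_reads: int = 1_000_000
    plasmid_length: int = 10_000
    exact_counts: bool = False

    def __post_init__(self) -> None:
        probs = (self.p_sbmi, self.p_mbmi, self.p_integrated, self.p_unmapped)
        if any(p < 0 or p > 1 for p in probs) or sum(probs) > 1:
            raise SimulationError("class probabilities must lie in [0,1] and sum <= 1")
        if self.empty_well_p < 0 or self.empty_well_p > 1:
            raise SimulationError("empty_well_p must lie in [0,1]")

    @property
    def p_single(self) -> float:
        return 1.0 - (self.p_sbmi + self.p_mbmi + self.p_integrated + self.p_unmapped)

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage sub-stream of the run's single seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGES[stage],))
        )


@dataclass(frozen=True)
class StrainTruth:
    strain_id: str
    barcodes: tuple[str, ...]
    # per barcode: tuple of (contig, position) insertion sites; empty for unmapped
    insertions: tuple[tuple[tuple[str, int], ...], ...]
    strain_class: str
    weight: float

    def __post_init__(self) -> None:
        if self.strain_class not in STRAIN_CLASSES:
            raise SimulationError(f"unknown strain class {self.strain_class!r}")
        if len(self.barcodes) != len(self.insertions):
            raise SimulationError("one insertion tuple required per barcode")


@dataclass
class CollectionTruth:
    """Ground-truth occupancy: each well holds at most one sorted strain."""

    n_plates: int
    occupants: dict[tuple[int, str], str]  # (plate index 0-based, well) -> strain_id

    def wells(self) -> Iterable[tuple[int, str]]:
        for p in range(self.n_plates):
            for w in WELL_POSITIONS:
                yield (p, w)

    @property
    def n_wells(self) -> int:
        return 96 * self.n_plates


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(params: SimParams) -> tuple[GeneAnnotation, ContigRegistry]:
    """Tile non-overlapping genes on one chromosome, plus a vector contig.

    Gene ``i`` (0-based) occupies ``[i*(L+g)+1, i*(L+g)+L]`` where ``L`` is
    the gene length and ``g`` the intergenic gap; strands alternate.
    """
    if params.n_genes < 1:
        raise SimulationError("n_genes must be >= 1")
    if params.gene_length < 1 or params.intergenic_gap < 0:
        raise SimulationError("infeasible gene packing")
    L, g = params.gene_length, params.intergenic_gap
    starts = np.arange(params.n_genes) * (L + g) + 1
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1:04d}" for i in range(params.n_genes)],
            "contig": "chromosome",
            "start": starts,
            "end": starts + L - 1,
            "strand": ["+" if i % 2 == 0 else "-" for i in range(params.n_genes)],
        }
    )
    chrom_len = params.n_genes * (L + g)
    registry = ContigRegistry(
        (
            Contig("chromosome", chrom_len, is_plasmid=False),
            Contig("vector", params.plasmid_length, is_plasmid=True),
        )
    )
    return GeneAnnotation(genes), registry


# ---------------------------------------------------------------------------
# pool
# ---------------------------------------------------------------------------

def _draw_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    alphabet = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 20 * n + 100:
            raise SimulationError("barcode space exhausted; increase barcode_length")
        bc = "".join(rng.choice(alphabet, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def make_pool(params: SimParams, annotation: GeneAnnotation,
              registry: ContigRegistry) -> list[StrainTruth]:
    """Draw the initial pool of barcoded strains.

    Classes follow the configured mixture; insertion positions are uniform
    over the relevant contig; abundance weights are log-normal (sigma 0 means
    exactly equal) and normalized to sum to 1.
    """
    rng = params.rng("pool")
    n = params.n_strains
    if n < 1:
        raise SimulationError("n_strains must be >= 1")
    probs = [params.p_single, params.p_sbmi, params.p_mbmi,
             params.p_integrated, params.p_unmapped]
    classes = rng.choice(len(STRAIN_CLASSES), size=n, p=probs)

    n_barcodes_needed = int(
        np.sum(np.where(classes == 2, params.barcodes_per_multi, 1))
    )
    barcodes = iter(_draw_barcodes(rng, n_barcodes_needed, params.barcode_length))

    chrom = registry.chromosomes[0]
    chrom_len = registry[chrom].length
    vector = registry.plasmids[0]
    vector_len = registry[vector].length

    if params.abundance_sigma == 0:
        weights = np.full(n, 1.0 / n)
    else:
        weights = rng.lognormal(mean=0.0, sigma=params.abundance_sigma, size=n)
        weights = weights / weights.sum()

    def chrom_site() -> tuple[str, int]:
        return (chrom, int(rng.integers(1, chrom_len + 1)))

    strains: list[StrainTruth] = []
    for i in range(n):
        cls = STRAIN_CLASSES[classes[i]]
        if cls == "single":
            bcs = (next(barcodes),)
            ins = ((chrom_site(),),)
        elif cls == "single_barcode_multi":
            bcs = (next(barcodes),)
            ins = (tuple(chrom_site() for _ in range(params.insertions_per_sbmi)),)
        elif cls == "multi_barcode_multi":
            bcs = tuple(next(barcodes) for _ in range(params.barcodes_per_multi))
            ins = tuple((chrom_site(),) for _ in bcs)
        elif cls == "integrated":
            bcs = (next(barcodes),)
            ins = (((vector, int(rng.integers(1, vector_len + 1))),),)
        else:  # unmapped
            bcs = (next(barcodes),)
            ins = ((),)
        strains.append(
            StrainTruth(f"strain{i + 1:05d}", bcs, ins, cls, float(weights[i]))
        )
    return strains


# ---------------------------------------------------------------------------
# sorting
# ---------------------------------------------------------------------------

def simulate_sort(pool: list[StrainTruth], n_plates: int,
                  params: SimParams) -> CollectionTruth:
    """FACS-sort single strains into plates: i.i.d. abundance-weighted draws
    with replacement; each well independently fails (stays empty) with the
    configured probability."""
    if not pool:
        raise SimulationError("cannot sort from an empty pool")
    rng = params.rng("sort")
    weights = np.array([s.weight for s in pool])
    weights = weights / weights.sum()
    occupants: dict[tuple[int, str], str] = {}
    n_wells = 96 * n_plates
    empty = rng.random(n_wells) < params.empty_well_p
    picks = rng.choice(len(pool), size=n_wells, p=weights)
    k = 0
    for p in range(n_plates):
        for w in WELL_POSITIONS:
            if not empty[k]:
                occupants[(p, w)] = pool[picks[k]].strain_id
            k += 1
    return CollectionTruth(n_plates, occupants)


# ---------------------------------------------------------------------------
# BarSeq on plate-well pools
# ---------------------------------------------------------------------------

def simulate_barseq(
    collection: CollectionTruth,
    pool: list[StrainTruth],
    layout: PoolLayout,
    params: SimParams,
) -> tuple[BarSeqMatrix, dict[tuple[int, str], float]]:
    """BarSeq count matrix over the plate-well pools of a sorted collection.

    Each occupied well gets a latent culture abundance (log-normal around 1).
    A pool's expected barcode composition is the abundance-weighted sum of its
    member wells' barcodes (every barcode of a multi-barcode strain
    contributes); observed counts are multinomial draws of ``reads_per_pool``
    from that composition, or exact expected counts when
    ``params.exact_counts``.  Returns the matrix and the latent well
    abundances (part of the exported ground truth).
    """
    if layout.n_plates < collection.n_plates:
        raise SimulationError("layout covers fewer plates than the collection")
    rng = params.rng("barseq")
    strains = {s.strain_id: s for s in pool}
    all_barcodes = [bc for s in pool for bc in s.barcodes]
    bc_index = {bc: i for i, bc in enumerate(all_barcodes)}

    well_abundance: dict[tuple[int, str], float] = {}
    for key in collection.wells():
        if key in collection.occupants:
            a = 1.0 if params.well_noise_sigma == 0 else float(
                rng.lognormal(0.0, params.well_noise_sigma)
            )
            well_abundance[key] = a

    n_pools = layout.n_pools
    expected = np.zeros((len(all_barcodes), n_pools))
    for (p, w), strain_id in collection.occupants.items():
        a = well_abundance[(p, w)]
        cols = (p, layout.n_plates + WELL_POSITIONS.index(w))
        for bc in strains[strain_id].barcodes:
            i = bc_index[bc]
            for j in cols:
                expected[i, j] += a

    counts = np.zeros_like(expected, dtype=np.int64)
    for j in range(n_pools):
        total = expected[:, j].sum()
        if total <= 0 or params.reads_per_pool == 0:
            continue
        comp = expected[:, j] / total
        if params.exact_counts:
            counts[:, j] = np.rint(comp * params.reads_per_pool).astype(np.int64)
        else:
            counts[:, j] = rng.multinomial(params.reads_per_pool, comp)
    matrix = BarSeqMatrix(all_barcodes, layout, counts)
    return matrix, well_abundance


# ---------------------------------------------------------------------------
# RB-TnSeq site table
# ---------------------------------------------------------------------------

def simulate_rbtnseq(pool: list[StrainTruth], registry: ContigRegistry,
                     params: SimParams) -> InsertionTable:
    """Barcode -> insertion-site read table from the initial pool.

    Reads per barcode are proportional to strain abundance and split equally
    over the barcode's true sites.  With probability ``chimera_rate`` a
    barcode acquires one spurious minority site whose depth is
    ``chimera_rel_depth`` times the major site (below the default 25 % filter
    threshold when < 0.25).  Unmapped strains are omitted; integrated strains
    map to the vector contig.
    """
    rng = params.rng("rbtnseq")
    chrom = registry.chromosomes[0]
    chrom_len = registry[chrom].length
    rows = []
    for strain in pool:
        for bc, sites in zip(strain.barcodes, strain.insertions):
            if not sites:
                continue  # unmapped: no site record at all
            total = strain.weight * params.rbtnseq_total_reads / len(strain.barcodes)
            per_site = total / len(sites)
            site_reads = [per_site] * len(sites)
            site_list = list(sites)
            if params.chimera_rate > 0 and rng.random() < params.chimera_rate:
                minor = params.chimera_rel_depth * max(site_reads)
                # keep the barcode's total read budget fixed
                scale = total / (total + minor)
                site_reads = [r * scale for r in site_reads] + [minor * scale]
                true_pos = {p for c, p in site_list if c == chrom}
                while True:
                    pos = int(rng.integers(1, chrom_len + 1))
                    if all(abs(pos - tp) > 10 for tp in true_pos):
                        break
                site_list.append((chrom, pos))
            for (contig, pos), reads in zip(site_list, site_reads):
                r = max(1, int(round(reads)))
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((bc, contig, pos, strand, r))
    df = pd.DataFrame(rows, columns=list(InsertionTable.COLUMNS))
    return InsertionTable(df, registry)


# ---------------------------------------------------------------------------
# convenience: full synthetic study
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """Everything one seeded run of the generator produces, truth included."""

    params: SimParams
    annotation: GeneAnnotation
    registry: ContigRegistry
    pool: list[StrainTruth]
    collection: CollectionTruth
    layout: PoolLayout
    barseq: BarSeqMatrix
    well_abundance: dict[tuple[int, str], float]
    insertions: InsertionTable

    def truth_frame(self) -> pd.DataFrame:
        """Ground-truth table: one row per occupied well and resident barcode."""
        strains = {s.strain_id: s for s in self.pool}
        rows = []
        for (p, w), sid in self.collection.occupants.items():
            s = strains[sid]
            for bc in s.barcodes:
                rows.append((p, w, sid, s.strain_class, bc))
        return pd.DataFrame(
            rows, columns=["plate", "well", "strain_id", "strain_class", "barcode"]
        )

    def pool_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.pool:
            for bc, sites in zip(s.barcodes, s.insertions):
                rows.append(
                    (s.strain_id, s.strain_class, s.weight, bc,
                     ";".join(f"{c}:{p}" for c, p in sites))
                )
        return pd.DataFrame(
            rows, columns=["strain_id", "strain_class", "weight", "barcode", "sites"]
        )

    def barcode_weights(self) -> dict[str, float]:
        """Idealized t0 BarSeq abundances: each barcode at its strain's weight."""
        return {bc: s.weight for s in self.pool for bc in s.barcodes}

    def truth_well_classes(self) -> pd.DataFrame:
        """Ground-truth well classification (same categories as the pipeline)."""
        from .layout import WELL_POSITIONS as _WP

        cls_map = {
            "single": "single_insertion",
            "single_barcode_multi": "single_barcode_multi",
            "multi_barcode_multi": "multi_barcode_multi",
            "integrated": "integrated",
            "unmapped": "unmapped",
        }
        strains = {s.strain_id: s for s in self.pool}
        rows = []
        for p in range(self.collection.n_plates):
            for w in _WP:
                sid = self.collection.occupants.get((p, w))
                if sid is None:
                    rows.append((p, w, "empty", ""))
                else:
                    s = strains[sid]
                    rows.append(
                        (p, w, cls_map[s.strain_class], ";".join(sorted(s.barcodes)))
                    )
        return pd.DataFrame(
            rows, columns=["plate", "well", "classification", "barcodes"]
        )

    def truth_assembly_stats(self):
        """AssemblyStats computed from ground truth (no decoding involved)."""
        from .mapping import AssemblyStats

        wells = self.truth_well_classes()
        bpw = wells["barcodes"].map(lambda s: 0 if not s else s.count(";") + 1)
        fractions = {int(k): float(v)
                     for k, v in bpw.value_counts(normalize=True).items()}
        solo = wells.loc[bpw == 1]
        f_single = (
            float((solo["classification"] == "single_insertion").mean())
            if len(solo) else 0.0
        )
        useful = float((wells["classification"] == "single_insertion").mean())
        return AssemblyStats(
            n_wells=len(wells),
            bpw_fractions=fractions,
            f_single=f_single,
            fraction_useful_wells=useful,
        )

    def true_coverage_curve(self, well_grid) -> np.ndarray:
        """Genes covered by useful wells among the first w wells, per grid point.

        A well is useful iff it holds exactly one single-insertion strain;
        coverage applies the middle-85 % eligibility rule to its insertion.
        """
        from .coverage import is_eligible, relative_position
        from .layout import WELL_POSITIONS as _WP

        genes = self.annotation.genes
        strains = {s.strain_id: s for s in self.pool}
        chrom_genes = genes.sort_values("start")
        starts = chrom_genes["start"].to_numpy()
        by_contig = {
            contig: sub for contig, sub in genes.groupby("contig", sort=False)
        }

        def genes_of(strain: StrainTruth) -> frozenset[str]:
            out = []
            for sites in strain.insertions:
                for contig, pos in sites:
                    sub = by_contig.get(contig)
                    if sub is None:
                        continue
                    hit = sub[(sub["start"] <= pos) & (sub["end"] >= pos)]
                    for g in hit.itertuples(index=False):
                        f = relative_position(pos, g.start, g.end, g.strand)
                        if is_eligible(f):
                            out.append(g.gene_id)
            return frozenset(out)

        ordered = []
        for p in range(self.collection.n_plates):
            for w in _WP:
                sid = self.collection.occupants.get((p, w))
                if sid is not None and strains[sid].strain_class == "single":
                    ordered.append((96 * p + _WP.index(w), genes_of(strains[sid])))
        ordered.sort()
        covered: set[str] = set()
        idx = 0
        curve = []
        for w in well_grid:
            while idx < len(ordered) and ordered[idx][0] < w:
                covered |= ordered[idx][1]
                idx += 1
            curve.append(len(covered))
        return np.asarray(curve, dtype=np.int64)


def simulate_study(params: SimParams, n_plates: int) -> SyntheticStudy:
    """Run the whole generator: genome -> pool -> sort -> BarSeq + RB-TnSeq."""
    annotation, registry = make_genome(params)
    pool = make_pool(params, annotation, registry)
    collection = simulate_sort(pool, n_plates, params)
    layout = PoolLayout.default(n_plates)
    barseq, well_abundance = simulate_barseq(collection, pool, layout, params)
    insertions = simulate_rbtnseq(pool, registry, params)
    return SyntheticStudy(
        params, annotation, registry, pool, collection, layout,
        barseq, well_abundance, insertions,
    )
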