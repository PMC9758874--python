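# Methods

## The plate-well pooling model

An ordered collection of `N` 96-well plates is pooled twice: all wells of a
plate into one *plate pool* (N pools) and the same well position across all
plates into one *well pool* (96 pools), `N + 96` pools in total. After
BarSeq, each barcode's read count in pool `j` is normalized by the pool's
total reads, giving compositions `α` on the plate axis and `γ` on the well
axis. Presence is called per axis when a count is at least `min_reads`
(default 3) and at least `min_frac` (default 1 %) of the barcode's total
count on that axis; the isolation-count estimate is `n = max(p, q)` for `p`
plate pools and `q` well pools present.

A barcode present in one pool per axis is **definite**. Otherwise the
candidate wells are the `p × q` Cartesian product and the consistent
*configurations* assign each isolation a well: the larger axis's pools are
each used exactly once and the map onto the smaller axis is surjective, so
the balanced case `p = q = n` gives the `n!` perfect matchings. Enumeration
is capped at `max_n = 4` isolations (24 balanced configurations); beyond the
cap a barcode is reported ambiguous with all candidate wells retained, which
mirrors the wet-lab fallback of transferring all of one plate's candidates
and resolving them in the quality-check sequencing round.

### Abundance likelihood

For a true pairing, `α` and `γ` measure the same culture, so
`log(α/γ) = log G_j − log A_p` where `A_p` and `G_j` are the latent total
culture abundances of the two pools. The model is

    log(α/γ) = μ + c_well − d_plate + ε,   ε ~ N(0, σ²)

with per-pool offsets `c`, `d` absorbing the pool totals. It is fitted
robustly on the definite barcodes: median polish for the offsets, median and
1.4826 × MAD of the residuals for `μ` and `σ` (floored at 1e-6 to keep the
density proper). Configurations are scored generatively: each matched well's
culture abundance is reconstructed as `γ_j · exp(c_j)`, a plate matched to
several wells compares `α` against the *sum* of the reconstructed abundances
(well abundances are additive in a pool), and each group contributes a
Gaussian log-density of the residual. Posteriors are normalized likelihoods
under a uniform prior over configurations. The maximum-posterior
configuration is accepted at posterior ≥ `cutoff` (default 0.85).

Three refinements matter in small collections, where a well pool holds only
a handful of wells and pool totals vary strongly:

* **Fallback terms.** A pool with no definite barcode has no offset
  estimate; any term touching it is scored under the *raw* log-ratio
  distribution (median/MAD without offsets), which is honestly broad, so
  such configurations cannot become confidently wrong.
* **Iterative refit** (default 3 rounds). Confidently decoded
  multi-isolation barcodes contribute pseudo-definite log-ratio equations
  (their 1-1 pairings), and grouped pairings with a single unknown member
  yield that member's offset by subtraction; both extend offset coverage to
  pools without definite residents before the final scoring pass.
* **Lack-of-fit guard.** A maximum-posterior configuration whose worst
  standardized residual exceeds 25 σ is demoted to ambiguous. This catches
  barcodes whose isolations collide on both axes simultaneously (e.g. twice
  in one plate *and* twice at one well position): their true placement has
  more isolations than `max(p, q)` and is outside the representable
  configuration space, so every candidate fits badly and the softmax would
  otherwise pick one with spurious confidence.

The isolation-count estimate `n = max(p, q)` is a structural lower bound;
double-axis collisions are the one case it misses, and they decode as
ambiguous rather than wrong.

## Multi-insertion classification

Sites within 3 bp on the same contig are merged per barcode (reads summed,
best-supported position kept) to absorb junction-mapping jitter. The
minority-site filter then keeps a site only if its reads exceed 25 % of the
barcode's strongest site; the strongest site (and exact ties) always
survives. The filter is idempotent and monotone in the threshold.

Barcode status: any surviving site on a plasmid/vector contig → *integrated*
(vector integration dominates because such strains are unusable regardless
of other sites); else ≥ 2 sites → *multi_site* (single-barcode
multi-insertion); one chromosomal site → *single*; no site record →
*unmapped*. Whether a contig is "vector" is a registry attribute, never
inferred from names.

Well classification from the decoded locations: two or more located barcodes
in one well → *multi_barcode_multi* regardless of their individual statuses
(co-residency implies a multi-insertion genome or cross-contamination, and
either disqualifies the well); one located barcode → that barcode's status;
none → *empty*. Only trusted placements (definite or high-confidence) count
as residency, so wells holding only ambiguous barcodes are conservatively
treated as empty. A barcode located in several wells is repeat isolation,
not multi-insertion.

## Assembly efficiency and saturation modeling

Collection statistics: `bpw` is the number of located barcode bins per well;
`f_single` is the single-site fraction among bins in `bpw = 1` wells — the
sequential filter that defines a usable well (first exactly one barcode,
then a single defined chromosomal site). With this conditional definition
the factored estimator `K = P(bpw = 1) × f_single` coincides with the direct
estimator (fraction of wells classified single-insertion); `estimate_K`
computes both and warns if they disagree by more than 0.05 (they can, e.g.
when `f_single` is supplied marginally, because multi-barcode strains have
individually-single bins that only ever occur in `bpw = 2` wells).

The Monte Carlo saturation model draws `b = round(K·w)` barcodes i.i.d. with
replacement from the initial pool, weighted by t0-style BarSeq abundance,
and counts genes with ≥ 1 eligible insertion. The draw pool is restricted to
*useful* barcodes — a single defined chromosomal site after the 25 % filter —
because `K` already prices the loss of unmapped, multi-site and integrated
strains into the wells-to-draws conversion; callers may additionally remove
barcodes identified as multi-barcode multi-insertion by co-residency.
Multi-barcode strains never sorted into the collection are undetectable in
the lookup table and remain in the pool; they bias predicted coverage
slightly upward (a few genes at the scales used here) — the same confound
the underlying classification scheme accepts.

Within each of the 250 repetitions per grid the draws are nested (one
maximal sequence, prefixes per grid point), so per-repetition curves are
monotone and scaling `K` rescales the curve along the well axis exactly.
Reported per size `w`: mean coverage, a 2.5–97.5 percentile band, and the
high-confidence count (genes covered in ≥ 95 % of repetitions).
Counterfactuals: equalized weights and/or `K = 1`. Residuals against an
observed collection are `true(w) − mean(w)` with linear interpolation
between grid points; incremental efficiency is the central finite difference
of mean coverage, and the practical size limit is the first grid point where
it falls below 2×10⁻³ genes/well.

The expectation has the exact closed form `E[C(b)] = Σ_g (1 − (1 − p_g)^b)`
with `p_g` the total draw weight of barcodes disrupting gene `g`; it is used
as an analytic oracle in the tests, while the Monte Carlo path provides the
bands and high-confidence sets that need realizations.

**Calibration accuracy at small scale.** The comparison of a *single* sorted
collection against the model mean has an irreducible realization noise of
roughly `√(0.1–0.15 G)` genes per grid point (3–5 genes for a 200-gene
genome), because which strains happen to be sorted varies between
realizations. At genome scale (thousands of genes) this noise is ~1 % of
genes and the model tracks an observed curve within it; for the scaled-down
synthetic studies used in the test suite the maximum residual is typically
2–5 % of the gene count, dominated by this noise rather than model bias (the
Monte Carlo mean agrees with the closed form to a fraction of a gene).

## Coverage rules and re-array planning

The relative position of an insertion in a gene is
`f = (position − start)/length` on the + strand and
`(end − position)/length` on the − strand, so `f = 0` is always the start
codon. Eligibility is the half-open band `0.05 ≤ f < 0.90`: strictly after
the first 5 % of positions and before the last 10 %, which on an integer
grid contains exactly 85 % of a gene's positions. A gene is covered when ≥ 1
eligible insertion from a usable barcode hits it.

For each covered gene the representative is the single-insertion strain
whose insertion minimizes `|f − 0.5|`; ties break by lower plate index, then
row-major well order. Barcodes co-resident with another located barcode are
excluded from representative selection (they are multi-barcode
multi-insertion strains even though each barcode maps to a single site). A
gene whose only eligible candidates decode ambiguously gets all candidate
wells from one source plate — the plate with the greatest posterior mass
over the barcode's configurations — transferred as `ambiguous_candidate`
records, to be resolved by re-decoding the condensed collection. Genes with
only multi-insertion coverage, and uncovered genes, are reported as lists
alongside the plan. Destinations fill row-major, skipping reserved
blank/control wells (default A1, B1, H12).

## Growth metrics

Per well, the blank-subtracted OD600 series yields: maximum growth rate =
the largest OLS slope of ln(OD) over every contiguous 5-point window whose
readings all exceed the detection floor (default 0.005, below which the log
is noise-dominated); and maximum OD600 on a width-3 median-filtered series
(suppresses single-read spikes). On exact exponential data the estimate
equals the generating rate to machine precision; on any data it equals the
brute-force maximum over all windows, a property the test suite asserts
directly. Wild-type control wells give a sample mean and unbiased covariance
of (max rate, max OD); mutant wells with Mahalanobis distance > 3 are
flagged as growth outliers. At least 3 controls with genuine variation in
both metrics are required; a singular covariance is an error rather than a
silent pseudo-inverse.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline exploits,
with one RNG seed and deterministic per-stage sub-streams:

* **Genome**: non-overlapping genes (default 200 × 900 bp, 100 bp gaps,
  alternating strands) on one chromosome plus a separate vector contig.
* **Pool**: default 1000 strains with log-normal abundance weights
  (σ = 1, matching the strong abundance bias of passaged conjugation pools)
  and class mixture 58 % single / 20 % single-barcode multi (2 insertions) /
  12 % multi-barcode multi (2 barcodes) / 4 % integrated / 6 % unmapped —
  single-insertion a slight majority, single-barcode multi-insertion the
  most common defect, multi-barcode next, integrated and unmapped minorities.
* **Sorting**: one abundance-weighted strain draw per well, i.i.d. with
  replacement; wells fail (stay empty) independently with probability 0.05.
* **BarSeq**: each occupied well gets a latent log-normal culture abundance
  (σ = 0.5 around unit median) — the systematic well-to-well variation the
  decoder requires; pool compositions are abundance-weighted sums over
  member wells and observed counts are multinomial draws of
  `reads_per_pool` (default 200 000) per pool. With `exact_counts=True` the
  expected counts are emitted directly.
* **RB-TnSeq**: reads proportional to strain abundance, split equally over a
  barcode's true sites; with the chimera rate, one spurious minority site is
  added at 10 % of the major site's depth (below the 25 % filter threshold)
  with the barcode's read budget held fixed.

"Noise-free" in the tests means exact expected counts; the per-well
abundance variation is signal, not noise — with it at zero, the pools carry
no information to separate the configurations of a multi-isolated barcode,
and such barcodes correctly fall to ambiguous.

What the generator does **not** model: sequencing errors in barcode reads
(exact matching is assumed), PCR amplification bias beyond multinomial
sampling, cross-contamination between wells, plate-position effects, or
strain fitness differences during outgrowth beyond the static log-normal
well factor. Pipeline exactness on this synthetic data therefore bounds
performance from above; on real data the presence thresholds and the
ambiguous fallback absorb part of the gap, and the quality-check re-decode
of the condensed collection catches the rest.

## Numerical and design choices

* Coordinates are 1-based inclusive externally (GFF3 convention);
  `intervaltree` half-open intervals are converted at the boundary.
* The abundance model's σ floor (1e-6), the lack-of-fit z threshold (25),
  and the refit round count (3) were chosen for the noise-free regime and
  are exposed as `PlateWellDecoder` arguments.
* `b = round(K·w)` uses nearest-integer rounding.
* The 95 % band is a percentile band over repetitions, not a parametric
  interval.
* Site merging (3 bp) happens before the 25 % filter; merging is skipped
  inside the saturation model's pool construction because the generator
  emits one record per site.
* Degenerate inputs: zero wells, empty presence patterns, sub-window growth
  series and singular control covariances raise typed errors
  (`ValidationError`, `DecodeError`, `PlanError`, `SimulationError`) rather
  than propagating NaNs.

## Known limitations

* Barcodes isolated more than `max_n = 4` times are never placed (factorial
  enumeration); they are carried as ambiguous. Heavy pool members therefore
  decode ambiguous in small collections — visible as `K` underestimation
  relative to ground truth when abundance bias is strong.
* Double-axis isolation collisions are outside the configuration space and
  decode ambiguous by design (via the lack-of-fit guard).
* Multi-barcode multi-insertion strains are detectable only through
  co-residency in the decoded collection; in the saturation model's draw
  pool, unsorted ones remain and bias predicted coverage slightly upward.
* The decoder's pool-effect estimates are per-pool medians; with very few
  definite barcodes per pool they are noisy, and the posterior can be
  overconfident under heavy multinomial noise (the 0.85 cutoff and the
  quality-check round are the systemic safeguards).
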