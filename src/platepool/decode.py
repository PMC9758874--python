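"""Probabilistic decoding of barcode locations from plate-well pools.

With one pool per plate and one per 96-well position, a barcode sorted into
well (p, j) is sequenced in exactly two pools: plate pool p and well pool j.
A barcode isolated once is *definite* — its unique plate pool and well pool
intersect in one well.  A barcode isolated ``n`` times appears in up to ``n``
plate pools and up to ``n`` well pools, and its true wells are narrowed down
to the (up to) ``n**2`` wells of the Cartesian product; which of the candidate
configurations is real must be inferred.

The inference exploits systematic well-to-well differences in culture
abundance: a barcode's normalized abundance in its plate pool and in its well
pool both reflect the same underlying culture, so for a *true* (plate, well)
pairing the log-ratio log(alpha/gamma) of the two normalized abundances is
drawn from a tight distribution, estimated robustly from the definite
barcodes.  Each candidate configuration is scored by the Gaussian
log-likelihood of its matched log-ratios; posteriors are likelihoods
normalized under a uniform prior.  The maximum-posterior configuration is
accepted as high confidence when its posterior reaches the cutoff
(default 0.85); otherwise all candidate wells are carried forward so a
re-array step can transfer one plate's worth and resolve the ambiguity in a
quality-check sequencing round.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DecodeError
from .io import BarSeqMatrix, LocationTable
from .layout import WELL_POSITIONS, PoolLayout


@dataclass(frozen=True)
class PresenceCall:
    """Pools in which one barcode was detected, with normalized abundances.

    ``plates`` maps plate pool id -> alpha (count / pool total); ``wells``
    maps well pool id -> gamma.  The isolation count estimate is
    ``n = max(#plates, #wells)``.
    """

    barcode: str
    plates: dict[str, float]
    wells: dict[str, float]

    @property
    def n(self) -> int:
        return max(len(self.plates), len(self.wells))

    @property
    def absent(self) -> bool:
        return not self.plates and not self.wells


@dataclass(frozen=True)
class AbundanceModel:
    """Distribution of log(alpha/gamma) fitted on definite barcodes.

    ``mu`` and ``sigma`` are the robust location and scale of the log-ratio.
    Optionally the model carries additive per-pool effects: a barcode's
    normalized abundance is its culture abundance divided by the pool's total
    culture abundance, so log(alpha/gamma) decomposes as
    mu + c_well - d_plate + noise, with c and d systematic offsets of the two
    pools.  The effects (estimated by median polish over definite barcodes)
    sharpen the likelihood considerably in small collections, where per-pool
    totals vary strongly; with no effects the model reduces to a global
    Gaussian on the log-ratio.
    """

    mu: float
    sigma: float
    plate_effects: Mapping[str, float] = field(default_factory=dict)
    well_effects: Mapping[str, float] = field(default_factory=dict)
    # raw log-ratio statistics, used for terms touching pools whose effect
    # could not be estimated (no definite barcode in that pool yet)
    fallback_mu: float | None = None
    fallback_sigma: float | None = None

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise DecodeError("abundance model scale must be positive")

    def knows(self, plate: str, wells: tuple[str, ...]) -> bool:
        return plate in self.plate_effects and all(
            w in self.well_effects for w in wells
        )

    def knows_well(self, well: str, plates: tuple[str, ...]) -> bool:
        return well in self.well_effects and all(
            p in self.plate_effects for p in plates
        )

    def plate_group_residual(
        self, alpha: float, plate: str, gammas: Mapping[str, float]
    ) -> float:
        """Residual of log(alpha) vs its prediction from the matched wells.

        Each matched well's culture abundance is reconstructed from its well
        pool (gamma corrected by the well pool's effect); the plate pool sees
        their sum, shifted by the plate pool's effect.  With no effects and a
        single well this reduces to log(alpha/gamma) - mu.
        """
        terms = np.array(
            [np.log(g) + self.well_effects.get(w, 0.0) for w, g in gammas.items()]
        )
        pred = self.mu - self.plate_effects.get(plate, 0.0) + _logsumexp(terms)
        return float(np.log(alpha) - pred)

    def well_group_residual(
        self, gamma: float, well: str, alphas: Mapping[str, float]
    ) -> float:
        """Residual of log(gamma) vs its prediction from the matched plates."""
        terms = np.array(
            [np.log(a) + self.plate_effects.get(p, 0.0) for p, a in alphas.items()]
        )
        pred = -self.mu - self.well_effects.get(well, 0.0) + _logsumexp(terms)
        return float(np.log(gamma) - pred)


def _logsumexp(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    m = x.max()
    return float(m + np.log(np.exp(x - m).sum()))


@dataclass(frozen=True)
class CandidateConfiguration:
    """One consistent assignment of a barcode's isolations to wells."""

    wells: tuple[tuple[str, str], ...]  # (plate pool id, well pool id) pairs
    log_likelihood: float
    posterior: float
    # worst per-term standardized residual: a lack-of-fit diagnostic; a high
    # max_z means even this configuration explains the pool abundances poorly
    max_z: float = 0.0


# ---------------------------------------------------------------------------
# presence calling
# ---------------------------------------------------------------------------

def call_presence(
    matrix: BarSeqMatrix,
    min_reads: int = 3,
    min_frac: float = 0.01,
) -> list[PresenceCall]:
    """Presence per barcode per pool, thresholded independently per axis.

    A barcode is present in a pool iff its count is >= ``min_reads`` and
    >= ``min_frac`` times the barcode's total count on that pooling axis
    (plate axis and well axis separately).
    """
    layout = matrix.layout
    totals = matrix.pool_totals.astype(float)
    totals[totals == 0] = np.nan
    calls = []
    plate_tot = matrix.plate_counts.sum(axis=1)
    well_tot = matrix.well_counts.sum(axis=1)
    for i, bc in enumerate(matrix.barcodes):
        row = matrix.counts[i]
        plates: dict[str, float] = {}
        wells: dict[str, float] = {}
        for j, pid in enumerate(layout.plate_pool_ids):
            c = row[j]
            if c >= min_reads and c >= min_frac * plate_tot[i]:
                plates[pid] = c / totals[j]
        for k, wid in enumerate(layout.well_pool_ids):
            j = layout.n_plates + k
            c = row[j]
            if c >= min_reads and c >= min_frac * well_tot[i]:
                wells[wid] = c / totals[j]
        calls.append(PresenceCall(bc, plates, wells))
    return calls


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def candidate_wells(call: PresenceCall) -> list[tuple[str, str]]:
    """All p x q candidate wells (Cartesian product of present pools)."""
    return [
        (p, w) for p in call.plates for w in call.wells
    ]


def enumerate_configurations(call: PresenceCall) -> list[tuple[tuple[str, str], ...]]:
    """All well configurations consistent with the presence pattern.

    Each isolation occupies a distinct well.  Every present pool must be
    explained, so with p plate pools and q well pools (n = max(p, q)
    isolations) the larger axis's pools are each used exactly once and the
    assignments onto the smaller axis are surjective.  In the balanced case
    p = q = n these are the n! perfect matchings.
    """
    plates = list(call.plates)
    wells = list(call.wells)
    p, q = len(plates), len(wells)
    if p == 0 or q == 0:
        return []
    configs: list[tuple[tuple[str, str], ...]] = []
    if p >= q:
        # each plate pool used once; map plates -> wells, surjective onto wells
        for assign in itertools.product(range(q), repeat=p):
            if len(set(assign)) == q:
                configs.append(
                    tuple((plates[i], wells[assign[i]]) for i in range(p))
                )
    else:
        # each well pool used once; map wells -> plates, surjective onto plates
        for assign in itertools.product(range(p), repeat=q):
            if len(set(assign)) == p:
                configs.append(
                    tuple((plates[assign[j]], wells[j]) for j in range(q))
                )
    return configs


# ---------------------------------------------------------------------------
# abundance model
# ---------------------------------------------------------------------------

def fit_abundance_model(
    calls: list[PresenceCall],
    min_definite: int = 20,
    fallback: AbundanceModel | None = None,
    pool_effects: bool = False,
    n_polish: int = 5,
) -> AbundanceModel:
    """Robust fit of the log(alpha/gamma) distribution over definite barcodes.

    The global location and scale are the median and 1.4826 x MAD.  With
    ``pool_effects=True``, additive per-pool offsets (log-ratio decomposed as
    mu + c_well - d_plate) are first estimated by median polish and the scale
    is taken on the residuals.  Raises if fewer than ``min_definite`` definite
    barcodes are available and no fallback model is supplied.
    """
    triples = definite_ratio_equations(calls)
    if len(triples) < min_definite:
        if fallback is not None:
            return fallback
        raise DecodeError(
            f"only {len(triples)} definite barcodes (< {min_definite}); "
            "supply a fallback AbundanceModel (mu, sigma) from configuration"
        )
    return _fit_from_equations(triples, pool_effects, n_polish)


def definite_ratio_equations(
    calls: list[PresenceCall],
) -> list[tuple[str, str, float]]:
    """(plate pool, well pool, log-ratio) equations from definite barcodes."""
    return [
        (next(iter(c.plates)), next(iter(c.wells)),
         float(np.log(next(iter(c.plates.values()))
                      / next(iter(c.wells.values())))))
        for c in calls
        if len(c.plates) == 1 and len(c.wells) == 1
    ]


def _fit_from_equations(
    triples: list[tuple[str, str, float]],
    pool_effects: bool,
    n_polish: int = 5,
) -> AbundanceModel:
    r = np.array([t[2] for t in triples])
    mu = float(np.median(r))
    raw_sigma = max(1.4826 * float(np.median(np.abs(r - mu))), 1e-6)
    if not pool_effects:
        return AbundanceModel(mu, raw_sigma)

    plates = [t[0] for t in triples]
    wells = [t[1] for t in triples]
    c: dict[str, float] = {w: 0.0 for w in set(wells)}
    d: dict[str, float] = {p: 0.0 for p in set(plates)}
    by_well: dict[str, list[int]] = {}
    by_plate: dict[str, list[int]] = {}
    for i, (p, w, _) in enumerate(triples):
        by_well.setdefault(w, []).append(i)
        by_plate.setdefault(p, []).append(i)
    for _ in range(n_polish):
        for w, idx in by_well.items():
            c[w] = float(np.median([r[i] - mu + d[plates[i]] for i in idx]))
        for p, idx in by_plate.items():
            d[p] = float(np.median([mu + c[wells[i]] - r[i] for i in idx]))
    resid = np.array([r[i] - (mu + c[wells[i]] - d[plates[i]])
                      for i in range(len(triples))])
    raw_mu = mu
    mu += float(np.median(resid))
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    return AbundanceModel(
        mu, max(sigma, 1e-6), d, c,
        fallback_mu=raw_mu, fallback_sigma=raw_sigma,
    )


# ---------------------------------------------------------------------------
# configuration scoring
# ---------------------------------------------------------------------------

def score_configurations(
    call: PresenceCall,
    model: AbundanceModel,
) -> list[CandidateConfiguration]:
    """Score every consistent configuration and normalize to posteriors.

    Per configuration the log-likelihood sums, over matched groups, the
    Gaussian log-density of log(alpha/gamma) under the fitted model.  When one
    pool on the smaller axis is matched to k pools of the larger axis, the
    k abundances add (the wells' contributions to that pool are additive).
    Posteriors use a uniform prior over configurations.
    """
    configs = enumerate_configurations(call)
    if not configs:
        return []
    fb_mu = model.fallback_mu if model.fallback_mu is not None else model.mu
    fb_sigma = (model.fallback_sigma if model.fallback_sigma is not None
                else model.sigma)
    lls = np.empty(len(configs))
    max_zs = np.empty(len(configs))
    for c, config in enumerate(configs):
        ll = 0.0
        max_z = 0.0
        if len(call.plates) <= len(call.wells):
            # group matched wells per plate: alpha vs the sum of its gammas
            by_plate: dict[str, dict[str, float]] = {}
            for plate, well in config:
                by_plate.setdefault(plate, {})[well] = call.wells[well]
            for plate, gammas in by_plate.items():
                if model.knows(plate, tuple(gammas)):
                    resid = model.plate_group_residual(
                        call.plates[plate], plate, gammas
                    )
                    ll += norm.logpdf(resid, 0.0, model.sigma)
                    max_z = max(max_z, abs(resid) / model.sigma)
                else:
                    raw = np.log(call.plates[plate] / sum(gammas.values()))
                    ll += norm.logpdf(raw, fb_mu, fb_sigma)
                    max_z = max(max_z, abs(raw - fb_mu) / fb_sigma)
        else:
            by_well: dict[str, dict[str, float]] = {}
            for plate, well in config:
                by_well.setdefault(well, {})[plate] = call.plates[plate]
            for well, alphas in by_well.items():
                if model.knows_well(well, tuple(alphas)):
                    resid = model.well_group_residual(
                        call.wells[well], well, alphas
                    )
                    ll += norm.logpdf(resid, 0.0, model.sigma)
                    max_z = max(max_z, abs(resid) / model.sigma)
                else:
                    raw = np.log(sum(alphas.values()) / call.wells[well])
                    ll += norm.logpdf(raw, fb_mu, fb_sigma)
                    max_z = max(max_z, abs(raw - fb_mu) / fb_sigma)
        lls[c] = ll
        max_zs[c] = max_z
    post = np.exp(lls - lls.max())
    post = post / post.sum()
    return [
        CandidateConfiguration(config, float(ll), float(p), float(z))
        for config, ll, p, z in zip(configs, lls, post, max_zs)
    ]


def _group_subtraction_equations(
    call: PresenceCall,
    config: CandidateConfiguration,
    model: AbundanceModel,
) -> list[tuple[str, str, float]]:
    """Effect equations for unknown pools in grouped matchings.

    In a configuration where plate p is matched to wells J, the generative
    model says alpha_p * exp(d_p) = exp(mu) * sum_J gamma_j * exp(c_j).  When
    the plate effect and all but one well effect are known, the unknown
    well's scaled abundance — and hence its effect — follows by subtraction;
    the result is emitted as an equivalent 1-1 log-ratio equation for the
    median polish.  The symmetric derivation covers wells matched to several
    plates.
    """
    eqs: list[tuple[str, str, float]] = []
    by_plate: dict[str, list[str]] = {}
    by_well: dict[str, list[str]] = {}
    for p, w in config.wells:
        by_plate.setdefault(p, []).append(w)
        by_well.setdefault(w, []).append(p)
    for p, wells in by_plate.items():
        if len(wells) < 2 or p not in model.plate_effects:
            continue
        unknown = [w for w in wells if w not in model.well_effects]
        if len(unknown) != 1:
            continue
        u = unknown[0]
        total = call.plates[p] * np.exp(model.plate_effects[p] - model.mu)
        known_sum = sum(
            call.wells[w] * np.exp(model.well_effects[w])
            for w in wells if w != u
        )
        a_u = total - known_sum
        if a_u <= 0:
            continue
        c_u = float(np.log(a_u / call.wells[u]))
        eqs.append((p, u, model.mu + c_u - model.plate_effects[p]))
    for w, plates in by_well.items():
        if len(plates) < 2 or w not in model.well_effects:
            continue
        unknown = [p for p in plates if p not in model.plate_effects]
        if len(unknown) != 1:
            continue
        v = unknown[0]
        total = call.wells[w] * np.exp(model.well_effects[w] + model.mu)
        known_sum = sum(
            call.plates[p] * np.exp(model.plate_effects[p])
            for p in plates if p != v
        )
        a_v = total - known_sum
        if a_v <= 0:
            continue
        d_v = float(np.log(a_v / call.plates[v]))
        eqs.append((v, w, model.mu + model.well_effects[w] - d_v))
    return eqs


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PlateWellDecoder:
    """Decoder model for one BarSeq matrix over a plate-well pooled collection.

    Parameters
    ----------
    matrix:
        BarSeq counts over the N + 96 pools.
    min_reads, min_frac:
        Presence thresholds (absolute reads; fraction of the barcode's total
        on each pooling axis).
    max_n:
        Isolation counts above this are not scored (configuration enumeration
        grows factorially); such barcodes are reported ambiguous with all
        candidate wells retained.
    cutoff:
        Posterior required to accept a MAP configuration as high confidence.
    min_definite, fallback_model:
        Minimum definite barcodes for fitting the abundance model, and the
        model to fall back on below that minimum.
    pool_effects:
        Estimate additive per-pool abundance offsets from the definite
        barcodes (recommended; essential for small collections).
    refit_rounds:
        Extra rounds in which confidently decoded multi-isolation barcodes
        contribute pseudo-definite log-ratio equations, extending pool-effect
        coverage to pools that hold no definite barcode, before the final
        scoring pass.
    """

    def __init__(
        self,
        matrix: BarSeqMatrix,
        *,
        min_reads: int = 3,
        min_frac: float = 0.01,
        max_n: int = 4,
        cutoff: float = 0.85,
        min_definite: int = 20,
        fallback_model: AbundanceModel | None = None,
        pool_effects: bool = True,
        refit_rounds: int = 3,
        lack_of_fit_z: float = 25.0,
    ) -> None:
        self.matrix = matrix
        self.min_reads = min_reads
        self.min_frac = min_frac
        self.max_n = max_n
        self.cutoff = cutoff
        self.min_definite = min_definite
        self.fallback_model = fallback_model
        self.pool_effects = pool_effects
        self.refit_rounds = refit_rounds
        # a MAP configuration whose worst standardized residual exceeds this
        # is demoted to ambiguous: none of the enumerated configurations
        # explains the pool abundances (e.g., isolations colliding on both
        # the plate and the well-position axis simultaneously)
        self.lack_of_fit_z = lack_of_fit_z

    def fit(self) -> "DecodeResults":
        """Call presence, fit the abundance model and decode every barcode."""
        layout = self.matrix.layout
        calls = call_presence(self.matrix, self.min_reads, self.min_frac)
        model = fit_abundance_model(
            calls, self.min_definite, self.fallback_model,
            pool_effects=self.pool_effects,
        )
        definite_eqs = definite_ratio_equations(calls)
        multi = [
            c for c in calls
            if c.plates and c.wells and 2 <= c.n <= self.max_n
        ]

        rounds = self.refit_rounds if self.pool_effects else 0
        configurations: dict[str, list[CandidateConfiguration]] = {}
        for rnd in range(rounds + 1):
            configurations = {
                c.barcode: score_configurations(c, model) for c in multi
            }
            if rnd == rounds:
                break
            pseudo: list[tuple[str, str, float]] = []
            for c in multi:
                scored = configurations[c.barcode]
                best = max(scored, key=lambda x: x.posterior)
                if best.posterior < self.cutoff:
                    continue
                n_plate = {p: 0 for p, _ in best.wells}
                n_well = {w: 0 for _, w in best.wells}
                for p, w in best.wells:
                    n_plate[p] += 1
                    n_well[w] += 1
                for p, w in best.wells:
                    # only 1-1 pairings within the configuration yield a
                    # clean single-well log-ratio equation
                    if n_plate[p] == 1 and n_well[w] == 1:
                        pseudo.append(
                            (p, w, float(np.log(c.plates[p] / c.wells[w])))
                        )
                pseudo.extend(_group_subtraction_equations(c, best, model))
            model = _fit_from_equations(
                definite_eqs + pseudo, self.pool_effects
            )

        rows: list[tuple] = []
        for call in calls:
            bc = call.barcode
            if call.absent or not call.plates or not call.wells:
                rows.append((bc, pd.NA, pd.NA, np.nan, "absent"))
                continue
            if call.n == 1:
                plate_id = next(iter(call.plates))
                well_id = next(iter(call.wells))
                rows.append(
                    (bc, layout.plate_index(plate_id),
                     layout.well_position(well_id), 1.0, "definite")
                )
                continue
            if call.n > self.max_n:
                cands = candidate_wells(call)
                for plate_id, well_id in cands:
                    rows.append(
                        (bc, layout.plate_index(plate_id),
                         layout.well_position(well_id), 0.0, "ambiguous")
                    )
                continue
            scored = configurations[bc]
            best = max(scored, key=lambda c: c.posterior)
            if best.posterior >= self.cutoff and best.max_z <= self.lack_of_fit_z:
                for plate_id, well_id in best.wells:
                    rows.append(
                        (bc, layout.plate_index(plate_id),
                         layout.well_position(well_id),
                         best.posterior, "high_confidence")
                    )
            else:
                # retain all candidate wells with their marginal posteriors
                marginal: dict[tuple[str, str], float] = {}
                for config in scored:
                    for pw in set(config.wells):
                        marginal[pw] = marginal.get(pw, 0.0) + config.posterior
                for plate_id, well_id in candidate_wells(call):
                    rows.append(
                        (bc, layout.plate_index(plate_id),
                         layout.well_position(well_id),
                         min(1.0, marginal.get((plate_id, well_id), 0.0)),
                         "ambiguous")
                    )
        table = LocationTable(
            pd.DataFrame(rows, columns=list(LocationTable.COLUMNS))
        )
        return DecodeResults(self, table, model, calls, configurations)


class DecodeResults:
    """Decoded locations plus the fitted abundance model and diagnostics."""

    def __init__(
        self,
        model_spec: PlateWellDecoder,
        location_table: LocationTable,
        abundance_model: AbundanceModel,
        presence_calls: list[PresenceCall],
        configurations: dict[str, list[CandidateConfiguration]],
    ) -> None:
        self.model_spec = model_spec
        self.location_table = location_table
        self.abundance_model = abundance_model
        self.presence_calls = presence_calls
        self.configurations = configurations

    @property
    def status_counts(self) -> pd.Series:
        """Barcodes per decode status (each barcode counted once)."""
        df = self.location_table.records
        return df.groupby("barcode")["status"].first().value_counts()

    def plate_posterior_mass(self, barcode: str) -> dict[int, float]:
        """Posterior mass per plate index over a barcode's configurations."""
        layout = self.model_spec.matrix.layout
        mass: dict[int, float] = {}
        for config in self.configurations.get(barcode, []):
            for plate_id, _ in set(config.wells):
                idx = layout.plate_index(plate_id)
                mass[idx] = mass.get(idx, 0.0) + config.posterior
        return mass

    def summary(self) -> str:
        counts = self.status_counts
        lines = [
            "Plate-well pool decode",
            "======================",
            f"pools: {self.model_spec.matrix.layout.n_plates} plates + 96 wells",
            f"barcodes: {len(self.model_spec.matrix.barcodes)}",
            f"abundance model: mu={self.abundance_model.mu:+.4f} "
            f"sigma={self.abundance_model.sigma:.4f}",
            f"posterior cutoff: {self.model_spec.cutoff}",
            "",
            "status counts:",
        ]
        for status in ("definite", "high_confidence", "ambiguous", "absent"):
            lines.append(f"  {status:16s} {int(counts.get(status, 0)):6d}")
        return "\n".join(lines)


def decode_collection(
    matrix: BarSeqMatrix,
    cutoff: float = 0.85,
    **kwargs,
) -> LocationTable:
    """Convenience wrapper: decode a matrix and return the location table."""
    return PlateWellDecoder(matrix, cutoff=cutoff, **kwargs).fit().location_table
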