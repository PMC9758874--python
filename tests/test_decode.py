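"""Plate-well pool decoding: presence, enumeration, scoring, golden path."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import platepool as pp
from platepool.decode import (
    AbundanceModel,
    PresenceCall,
    candidate_wells,
    enumerate_configurations,
    fit_abundance_model,
    score_configurations,
)
from platepool.errors import DecodeError

from conftest import trusted_placements, truth_wells_by_barcode


def make_matrix(cells, n_plates=2, barcodes=("ACGTACGT",)):
    """Matrix from {(barcode, pool id): count}; other pools get filler reads
    on a second dummy barcode so pool totals are positive."""
    layout = pp.PoolLayout.default(n_plates)
    all_bcs = list(barcodes) + ["T" * 8]
    counts = np.zeros((len(all_bcs), layout.n_pools), dtype=int)
    counts[-1, :] = 10_000  # filler so every pool has reads
    for (bc, pool), c in cells.items():
        counts[all_bcs.index(bc), layout.pool_ids.index(pool)] = c
    return pp.BarSeqMatrix(all_bcs, layout, counts)


class TestPresence:
    def test_single_isolation_yields_one_plate_and_one_well(self):
        m = make_matrix({("ACGTACGT", "P1"): 500, ("ACGTACGT", "G1"): 480})
        call = pp.call_presence(m)[0]
        assert set(call.plates) == {"P1"}
        assert set(call.wells) == {"G1"}
        assert call.n == 1

    def test_reads_below_min_reads_not_called(self):
        m = make_matrix(
            {("ACGTACGT", "P1"): 500, ("ACGTACGT", "P2"): 2,
             ("ACGTACGT", "G1"): 480}
        )
        call = pp.call_presence(m, min_reads=3)[0]
        assert set(call.plates) == {"P1"}

    def test_all_zero_row_is_absent(self):
        m = make_matrix({})
        assert pp.call_presence(m)[0].absent


class TestEnumeration:
    def test_worked_example_two_isolations(self):
        """Presence in P1, P2, G1, H2 narrows to 4 candidate wells and 2
        balanced configurations."""
        call = PresenceCall("ACGTACGT", {"P1": 0.1, "P2": 0.1},
                            {"G1": 0.1, "H2": 0.1})
        cands = candidate_wells(call)
        assert len(cands) == 4
        assert set(cands) == {("P1", "G1"), ("P1", "H2"),
                              ("P2", "G1"), ("P2", "H2")}
        assert len(enumerate_configurations(call)) == 2

    def test_balanced_three_isolations(self):
        call = PresenceCall("ACGTACGT",
                            {f"P{i}": 0.1 for i in (1, 2, 3)},
                            {w: 0.1 for w in ("A1", "B2", "C3")})
        assert len(candidate_wells(call)) == 9
        configs = enumerate_configurations(call)
        assert len(configs) == 6  # 3! perfect matchings
        # brute-force oracle: every bijection, each exactly once
        plates, wells = ["P1", "P2", "P3"], ["A1", "B2", "C3"]
        expected = {
            frozenset(zip(plates, perm))
            for perm in itertools.permutations(wells)
        }
        assert {frozenset(c) for c in configs} == expected

    def test_unbalanced_pattern_uses_surjections(self):
        call = PresenceCall("ACGTACGT", {"P1": 0.1},
                            {"A1": 0.1, "B2": 0.1})
        configs = enumerate_configurations(call)
        assert configs == [(("P1", "A1"), ("P1", "B2"))]


class TestAbundanceModel:
    def _definite(self, ratios):
        calls = []
        for i, r in enumerate(ratios):
            gamma = 0.01
            calls.append(
                PresenceCall(f"BC{i}", {"P1": gamma * np.exp(r)}, {"A1": gamma})
            )
        return calls

    def test_symmetric_ratios_give_zero_location(self):
        model = fit_abundance_model(self._definite([0.0] * 25), min_definite=20)
        assert model.mu == pytest.approx(0.0)

    def test_mad_arithmetic(self):
        model = fit_abundance_model(self._definite([-0.1, 0.0, 0.1]),
                                    min_definite=3)
        assert model.mu == pytest.approx(0.0, abs=1e-12)
        assert model.sigma == pytest.approx(1.4826 * 0.1, rel=1e-6)

    def test_too_few_definite_barcodes_raises(self):
        with pytest.raises(DecodeError, match="fallback"):
            fit_abundance_model(self._definite([0.0] * 5), min_definite=20)

    def test_fallback_model_used_when_supplied(self):
        fb = AbundanceModel(0.5, 2.0)
        model = fit_abundance_model(self._definite([0.0] * 5),
                                    min_definite=20, fallback=fb)
        assert model is fb


class TestScoring:
    def test_single_configuration_has_posterior_one(self):
        call = PresenceCall("ACGTACGT", {"P1": 0.01}, {"G1": 0.01})
        scored = score_configurations(call, AbundanceModel(0.0, 1.0))
        assert len(scored) == 1
        assert scored[0].posterior == pytest.approx(1.0)

    def test_matching_large_with_large_wins(self):
        """Well-separated abundances: the matching pairing the abundant plate
        with the abundant well dominates (evaluated densities by hand)."""
        call = PresenceCall(
            "ACGTACGT",
            {"P1": 0.01, "P2": 0.0001},
            {"G1": 0.011, "H2": 0.00011},
        )
        scored = score_configurations(call, AbundanceModel(0.0, 1.0))
        best = max(scored, key=lambda c: c.posterior)
        assert set(best.wells) == {("P1", "G1"), ("P2", "H2")}
        assert best.posterior > 0.99

    def test_equal_abundances_give_uniform_posterior(self):
        call = PresenceCall("ACGTACGT",
                            {"P1": 0.01, "P2": 0.01},
                            {"G1": 0.01, "H2": 0.01})
        scored = score_configurations(call, AbundanceModel(0.0, 1.0))
        assert [c.posterior for c in scored] == pytest.approx([0.5, 0.5])

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = dict(zip(["P1", "P2", "P3"], rng.uniform(1e-4, 1e-1, 3)))
            w = dict(zip(["A1", "B2", "C3"], rng.uniform(1e-4, 1e-1, 3)))
            scored = score_configurations(
                PresenceCall("ACGTACGT", p, w), AbundanceModel(0.0, 0.5)
            )
            assert sum(c.posterior for c in scored) == pytest.approx(1.0, abs=1e-9)


class TestDecodeGoldenPath:
    def test_noise_free_decode_recovers_truth_for_all_n_up_to_4(
        self, decode_study
    ):
        """On exact expected counts every barcode isolated 1-4 times is placed
        definitively or with high confidence at exactly its true wells."""
        study = decode_study
        results = pp.PlateWellDecoder(study.barseq).fit()
        truth = truth_wells_by_barcode(study)
        placed = trusted_placements(results)
        checked = 0
        for bc, wells in truth.items():
            if len(wells) > 4:
                continue
            assert placed.get(bc, set()) == wells, bc
            checked += 1
        assert checked > 200  # the fixture exercises many barcodes

    def test_boundary_posterior_below_cutoff_is_ambiguous(self):
        m = make_matrix(
            {("ACGTACGT", "P1"): 500, ("ACGTACGT", "P2"): 490,
             ("ACGTACGT", "G1"): 500, ("ACGTACGT", "H2"): 490}
        )
        results = pp.PlateWellDecoder(
            m, min_definite=1,
            fallback_model=AbundanceModel(0.0, 1.0), pool_effects=False,
        ).fit()
        rows = results.location_table.records
        bc_rows = rows[rows["barcode"] == "ACGTACGT"]
        # symmetric abundances: both matchings near 0.5 < 0.85
        assert (bc_rows["status"] == "ambiguous").all()
        assert len(bc_rows) == 4  # all candidate wells retained

    def test_absent_barcode_reported_absent(self, decode_study):
        results = pp.PlateWellDecoder(decode_study.barseq).fit()
        rows = results.location_table.records
        statuses = rows.groupby("barcode")["status"].first()
        truth = truth_wells_by_barcode(decode_study)
        never_sorted = set(statuses.index) - set(truth)
        assert never_sorted  # the pool is larger than the collection
        assert (statuses.loc[sorted(never_sorted)] == "absent").all()

    def test_summary_mentions_status_counts(self, decode_study):
        results = pp.PlateWellDecoder(decode_study.barseq).fit()
        text = results.summary()
        assert "definite" in text and "ambiguous" in text

    def test_map_recovers_twice_isolated_barcodes_under_read_noise(self):
        """With multinomial read sampling, the MAP configuration recovers the
        true placement for at least 95 % of barcodes isolated twice."""
        params = pp.SimParams(seed=2025, n_strains=1000, n_genes=60,
                              exact_counts=False, reads_per_pool=500_000)
        study = pp.simulate_study(params, 4)
        results = pp.PlateWellDecoder(study.barseq).fit()
        truth = truth_wells_by_barcode(study)
        layout = study.layout
        n2 = correct = 0
        for bc, wells in truth.items():
            if len(wells) != 2 or bc not in results.configurations:
                continue
            n2 += 1
            best = max(results.configurations[bc], key=lambda c: c.posterior)
            placed = {
                (layout.plate_index(p), layout.well_position(w))
                for p, w in best.wells
            }
            correct += placed == wells
        assert n2 >= 40
        assert correct / n2 >= 0.95

    def test_decoding_is_equivariant_under_plate_relabeling(self, decode_study):
        """Reversing the plate order of the matrix permutes the decoded plate
        indices correspondingly and nothing else."""
        matrix = decode_study.barseq
        n = matrix.layout.n_plates
        perm = list(range(n))[::-1]
        counts = matrix.counts.copy()
        counts[:, :n] = counts[:, perm]
        relabeled = pp.BarSeqMatrix(matrix.barcodes, matrix.layout, counts)

        base = pp.PlateWellDecoder(matrix).fit().location_table.located()
        moved = pp.PlateWellDecoder(relabeled).fit().location_table.located()
        key = ["barcode", "plate", "well"]
        expected = base.assign(plate=base["plate"].map(lambda p: perm[int(p)]))
        left = expected[key].astype({"plate": int}).sort_values(key) \
                            .reset_index(drop=True)
        right = moved[key].astype({"plate": int}).sort_values(key) \
                          .reset_index(drop=True)
        pd.testing.assert_frame_equal(left, right)
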