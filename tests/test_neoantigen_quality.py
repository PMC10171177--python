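"""Cross-reactivity distance and the neoantigen quality model."""

from __future__ import annotations

import numpy as np
import pytest

from clonetrack.neoantigen_quality import (
    BindingTable,
    EpitopeSet,
    NeoantigenRecord,
    SubstitutionModel,
    compare_quality_by_immunogenicity,
    cross_reactivity_distance,
    enumerate_mutant_9mers,
    neoantigen_quality,
    quality_9mer,
)
from clonetrack.repertoire_io import ValidationError


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


PEP_A = "ACDEFGHIK"
PEP_B = "ACDEFGHIL"  # one mismatch at position 9
PEP_C = "LMNPQRSTV"


class TestDistance:
    def test_identity_is_zero(self, toy_model):
        assert cross_reactivity_distance(PEP_A, PEP_A, toy_model) == 0.0

    def test_indicator_model_reduces_to_hamming(self, hamming_model):
        for other in (PEP_B, PEP_C, "AADEFGHIK"):
            assert cross_reactivity_distance(
                PEP_A, other, hamming_model
            ) == _hamming(PEP_A, other)

    def test_single_substitution_is_weighted_matrix_entry(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0.5, 3.0, size=(20, 20))
        np.fill_diagonal(m, 0.0)
        weights = rng.uniform(0.1, 2.0, size=9)
        model = SubstitutionModel(m, weights)
        # position 9 (index 8): K -> L
        from clonetrack.neoantigen_quality import AMINO_ACIDS

        i, j = AMINO_ACIDS.index("K"), AMINO_ACIDS.index("L")
        assert cross_reactivity_distance(PEP_A, PEP_B, model) == pytest.approx(
            weights[8] * m[i, j]
        )

    def test_rejects_wrong_length_or_residue(self, hamming_model):
        with pytest.raises(ValidationError):
            cross_reactivity_distance("ACDEF", PEP_A, hamming_model)
        with pytest.raises(ValidationError):
            cross_reactivity_distance("ACDEFGHIX", PEP_A, hamming_model)

    def test_nonnegative_and_zero_only_at_identity(self, toy_model):
        rng = np.random.default_rng(1)
        from clonetrack.neoantigen_quality import AMINO_ACIDS

        for _ in range(50):
            a = "".join(rng.choice(list(AMINO_ACIDS), 9))
            b = "".join(rng.choice(list(AMINO_ACIDS), 9))
            d = cross_reactivity_distance(a, b, toy_model)
            assert d >= 0.0
            if a != b:
                assert d > 0.0


class TestWindows:
    @pytest.mark.parametrize(
        "length,mut_pos,n_windows,starts",
        [(15, 8, 7, range(1, 8)), (9, 5, 1, [1]), (27, 14, 9, range(6, 15))],
    )
    def test_window_enumeration(self, length, mut_pos, n_windows, starts):
        wt = ("ACDEFGHIKLMNPQRSTVWYACDEFGH")[:length]
        old = wt[mut_pos - 1]
        new = "W" if old != "W" else "Y"
        mt = wt[: mut_pos - 1] + new + wt[mut_pos:]
        rec = NeoantigenRecord("n1", mt, wt, mut_pos, ("HLA-A*02:01",))
        windows = enumerate_mutant_9mers(rec)
        assert len(windows) == n_windows
        assert [w.start for w in windows] == list(starts)
        for w in windows:
            assert len(w.mt) == 9 and len(w.wt) == 9
            # every window covers the substituted residue
            assert w.start <= mut_pos <= w.start + 8
            assert _hamming(w.mt, w.wt) == 1

    def test_record_must_differ_exactly_at_mut_pos(self):
        with pytest.raises(ValidationError):
            NeoantigenRecord("n1", "ACDEFGHIK", "ACDEFGHIK", 5, ())
        with pytest.raises(ValidationError):
            NeoantigenRecord("n1", "WCDEFGHIL", "ACDEFGHIK", 9, ())


class TestQuality9mer:
    def test_membership_in_epitope_set_zeroes_second_term(self, hamming_model):
        iedb = EpitopeSet([PEP_A, PEP_C])
        q = quality_9mer(PEP_A, PEP_B, iedb, hamming_model)
        assert q == cross_reactivity_distance(PEP_A, PEP_B, hamming_model)

    def test_wild_type_identity_gives_nonpositive_quality(self, hamming_model):
        iedb = EpitopeSet([PEP_C])
        q = quality_9mer(PEP_A, PEP_A, iedb, hamming_model)
        assert q == -_hamming(PEP_A, PEP_C)

    def test_toy_iedb_hand_computation(self, hamming_model):
        # WT one mismatch away; nearest of five IEDB 9-mers three away
        mt = "ACDEFGHIK"
        wt = "ACDEFGHIL"
        iedb = EpitopeSet(
            ["ACDEFHGLM", "ACDEFGLMN", "LMNPQRSTV", "YYYEFGHIK", "ACDEYYYIK"]
        )
        dists = [_hamming(mt, p) for p in iedb.nine_mers]
        assert min(dists) == 3
        assert quality_9mer(mt, wt, iedb, hamming_model) == 1 - 3

    def test_enlarging_epitope_set_never_decreases_quality(self, toy_model):
        # Q rewards proximity to known epitopes: the min distance over a
        # superset can only shrink, so Q can only rise (or stay) as the
        # epitope set grows.
        iedb_small = EpitopeSet([PEP_C])
        iedb_big = EpitopeSet([PEP_C, "ACDEFGHIW", "ACDEFGYIK"])
        q_small = quality_9mer(PEP_A, PEP_B, iedb_small, toy_model)
        q_big = quality_9mer(PEP_A, PEP_B, iedb_big, toy_model)
        assert q_big >= q_small

    def test_empty_epitope_set_rejected(self, hamming_model):
        with pytest.raises(ValidationError):
            quality_9mer(PEP_A, PEP_B, EpitopeSet([]), hamming_model)

    def test_nine_mer_subsequence_expansion(self):
        iedb = EpitopeSet.from_epitopes(["ACDEFGHIKL"])  # 10-mer -> two 9-mers
        assert sorted(iedb.nine_mers) == ["ACDEFGHIK", "CDEFGHIKL"]


def _binding_for(rec, kd_by_start):
    """BindingTable giving each window's mt 9-mer the Kd of its start."""
    kd = {}
    for w in enumerate_mutant_9mers(rec):
        if w.start in kd_by_start:
            for allele in rec.patient_hla:
                kd[(w.mt, allele)] = kd_by_start[w.start]
    return BindingTable(kd)


class TestNeoantigenQuality:
    def _record(self):
        wt = "ACDEFGHIKLMNPQR"
        mt = wt[:7] + "W" + wt[8:]
        return NeoantigenRecord("n1", mt, wt, 8, ("HLA-A*01:01",))

    def test_mean_of_two_best_binders_ignores_non_binders(self, hamming_model):
        rec = self._record()
        iedb = EpitopeSet([w.mt for w in enumerate_mutant_9mers(rec)][:1])
        # windows 1 and 2 bind; window 3 (higher quality irrelevant) does not
        binding = _binding_for(rec, {1: 50.0, 2: 500.0, 3: 100000.0})
        res = neoantigen_quality(rec, iedb, hamming_model, binding)
        qualities = {
            w.start: quality_9mer(w.mt, w.wt, iedb, hamming_model)
            for w in enumerate_mutant_9mers(rec)[:2]
        }
        expected = sum(qualities.values()) / 2
        assert res.quality == pytest.approx(expected)
        assert {wq.window.start for wq in res.selected} <= set(qualities)

    def test_two_best_selection(self, hamming_model):
        rec = self._record()
        windows = enumerate_mutant_9mers(rec)
        iedb = EpitopeSet([w.mt for w in windows])
        binding = _binding_for(rec, {w.start: 100.0 for w in windows})
        res = neoantigen_quality(rec, iedb, hamming_model, binding)
        all_q = sorted(
            (quality_9mer(w.mt, w.wt, iedb, hamming_model) for w in windows),
            reverse=True,
        )
        assert res.quality == pytest.approx(sum(all_q[:2]) / 2)

    def test_single_binder_used_alone(self, hamming_model):
        rec = self._record()
        iedb = EpitopeSet(["LMNPQRSTV"])
        binding = _binding_for(rec, {4: 3999.0})
        res = neoantigen_quality(rec, iedb, hamming_model, binding)
        [w] = enumerate_mutant_9mers(rec)[3:4]
        assert res.quality == pytest.approx(
            quality_9mer(w.mt, w.wt, iedb, hamming_model)
        )
        assert len(res.selected) == 1

    def test_no_binder_is_excluded_not_scored(self, hamming_model):
        rec = self._record()
        iedb = EpitopeSet(["LMNPQRSTV"])
        binding = _binding_for(rec, {4: 4001.0})  # above the 4000 nM cut-off
        res = neoantigen_quality(rec, iedb, hamming_model, binding)
        assert res.quality is None
        assert res.exclusion_reason == "no_predicted_binder"

    def test_invariant_to_duplicated_iedb_entries(self, hamming_model):
        rec = self._record()
        windows = enumerate_mutant_9mers(rec)
        binding = _binding_for(rec, {w.start: 10.0 for w in windows})
        iedb_a = EpitopeSet(["LMNPQRSTV", "ACDEFGHIK"])
        iedb_b = EpitopeSet(["LMNPQRSTV", "ACDEFGHIK", "LMNPQRSTV"])
        qa = neoantigen_quality(rec, iedb_a, hamming_model, binding).quality
        qb = neoantigen_quality(rec, iedb_b, hamming_model, binding).quality
        assert qa == qb


class TestRankComparison:
    def test_detects_planted_enrichment(self):
        rng = np.random.default_rng(2)
        q = np.concatenate([rng.normal(2, 1, 22), rng.normal(0, 1, 58)])
        labels = np.array([True] * 22 + [False] * 58)
        _, p = compare_quality_by_immunogenicity(q, labels)
        assert p < 0.01

    def test_requires_both_labels(self):
        with pytest.raises(ValidationError):
            compare_quality_by_immunogenicity([1.0, 2.0], [True, True])


class TestModelIO:
    def test_round_trip_through_parameter_file(self, tmp_path, toy_model):
        path = tmp_path / "model.yaml"
        toy_model.to_file(path)
        back = SubstitutionModel.from_file(path)
        np.testing.assert_allclose(back.matrix, toy_model.matrix)
        np.testing.assert_allclose(back.weights, toy_model.weights)

    def test_nonzero_diagonal_rejected(self):
        m = np.ones((20, 20))
        with pytest.raises(ValidationError):
            SubstitutionModel(m, np.ones(9))
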