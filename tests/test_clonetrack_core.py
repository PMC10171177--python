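"""The adapted expansion test, its filters and the response procedures."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from clonetrack.clonetrack_core import (
    atezolizumab_response,
    bonferroni_clones,
    booster_response,
    expansion_p_adapted,
    fisher_two_sided,
    fold_change,
    pairwise_expansion,
    qc_pass,
    rescaled_table,
    standard_fisher_p,
    vaccine_response,
)
from clonetrack.repertoire_io import (
    ConfigurationError,
    Phase,
    TreatmentWindows,
    ValidationError,
)
from clonetrack.synthetic_data import (
    SamplePlan,
    SimulationSpec,
    default_schedule,
    simulate_longitudinal_repertoire,
)
from conftest import clone, make_repertoire, make_sample
from _oracles import adapted_expansion_oracle, fisher_two_sided_oracle

WINDOWS = TreatmentWindows(
    atezolizumab_day=42, first_vaccine_day=63, first_chemo_day=147,
    booster_day=365,
)


def _patient(sample_specs):
    """sample_specs: list of (day, phase, counts dict)."""
    samples = [
        make_sample(c, sample_id=f"S{i}", day=d, phase=p)
        for i, (d, p, c) in enumerate(sample_specs)
    ]
    return make_repertoire(samples, windows=WINDOWS)


class TestAdaptedP:
    def test_fold_one_returns_exactly_one(self):
        assert expansion_p_adapted(5, 1000, 5, 1000) == 1.0

    def test_absent_in_both_returns_one(self):
        assert expansion_p_adapted(0, 10000, 0, 10000) == 1.0

    @pytest.mark.parametrize(
        "n_x,N,m_x,M",
        [(0, 10000, 30, 10000), (2, 1000, 40, 1000), (1, 500, 9, 400),
         (3, 200, 12, 300)],
    )
    def test_matches_enumeration_oracle_on_rescaled_table(self, n_x, N, m_x, M):
        expected = adapted_expansion_oracle(n_x, N, m_x, M)
        assert expansion_p_adapted(n_x, N, m_x, M) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_scipy_fisher_on_the_same_table(self):
        # independent route: scipy's two-sided convention on the rescaled table
        t = rescaled_table(2, 1000, 40, 1000)
        _, p_scipy = fisher_exact([[t.a, t.b], [t.c, t.d]])
        assert expansion_p_adapted(2, 1000, 40, 1000) == pytest.approx(
            p_scipy, rel=1e-9
        )

    @given(
        st.integers(0, 60), st.integers(1, 300),
        st.integers(0, 60), st.integers(1, 300),
    )
    def test_fold_below_two_is_exactly_one(self, n_x, N, m_x, M):
        n_x, m_x = min(n_x, N), min(m_x, M)
        if fold_change(n_x, N, m_x, M) < 2:
            assert expansion_p_adapted(n_x, N, m_x, M) == 1.0

    def test_detection_strengthens_with_later_count_once_gated(self):
        # The expansion-supporting (lower) tail of the rescaled table is
        # strictly monotone in m_x.  The two-sided tie-inclusive P tracks it
        # but can tick up by a few percent when a far-tail table crosses the
        # observed probability, so it is checked as near-monotone.
        from fractions import Fraction
        from math import comb

        n_x, N, M = 2, 1000, 1000
        prev_one = Fraction(2)
        prev_two = 1.0
        for m_x in range(4, 120):
            t = rescaled_table(n_x, N, m_x, M)
            r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
            den = comb(r1 + r2, c1)
            one_sided = sum(
                Fraction(comb(r1, k) * comb(r2, c1 - k), den)
                for k in range(max(0, c1 - r2), t.a + 1)
            )
            assert one_sided < prev_one
            prev_one = one_sided
            p = expansion_p_adapted(n_x, N, m_x, M)
            assert p <= prev_two * 1.10
            prev_two = p
        assert prev_two < 1e-15  # detection keeps strengthening overall

    def test_infinite_fold_for_de_novo_clone(self):
        assert fold_change(0, 100, 5, 100) == float("inf")
        assert fold_change(0, 100, 0, 100) == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            expansion_p_adapted(5, 4, 0, 10)
        with pytest.raises(ValidationError):
            expansion_p_adapted(0, 0, 0, 10)

    def test_half_rescaling_preserves_clone_count(self):
        t = rescaled_table(7, 1001, 50, 2000)
        assert t.a == 7
        # round-half-even: 1001/2 = 500.5 -> 500
        assert t.a + t.b == 500
        assert (t.c, t.d) == (50, 1950)


class TestStandardFisher:
    def test_matches_oracle(self):
        expected = fisher_two_sided_oracle(5, 9995, 50, 9950)
        assert standard_fisher_p(5, 10000, 50, 10000) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_scipy(self):
        _, p_scipy = fisher_exact([[5, 9995], [50, 9950]])
        assert standard_fisher_p(5, 10000, 50, 10000) == pytest.approx(
            p_scipy, rel=1e-9
        )

    def test_unchanged_counts_give_p_one(self):
        assert standard_fisher_p(5, 1000, 5, 1000) == 1.0

    def test_cache_returns_consistent_values(self):
        a = fisher_two_sided(2, 498, 40, 960)
        b = fisher_two_sided(2, 498, 40, 960)
        assert a == b


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,n,expected", [(0.5, 10, 1.0), (1e-6, 1000, 1e-3), (0.0, 7, 0.0)]
    )
    def test_examples(self, p, n, expected):
        assert bonferroni_clones(p, n) == pytest.approx(expected)

    def test_requires_at_least_one_clone(self):
        with pytest.raises(ValidationError):
            bonferroni_clones(0.5, 0)


class TestQC:
    @pytest.mark.parametrize(
        "counts,expected",
        [((3, 3, 0), True), ((2, 2, 2), False), ((5, 0, 0), False),
         ((3, 4, 5), True)],
    )
    def test_three_reads_in_two_samples(self, counts, expected):
        c = clone(1)
        rep = _patient(
            [
                (day, Phase.OTHER, {c: n} if n else {clone(2): 1})
                for day, n in zip((10, 20, 30), counts)
            ]
        )
        assert qc_pass(c, rep) is expected


class TestResponses:
    def test_identical_samples_are_null(self):
        counts = {clone(i): 10 for i in range(50)}
        rep = _patient(
            [(42, Phase.PRE_ATEZOLIZUMAB, counts),
             (63, Phase.POST_ATEZOLIZUMAB_PRE_VACCINE, dict(counts))]
        )
        call = atezolizumab_response(rep)
        assert not call.responder and not call.expanded_clones

    def test_missing_anchor_raises_configuration_error(self):
        rep = _patient([(98, Phase.POST_PRIMING, {clone(1): 5})])
        with pytest.raises(ConfigurationError):
            atezolizumab_response(rep)

    def test_vaccine_excludes_clones_seen_before_vaccination(self):
        hot = clone(99)
        bg = {clone(i): 100 for i in range(20)}
        rep = _patient(
            [
                (42, Phase.PRE_ATEZOLIZUMAB, {**bg, hot: 1}),
                (63, Phase.POST_ATEZOLIZUMAB_PRE_VACCINE, dict(bg)),
                (98, Phase.POST_PRIMING, {**bg, hot: 500}),
            ]
        )
        call = vaccine_response(rep)
        assert hot not in call.expanded_clones

    def test_vaccine_detects_de_novo_expansion(self):
        hot = clone(99)
        bg = {clone(i): 100 for i in range(20)}
        rep = _patient(
            [
                (42, Phase.PRE_ATEZOLIZUMAB, dict(bg)),
                (63, Phase.POST_ATEZOLIZUMAB_PRE_VACCINE, dict(bg)),
                (98, Phase.POST_PRIMING, {**bg, hot: 300}),
                (126, Phase.POST_PRIMING, {**bg, hot: 400}),
            ]
        )
        call = vaccine_response(rep)
        assert call.responder and hot in call.expanded_clones

    def test_spiked_simulation_recovers_expanded_clones(self):
        spec = SimulationSpec(seed=11, schedule=default_schedule(100_000))
        rep, truth = simulate_longitudinal_repertoire(spec)
        call = vaccine_response(rep)
        detected = set(call.expanded_clones)
        assert detected <= truth.spiked_clones
        assert len(detected & truth.spiked_clones) >= 18  # recall >= 0.9

    def test_booster_direction_filter_blocks_contraction(self):
        c = clone(1)
        bg = {clone(i): 1000 for i in range(2, 12)}
        rep = _patient(
            [
                (360, Phase.PRE_BOOSTER, {**bg, c: 50}),
                (393, Phase.POST_BOOSTER, {**bg, c: 5}),
            ]
        )
        call = booster_response(rep, {c})
        assert not call.responder

    def test_booster_detects_re_expansion_without_fold_gate(self):
        c = clone(1)
        bg = {clone(i): 995 for i in range(2, 12)}
        rep = _patient(
            [
                (360, Phase.PRE_BOOSTER, {**bg, c: 50}),
                (393, Phase.POST_BOOSTER, {**bg, c: 150}),
            ]
        )
        call = booster_response(rep, {c})
        assert call.responder
        r = call.expanded_clones[c]
        expected = fisher_two_sided_oracle(r.n_x, r.N - r.n_x,
                                           r.m_x, r.M - r.m_x)
        assert r.p_raw == pytest.approx(expected, abs=1e-12)

    def test_booster_empty_primed_set_is_non_responder(self):
        rep = _patient(
            [(360, Phase.PRE_BOOSTER, {clone(1): 5}),
             (393, Phase.POST_BOOSTER, {clone(1): 5})]
        )
        call = booster_response(rep, set())
        assert not call.responder and not call.expanded_clones

    def test_atezolizumab_and_vaccine_sets_disjoint_for_pre_vaccine_clones(self):
        # a clone expanded by the checkpoint dose is visible pre-vaccine and
        # therefore can never enter the vaccine-expanded set
        hot = clone(99)
        bg = {clone(i): 100 for i in range(30)}
        rep = _patient(
            [
                (42, Phase.PRE_ATEZOLIZUMAB, dict(bg)),
                (63, Phase.POST_ATEZOLIZUMAB_PRE_VACCINE, {**bg, hot: 400}),
                (98, Phase.POST_PRIMING, {**bg, hot: 800}),
            ]
        )
        atezo = atezolizumab_response(rep)
        vaccine = vaccine_response(rep)
        assert hot in atezo.expanded_clones
        assert not set(atezo.expanded_clones) & set(vaccine.expanded_clones)


class TestPairwise:
    def test_bonferroni_factor_is_union_size(self):
        baseline = make_sample({clone(i): 10 for i in range(5)},
                               sample_id="A", day=0)
        later = make_sample({clone(i): 10 for i in range(3, 10)},
                            sample_id="B", day=1)
        results = pairwise_expansion(baseline, later)
        union = set(baseline.counts) | set(later.counts)
        for r in results:
            if r.p_raw < 1.0:
                assert r.p_adjusted == pytest.approx(
                    min(1.0, r.p_raw * len(union))
                )

    def test_null_multinomial_pair_flags_nothing(self):
        sched = (SamplePlan(1, Phase.OTHER, 20000),
                 SamplePlan(2, Phase.OTHER, 20000))
        spec = SimulationSpec(seed=3, n_spikes=0, n_clones=4000,
                              schedule=sched)
        rep, _ = simulate_longitudinal_repertoire(spec)
        results = pairwise_expansion(rep.samples[0], rep.samples[1])
        assert sum(r.significant for r in results) == 0
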