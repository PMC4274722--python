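"""Indicator scores, consensus, robust filter and entry verdicts."""

import numpy as np
import pytest

from xtalbio.classifier import (
    Call,
    InterfaceCall,
    Verdict,
    consensus_call,
    core_rim_indicator,
    core_surface_indicator,
    entry_verdict,
    geometry_indicator,
    robust_filter,
)
from xtalbio.evolution import EntropyProfile
from xtalbio.interfaces import AsaResult, Interface
from xtalbio.symmetry import SymOperator, classify_operator


def make_interface(burials_a, burials_b=()):
    """Interface with prescribed per-residue burial ratios.

    Every residue gets unbound ASA 20 (well above the surface threshold)
    and bound ASA scaled by 1 - burial.
    """
    burials_a = np.asarray(burials_a, float)
    burials_b = np.asarray(burials_b if len(burials_b) else burials_a, float)

    def asa(n):
        return AsaResult(np.full(n, 20.0), np.full(n, 20.0), 1.4, 960)

    return Interface(
        id=1, chain_a="A", chain_b="B", op_b=SymOperator(),
        operator_class=classify_operator(SymOperator()),
        area=500.0, contacts=[],
        asa_a_unbound=asa(len(burials_a)), asa_b_unbound=asa(len(burials_b)),
        asa_a_bound=20.0 * (1 - burials_a), asa_b_bound=20.0 * (1 - burials_b),
    )


def profile(entropies):
    return EntropyProfile(np.asarray(entropies, float), 40, 0.5)


# a 12-residue partner: 4 deeply buried, 3 partially, 5 untouched
BURIED = [1.0, 1.0, 0.98, 0.97, 0.5, 0.4, 0.3, 0.0, 0.0, 0.0, 0.0, 0.0]


class TestGeometryIndicator:
    def test_no_core_is_xtal(self):
        n, call = geometry_indicator(make_interface([0.2] * 8))
        assert (n, call) == (0, Call.XTAL)

    def test_six_core_flip(self):
        # six or more core residues (summed over partners) call biological
        iface6 = make_interface([1.0, 1.0, 1.0, 0.0], [1.0, 1.0, 1.0, 0.0])
        assert geometry_indicator(iface6) == (6, Call.BIO)
        iface5 = make_interface([1.0, 1.0, 1.0, 0.0], [1.0, 1.0, 0.0, 0.0])
        assert geometry_indicator(iface5) == (5, Call.XTAL)

    def test_lowering_cutoff_never_flips_bio_to_xtal(self):
        iface = make_interface(BURIED)
        calls = [geometry_indicator(iface, cutoff)[1]
                 for cutoff in (8, 6, 4, 2, 1)]
        if Call.BIO in calls:
            first = calls.index(Call.BIO)
            assert all(c == Call.BIO for c in calls[first:])


class TestCoreRimIndicator:
    def test_conserved_core_ratio_zero(self):
        iface = make_interface(BURIED)
        ents = [0.0] * 4 + [1.5] * 3 + [1.0] * 5
        ratio, call = core_rim_indicator(iface, profile(ents), profile(ents))
        assert ratio == pytest.approx(0.0)
        assert call == Call.BIO

    def test_equal_core_and_rim_ratio_one(self):
        iface = make_interface(BURIED)
        ents = [1.0] * 12
        ratio, call = core_rim_indicator(iface, profile(ents), profile(ents))
        assert ratio == pytest.approx(1.0)
        assert call == Call.XTAL

    def test_half_ratio(self):
        iface = make_interface(BURIED)
        ents = [0.5] * 4 + [1.0] * 3 + [2.0] * 5
        ratio, _ = core_rim_indicator(iface, profile(ents), profile(ents))
        assert ratio == pytest.approx(0.5)

    def test_insufficient_profile_abstains(self):
        iface = make_interface(BURIED)
        weak = EntropyProfile(np.ones(12), 3, 0.5, insufficient=True)
        assert core_rim_indicator(iface, weak, weak) == (None, Call.NOPRED)

    def test_empty_rim_abstains(self):
        iface = make_interface([1.0, 1.0, 0.0, 0.0])
        ents = [0.0, 0.0, 1.0, 1.0]
        assert core_rim_indicator(iface, profile(ents), profile(ents))[1] \
            == Call.NOPRED


class TestCoreSurfaceIndicator:
    def test_constant_profile_degenerate(self):
        iface = make_interface(BURIED)
        flat = profile([1.0] * 12)
        score, call = core_surface_indicator(iface, flat, flat, seed=1)
        assert (score, call) == (None, Call.NOPRED)

    def test_conserved_core_negative_score(self, rng):
        iface = make_interface(BURIED)
        ents = [0.0] * 4 + [1.5] * 3 + list(rng.uniform(1.0, 2.0, 5))
        p = profile(ents)
        score, call = core_surface_indicator(iface, p, p, seed=1)
        assert score < 0 and call == Call.BIO

    def test_seed_stability_at_large_sample_count(self, rng):
        iface = make_interface(BURIED)
        ents = [0.2] * 4 + [1.0] * 3 + list(rng.uniform(0.2, 2.0, 5))
        p = profile(ents)
        s1, _ = core_surface_indicator(iface, p, p, n_samples=10_000, seed=1)
        s2, _ = core_surface_indicator(iface, p, p, n_samples=10_000, seed=2)
        assert abs(s1 - s2) < 0.1

    def test_small_surface_pool_abstains(self):
        iface = make_interface([1.0] * 8 + [0.0] * 2)
        p = profile([0.5] * 8 + [1.0, 2.0])
        assert core_surface_indicator(iface, p, p, seed=1)[1] == Call.NOPRED

    def test_sample_count_validation(self):
        iface = make_interface(BURIED)
        p = profile([1.0] * 12)
        with pytest.raises(ValueError):
            core_surface_indicator(iface, p, p, n_samples=50, seed=1)


class TestConsensus:
    @pytest.mark.parametrize("calls,expected", [
        ((Call.BIO, Call.BIO, Call.XTAL), Call.BIO),
        ((Call.XTAL, Call.XTAL, Call.BIO), Call.XTAL),
        ((Call.XTAL, Call.NOPRED, Call.NOPRED), Call.XTAL),
        ((Call.BIO, Call.NOPRED, Call.NOPRED), Call.BIO),
        ((Call.NOPRED, Call.NOPRED, Call.NOPRED), Call.NOPRED),
        # ties break toward the core-surface vote when it exists
        ((Call.BIO, Call.NOPRED, Call.XTAL), Call.XTAL),
        ((Call.XTAL, Call.NOPRED, Call.BIO), Call.BIO),
        # otherwise toward geometry
        ((Call.BIO, Call.XTAL, Call.NOPRED), Call.BIO),
    ])
    def test_vote_table(self, calls, expected):
        assert consensus_call(*calls) == expected


def make_call(cg, cr, cs, score, consensus):
    return InterfaceCall(1, "A", "B", "x,y,z|0,0,0", "AU", 700.0, 8,
                         0.4, score, cg, cr, cs, consensus)


def entry(resolution=1.8, r_free=0.22):
    from xtalbio.fixtures import FixtureSpec, make_crystal_fixture

    st, _ = make_crystal_fixture(FixtureSpec(
        spacegroup_symbol="P 1", chain_length=12,
        interface_target="NONE", seed=0))
    st.resolution = resolution
    st.r_free = r_free
    return st


class TestRobustFilter:
    UNANIMOUS_BIO = make_call(Call.BIO, Call.BIO, Call.BIO, -4.0, Call.BIO)

    def test_qualifying_bio_call(self):
        assert robust_filter(entry(), self.UNANIMOUS_BIO, n_homologs=45)

    def test_score_threshold_for_bio(self):
        weak = make_call(Call.BIO, Call.BIO, Call.BIO, -2.0, Call.BIO)
        assert not robust_filter(entry(), weak, 45)
        boundary = make_call(Call.BIO, Call.BIO, Call.BIO, -3.3, Call.BIO)
        assert not robust_filter(entry(), boundary, 45)

    def test_score_threshold_for_xtal(self):
        good = make_call(Call.XTAL, Call.XTAL, Call.XTAL, 0.2, Call.XTAL)
        assert robust_filter(entry(), good, 45)
        boundary = make_call(Call.XTAL, Call.XTAL, Call.XTAL, 0.15, Call.XTAL)
        assert not robust_filter(entry(), boundary, 45)

    def test_unanimity_required(self):
        split = make_call(Call.BIO, Call.XTAL, Call.BIO, -4.0, Call.BIO)
        assert not robust_filter(entry(), split, 45)
        abstain = make_call(Call.BIO, Call.NOPRED, Call.BIO, -4.0, Call.BIO)
        assert not robust_filter(entry(), abstain, 45)

    def test_homolog_count_boundary(self):
        assert robust_filter(entry(), self.UNANIMOUS_BIO, 30)
        assert not robust_filter(entry(), self.UNANIMOUS_BIO, 29)

    def test_structure_quality_boundaries(self):
        assert not robust_filter(entry(resolution=2.5), self.UNANIMOUS_BIO, 45)
        assert robust_filter(entry(resolution=2.49), self.UNANIMOUS_BIO, 45)
        assert not robust_filter(entry(r_free=0.30), self.UNANIMOUS_BIO, 45)
        assert not robust_filter(entry(resolution=None), self.UNANIMOUS_BIO, 45)

    def test_tightening_shrinks_robust_set(self):
        calls = [make_call(Call.BIO, Call.BIO, Call.BIO, s, Call.BIO)
                 for s in np.linspace(-6, -1, 11)]
        loose = sum(robust_filter(entry(), c, 45, bio_score=-3.3)
                    for c in calls)
        tight = sum(robust_filter(entry(), c, 45, bio_score=-4.5)
                    for c in calls)
        assert tight <= loose


class TestEntryVerdict:
    def test_all_xtal_monomeric(self):
        calls = [make_call(Call.XTAL, Call.XTAL, Call.XTAL, 1.0, Call.XTAL)]
        assert entry_verdict(calls) == Verdict.MONOMERIC

    def test_one_bio_among_many(self):
        calls = [make_call(Call.XTAL, Call.XTAL, Call.XTAL, 1.0, Call.XTAL)
                 for _ in range(10)]
        calls.append(make_call(Call.BIO, Call.BIO, Call.BIO, -4.0, Call.BIO))
        assert entry_verdict(calls) == Verdict.MULTIMERIC

    def test_empty_list_monomeric(self):
        assert entry_verdict([]) == Verdict.MONOMERIC
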