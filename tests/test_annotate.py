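"""Retention indices, the library-score gate and consensus screening."""

import itertools

import pytest
from hypothesis import given, strategies as st

from breathvoc import (AnnotationConfig, ChemClass, CompoundRecord, Peak,
                       PeakGroup, PeakTable, Platform, Tier, compute_ri,
                       library_gate, match_ions, predict_ei_ions,
                       predict_pci_ions, screen_candidates)
from breathvoc.errors import ExtrapolationError, InputError

LADDER = [(n, 1.0 + 0.9 * (n - 5)) for n in range(5, 21)]  # C5..C20


def table(platform, mzs, ri=None, intensity=50.0):
    return PeakTable(Platform(platform),
                     [Peak(float(m), intensity, retention_index=ri) for m in mzs])


class TestComputeRi:
    def test_anchor_alkane_is_exact(self):
        assert compute_ri(LADDER[0][1], LADDER) == pytest.approx(500.0)
        assert compute_ri(LADDER[-1][1], LADDER) == pytest.approx(2000.0)

    def test_midpoint_between_c12_and_c13(self):
        rt = (LADDER[7][1] + LADDER[8][1]) / 2
        assert compute_ri(rt, LADDER) == pytest.approx(1250.0)

    def test_hand_computed_placement(self):
        # rt 30% of the way from C7 to C8 -> RI 730
        rt = LADDER[2][1] + 0.3 * (LADDER[3][1] - LADDER[2][1])
        assert compute_ri(rt, LADDER) == pytest.approx(730.0)

    def test_no_silent_extrapolation(self):
        with pytest.raises(ExtrapolationError):
            compute_ri(0.5, LADDER)
        with pytest.raises(ExtrapolationError):
            compute_ri(99.0, LADDER)

    def test_rejects_unsorted_ladder(self):
        bad = [(5, 1.0), (6, 0.9), (7, 2.0)]
        with pytest.raises(InputError):
            compute_ri(1.5, bad)


class TestLibraryGate:
    def test_below_800_needs_cross_platform(self):
        assert library_gate(750, 820) is True

    def test_boundary_is_strict(self):
        assert library_gate(800, 800) is False
        assert library_gate(1000, 1000) is False
        assert library_gate(799, 1000) is True

    def test_scores_validated(self):
        with pytest.raises(InputError):
            library_gate(-1, 500)
        with pytest.raises(InputError):
            library_gate(500, 1001)


class TestMatchIons:
    def test_propanal_ei_fragment_matches(self, propanal):
        ev = match_ions(predict_ei_ions(propanal),
                        table("EI", [29.1], ri=489))
        assert ev.matched
        assert ev.matched_ions == [(29, 29.1, 50.0)]

    def test_empty_peak_table_never_matches(self, propanal):
        ev = match_ions(predict_ei_ions(propanal), table("EI", [], ri=489))
        assert not ev.matched and ev.matched_ions == []

    def test_decoy_shift_defeats_matching(self, acetic_acid):
        preds = predict_pci_ions(acetic_acid)
        shifted = table("PCI", [p.mz + 5 for p in preds], ri=627)
        assert not match_ions(preds, shifted).matched

    def test_platform_mismatch_is_usage_error(self, propanal):
        with pytest.raises(InputError):
            match_ions(predict_ei_ions(propanal), table("PCI", [29], ri=489))

    def test_base_prediction_must_match(self, acetic_acid):
        # PCI base peak is M+H 61; offering only a decoy peak fails
        preds = predict_pci_ions(acetic_acid)
        assert not match_ions(preds, table("PCI", [200], ri=627)).matched
        assert match_ions(preds, table("PCI", [61], ri=627)).matched


@pytest.fixture
def acetic_group():
    return PeakGroup(tables={
        Platform.EI: table("EI", [60, 43], ri=627),
        Platform.PCI: table("PCI", [61], ri=627),
        Platform.SIFT_H3O: table("SIFT_H3O", [61, 79, 97]),
    }, observed_ri=627.0, feature_id="RT15.59")


class TestScreenCandidates:
    def test_acetic_acid_beats_ammonium_acetate(self, acetic_group, acetic_acid):
        ammonium = CompoundRecord("ammonium acetate", "C2H7NO2", ChemClass.ACID)
        assert ammonium.molecular_mass == 77
        results = screen_candidates(acetic_group, [ammonium, acetic_acid])
        assert results[0].candidate.name == "acetic acid"
        assert results[0].tier is Tier.CONFIRMED
        rejected = results[-1]
        assert rejected.candidate.name == "ammonium acetate"
        assert rejected.tier is Tier.REJECTED
        assert any(e.contradicts for e in rejected.evidence)

    def test_propanal_confirmed_with_ri(self, propanal, acetone):
        group = PeakGroup(tables={
            Platform.EI: table("EI", [58, 29], ri=489),
            Platform.PCI: table("PCI", [59], ri=489),
            Platform.SIFT_NO: table("SIFT_NO", [57]),
        }, observed_ri=489.0)
        results = screen_candidates(group, [acetone, propanal])
        top = results[0]
        assert top.candidate.name == "propanal"
        assert top.tier is Tier.CONFIRMED

    def test_two_platforms_without_ri_is_probable(self, propanal):
        group = PeakGroup(tables={
            Platform.EI: table("EI", [58, 29], ri=489),
            Platform.PCI: table("PCI", [59], ri=489),
        }, observed_ri=None)
        (res,) = screen_candidates(group, [propanal])
        assert res.tier is Tier.PROBABLE

    def test_single_platform_is_tentative(self, propanal):
        group = PeakGroup(tables={Platform.PCI: table("PCI", [59], ri=489)})
        (res,) = screen_candidates(group, [propanal])
        assert res.tier is Tier.TENTATIVE

    def test_ethylphenol_isomers_ambiguous_until_ri_separates(self):
        e2 = CompoundRecord("2-ethylphenol", "C8H10O", ChemClass.PHENOL,
                            reference_ri=1286.0, substituted_benzene=True)
        e4 = CompoundRecord("4-ethylphenol", "C8H10O", ChemClass.PHENOL,
                            reference_ri=1323.0, substituted_benzene=True)
        sift_only = PeakGroup(tables={
            Platform.SIFT_H3O: table("SIFT_H3O", [123, 141, 159]),
            Platform.SIFT_NO: table("SIFT_NO", [122, 140, 158]),
        })
        results = screen_candidates(sift_only, [e2, e4])
        by_name = {r.candidate.name: r for r in results}
        assert by_name["2-ethylphenol"].ambiguity_set == ["4-ethylphenol"]
        assert by_name["4-ethylphenol"].ambiguity_set == ["2-ethylphenol"]

        with_ri = PeakGroup(tables=dict(sift_only.tables), observed_ri=1286.0)
        results = screen_candidates(with_ri, [e2, e4])
        by_name = {r.candidate.name: r for r in results}
        assert by_name["2-ethylphenol"].ambiguity_set == []
        assert results[0].candidate.name == "2-ethylphenol"

    def test_permutation_invariant(self, acetic_group, acetic_acid, propanal,
                                   acetone):
        candidates = [acetic_acid, propanal, acetone]
        orders = [screen_candidates(acetic_group, list(perm))
                  for perm in itertools.permutations(candidates)]
        names = [[r.candidate.name for r in res] for res in orders]
        assert all(n == names[0] for n in names)

    def test_adding_matched_platform_never_lowers_tier(self, propanal):
        from breathvoc.records import TIER_RANK
        small = PeakGroup(tables={
            Platform.EI: table("EI", [58, 29], ri=489)}, observed_ri=489.0)
        bigger = PeakGroup(tables={
            Platform.EI: table("EI", [58, 29], ri=489),
            Platform.PCI: table("PCI", [59], ri=489)}, observed_ri=489.0)
        (before,) = screen_candidates(small, [propanal])
        (after,) = screen_candidates(bigger, [propanal])
        assert TIER_RANK[after.tier] <= TIER_RANK[before.tier]

    def test_all_contradicted_never_outranks_a_match(self, acetic_group,
                                                     acetic_acid):
        decoy = CompoundRecord("decoy", "C10H20O", ChemClass.KETONE)
        results = screen_candidates(acetic_group, [decoy, acetic_acid])
        names = [r.candidate.name for r in results]
        assert names.index("acetic acid") < names.index("decoy")

    def test_empty_candidates_rejected(self, acetic_group):
        with pytest.raises(InputError):
            screen_candidates(acetic_group, [])


@given(st.floats(min_value=1.01, max_value=14.4))
def test_ri_is_monotone_in_rt(rt):
    lo = compute_ri(rt, LADDER)
    hi = compute_ri(rt + 0.05, LADDER)
    assert hi > lo
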