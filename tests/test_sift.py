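"""SIFT-MS reaction channels, precursor series and MIM quantitation."""

import pytest
from hypothesis import given, strategies as st

from breathvoc import (ChemClass, CompoundRecord, IntensityClass,
                       KineticEntry, precursor_series,
                       predict_sift_products, quantify_mim)
from breathvoc.errors import (UndefinedStatisticError,
                              UnsupportedChannelError)


def test_precursor_hydrate_series():
    assert precursor_series("H3O+") == [19, 37, 55, 73]
    assert precursor_series("NO+") == [30, 48, 66]
    series = precursor_series("H3O+")
    assert series[-1] - series[0] == 54  # three 18 Da hydrate steps


def test_unknown_precursor_lists_supported():
    with pytest.raises(UnsupportedChannelError, match="H3O"):
        precursor_series("O2+")


def test_acid_h3o_protonation_and_hydrates(acetic_acid):
    got = predict_sift_products(acetic_acid, "H3O+")
    assert sorted(p.mz for p in got) == [61, 79, 97]
    base = [p for p in got if p.intensity_class is IntensityClass.BASE]
    assert len(base) == 1 and base[0].mz == 61


def test_alcohol_h3o_adds_dehydration(butanol):
    got = {p.transform: p.mz for p in predict_sift_products(butanol, "H3O+")}
    assert got["M+H"] == 75
    assert got["M-17"] == 57  # [M+H-H2O]+
    assert got["M+H+1H2O"] == 93 and got["M+H+2H2O"] == 111


def test_phenol_no_electron_transfer(phenol):
    got = predict_sift_products(phenol, "NO+")
    channels = {p.channel: p.mz for p in got}
    assert channels["electron-transfer"] == 94
    adducts = sorted(p.mz for p in got if p.channel == "water-adduct")
    assert adducts == [112, 130]


def test_saturated_aldehyde_no_hydride_abstraction(heptanal):
    got = predict_sift_products(heptanal, "NO+")
    assert [p.mz for p in got] == [113]
    assert got.ions[0].channel == "hydride-abstraction"
    assert not got.dissociative_ionisation


def test_acid_no_adduct_with_dissociative_flag(butanoic_acid):
    got = predict_sift_products(butanoic_acid, "NO+")
    assert [p.mz for p in got] == [118]  # M+NO = 88 + 30
    assert got.dissociative_ionisation  # fragments from the kinetic library


def test_unsupported_class_precursor_pair(benzaldehyde):
    with pytest.raises(UnsupportedChannelError):
        predict_sift_products(benzaldehyde, "NO+")


def test_channels_depend_only_on_class_not_intensity(acetic_acid):
    # same class, different compound: same transform labels
    propanoic = CompoundRecord("propanoic acid", "C3H6O2", ChemClass.ACID)
    a = [p.transform for p in predict_sift_products(acetic_acid, "H3O+")]
    b = [p.transform for p in predict_sift_products(propanoic, "H3O+")]
    assert a == b


@given(m=st.integers(min_value=46, max_value=250))
def test_h3o_hydrate_series_is_arithmetic_from_mh(m):
    # formula CH(m-28)O has nominal mass exactly m
    acid = CompoundRecord("a", {"C": 1, "H": m - 28, "O": 1}, ChemClass.ACID)
    assert acid.molecular_mass == m
    got = sorted(p.mz for p in predict_sift_products(acid, "H3O+"))
    assert got == [m + 1, m + 19, m + 37]


def _entry(k=3e-9):
    return KineticEntry("butanal", "H3O+", k, [(73, 1.0)])


def test_quantify_mim_hand_computed_value():
    # ratio 7.5e-4 / (k t N) = 7.5e-4 / (3e-9 * 0.01 * 2.5e16) = 1e-9 -> 1 ppbv
    ppbv = quantify_mim(product_counts=600.0, precursor_counts=8e5,
                        kinetics=_entry(), reaction_time=0.01,
                        number_density=2.5e16)
    assert ppbv == pytest.approx(1.0)


def test_quantify_mim_linearity_and_zero():
    kw = dict(precursor_counts=8e5, kinetics=_entry(),
              reaction_time=0.01, number_density=2.5e16)
    one = quantify_mim(600.0, **kw)
    assert quantify_mim(1200.0, **kw) == pytest.approx(2 * one)
    assert quantify_mim(0.0, **kw) == 0.0
    # degree -1 in precursor counts
    kw2 = dict(kw, precursor_counts=4e5)
    assert quantify_mim(600.0, **kw2) == pytest.approx(2 * one)


def test_quantify_mim_zero_precursor_undefined():
    with pytest.raises(UndefinedStatisticError):
        quantify_mim(600.0, 0.0, _entry(), 0.01, 2.5e16)


def test_kinetic_entry_validates_branching():
    with pytest.raises(Exception):
        KineticEntry("x", "H3O+", 3e-9, [(73, 0.6), (91, 0.6)])
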