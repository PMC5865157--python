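import pytest

from breathvoc import ChemClass, CompoundRecord


def compound(name, formula, chem_class, ri=None, **kw):
    return CompoundRecord(name=name, formula=formula, chem_class=chem_class,
                          reference_ri=ri, **kw)


@pytest.fixture
def propanal():
    return compound("propanal", "C3H6O", ChemClass.ALDEHYDE_SATURATED, ri=489.0)


@pytest.fixture
def acetone():
    return compound("acetone", "C3H6O", ChemClass.KETONE, ri=498.0)


@pytest.fixture
def heptanal():
    return compound("heptanal", "C7H14O", ChemClass.ALDEHYDE_SATURATED, ri=918.0)


@pytest.fixture
def acetic_acid():
    return compound("acetic acid", "C2H4O2", ChemClass.ACID, ri=627.0)


@pytest.fixture
def butanoic_acid():
    return compound("butanoic acid", "C4H8O2", ChemClass.ACID, ri=821.0)


@pytest.fixture
def phenol():
    return compound("phenol", "C6H6O", ChemClass.PHENOL, ri=995.0)


@pytest.fixture
def benzaldehyde():
    return compound("benzaldehyde", "C7H6O", ChemClass.AROMATIC, ri=962.0,
                    substituted_benzene=True)


@pytest.fixture
def butanol():
    return compound("1-butanol", "C4H10O", ChemClass.ALCOHOL_PRIMARY, ri=674.0)
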