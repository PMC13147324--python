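import numpy as np
import pytest

from saftsol import default_database
from saftsol.parameters import MeltingProps, PureComponentParams


@pytest.fixture(scope="session")
def db():
    return default_database()


@pytest.fixture(scope="session")
def ibu(db):
    return db.component("IBU")


@pytest.fixture(scope="session")
def ibu_melting(db):
    return db.melting_props("IBU")


@pytest.fixture(scope="session")
def ethanol(db):
    return db.component("EtOH")


@pytest.fixture(scope="session")
def acetone(db):
    return db.component("ACT")


@pytest.fixture(scope="session")
def water(db):
    return db.component("WAT")


@pytest.fixture
def nonassoc_pair():
    """Cheap non-associating drug/solvent pair for fast sweeps."""
    api = PureComponentParams(
        id="NONASSOC-API", name="nonassociating model drug", m_seg=6.0,
        sigma=3.4, u_kB=290.0, eps_AB_kB=0.0, kappa_AB=0.0,
        assoc_scheme="none", Mw=250.0,
    )
    mp = MeltingProps(T_SL=400.0, dH_SL=30000.0, dCp_SL=75.0)
    solvent = PureComponentParams(
        id="NONASSOC-SOLV", name="nonassociating model solvent", m_seg=2.5,
        sigma=3.6, u_kB=240.0, eps_AB_kB=0.0, kappa_AB=0.0,
        assoc_scheme="none", Mw=80.0,
    )
    return api, mp, solvent


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
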