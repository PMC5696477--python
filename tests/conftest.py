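import warnings

import pytest

from jetcool import synthetic
from jetcool.structure import infer_roles


@pytest.fixture(scope="session")
def table1():
    """(records, types, distributions) of the packaged YG reference table."""
    return synthetic.table1_fixture()


@pytest.fixture(scope="session")
def yg_groups():
    return synthetic.yg_side_chain_groups()


def _build(dihedrals, residue="YG", label=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.build_dipeptide_geometry(dihedrals, residue=residue, label=label)


@pytest.fixture(scope="session")
def build_geometry():
    """Builder callable that silences steric-clash warnings."""
    return _build


@pytest.fixture(scope="session")
def folded_yg():
    """Folded gamma_D toy conformer (yg1-like) with its role map."""
    geom = _build(synthetic.YG1_FOLD_DIHEDRALS, "YG", label="yg1_like")
    return geom, infer_roles(geom)


@pytest.fixture(scope="session")
def extended_pi_yg():
    """Extended epsilon_D toy conformer with an NH...pi contact (yg26-like)."""
    geom = _build(synthetic.YG26_EXTENDED_DIHEDRALS, "YG", label="yg26_like")
    return geom, infer_roles(geom)


@pytest.fixture(scope="session")
def b_terminus_yg():
    """Folded gamma_L toy conformer with a B-type amino terminus (yg6-like)."""
    geom = _build(synthetic.YG6_B_DIHEDRALS, "YG", label="yg6_like")
    return geom, infer_roles(geom)
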