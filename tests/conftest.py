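"""Shared synthetic fixtures: helices, toy domains, and built fusions."""

import numpy as np
import pytest

from helixfuse.fixtures import make_two_helix_domain
from helixfuse.fusion_design import build_fusion_model, plan_terminal_fusion
from helixfuse.helix_geometry import assign_helices, build_ideal_helix


@pytest.fixture(scope="session")
def ideal_helix20():
    return build_ideal_helix(20)


@pytest.fixture(scope="session")
def donor_acceptor():
    donor = make_two_helix_domain()
    donor.id = "donor"
    acceptor = make_two_helix_domain()
    acceptor.id = "acceptor"
    return donor, acceptor


@pytest.fixture(scope="session")
def helix_pair(donor_acceptor):
    donor, acceptor = donor_acceptor
    dh = assign_helices(donor.chains[0])[-1]   # C-terminal donor helix
    ah = assign_helices(acceptor.chains[0])[0]  # N-terminal acceptor helix
    return dh, ah


def plan_and_build(donor, dh, acceptor, ah, n_insert=0, **kw):
    design = plan_terminal_fusion(donor, dh, dh.end, acceptor, ah, ah.start,
                                  n_insert=n_insert, **kw)
    build_fusion_model(design)
    return design


@pytest.fixture()
def fused_design(donor_acceptor, helix_pair):
    donor, acceptor = donor_acceptor
    dh, ah = helix_pair
    return plan_and_build(donor, dh, acceptor, ah, n_insert=0)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
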