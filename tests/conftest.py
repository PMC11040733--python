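import numpy as np
import pytest

from asmgo import ForceFieldParams, build_topology, fixtures


@pytest.fixture(scope="session")
def helix():
    return fixtures.make_helix_chain(10, seed=0)


@pytest.fixture(scope="session")
def hairpin():
    return fixtures.make_hairpin_chain(16, seed=0)


@pytest.fixture(scope="session")
def ring5():
    return fixtures.make_cn_ring(5, n_residues=16, seed=1)


@pytest.fixture(scope="session")
def ring3():
    return fixtures.make_cn_ring(3, n_residues=12, seed=2)


@pytest.fixture(scope="session")
def stacked_rings():
    return fixtures.make_stacked_rings(3, n_residues=16, seed=1)


@pytest.fixture(scope="session")
def heterodimer():
    return fixtures.make_heterodimer(14, 14, seed=0)


@pytest.fixture(scope="session")
def two_state():
    return fixtures.make_two_state_chain(16, seed=0)


@pytest.fixture(scope="session")
def ring5_topology(ring5):
    return build_topology(ring5)


@pytest.fixture(scope="session")
def hairpin_topology(hairpin):
    return build_topology(hairpin)


@pytest.fixture
def params():
    return ForceFieldParams()


def brute_force_contacts(conformation, params=None):
    """O(N^2 A^2) reference contact detection: independent oracle."""
    params = params or ForceFieldParams()
    residues = [
        (ci, res)
        for ci, chain in enumerate(conformation.chains)
        for res in chain.residues
    ]
    found = set()
    for a in range(len(residues)):
        ca_chain, ra = residues[a]
        for b in range(a + 1, len(residues)):
            cb_chain, rb = residues[b]
            if ca_chain == cb_chain and rb.index - ra.index < params.exclusion_window:
                continue
            hit = False
            for at_a in ra.atoms:
                if params.heavy_atoms_only and at_a.is_hydrogen:
                    continue
                for at_b in rb.atoms:
                    if params.heavy_atoms_only and at_b.is_hydrogen:
                        continue
                    d = np.linalg.norm(at_a.coords - at_b.coords)
                    if d <= params.contact_scale * (at_a.vdw_radius + at_b.vdw_radius):
                        hit = True
                        break
                if hit:
                    break
            if hit:
                kind = "intra" if ca_chain == cb_chain else "inter"
                found.add((ca_chain, ra.index, cb_chain, rb.index, kind))
    return found
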