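"""Elastic-network Hessian, covariance and perturbation-response maps."""

import numpy as np
import pytest

from mitotox.enm import (
    ElasticNetwork,
    bound_condition,
    build_hessian,
    contact_count,
    count_zero_modes,
    covariance_from_hessian,
    is_connected,
    prs_map,
    read_calpha_pdb,
    receptor_mask,
)
from mitotox.errors import GeometryError, PDBFormatError
from mitotox.synthetic import SyntheticConfig, make_helix_structure, make_ligand_blob


def test_two_node_hessian_by_hand():
    """Nodes at (0,0,0) and (1,0,0) with γ=0.5: off-diagonal block is
    −0.5·diag(1,0,0)."""
    net = ElasticNetwork(np.array([[0.0, 0, 0], [1.0, 0, 0]]), gamma=0.5, cutoff=4.0)
    h = build_hessian(net)
    assert np.allclose(h[0:3, 3:6], -0.5 * np.diag([1.0, 0.0, 0.0]))
    assert np.allclose(h[0:3, 0:3], 0.5 * np.diag([1.0, 0.0, 0.0]))


def test_distance_weighted_block_by_hand():
    net = ElasticNetwork(np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                         mode="distance_weighted", p_exponent=2)
    h = build_hessian(net)
    # −1/s^(p+2) (r_j−r_i)(r_j−r_i)ᵀ = −(1/16)·diag(4,0,0)
    assert h[0, 3] == pytest.approx(-4.0 / 16.0)


def test_hessian_symmetric(helix20):
    h = build_hessian(ElasticNetwork(helix20, cutoff=13.0))
    assert np.max(np.abs(h - h.T)) == 0.0


def test_connected_helix_has_six_zero_modes(helix20):
    """Rigid translations and rotations are the only null modes."""
    h = build_hessian(ElasticNetwork(helix20, cutoff=13.0))
    w = np.linalg.eigvalsh(h)
    assert count_zero_modes(h) == 6
    assert np.all(w[:6] < 1e-9) and w[6] > 1e-9


def test_disconnected_network_warns():
    far = np.vstack([np.random.default_rng(0).normal(size=(4, 3)),
                     np.random.default_rng(1).normal(size=(4, 3)) + 100.0])
    net = ElasticNetwork(far, cutoff=13.0)
    assert not is_connected(net)
    with pytest.warns(UserWarning, match="disconnected"):
        covariance_from_hessian(build_hessian(net))


def test_coincident_nodes_rejected():
    with pytest.raises(GeometryError):
        build_hessian(ElasticNetwork(np.zeros((2, 3)) + [[0, 0, 0], [0, 0, 1e-9]]))


def test_single_node_rejected():
    with pytest.raises(GeometryError):
        ElasticNetwork(np.zeros((1, 3)))


def test_pseudo_inverse_identities(helix20):
    h = build_hessian(ElasticNetwork(helix20, cutoff=13.0))
    c = covariance_from_hessian(h)
    assert np.max(np.abs(h @ c @ h - h)) < 1e-8
    assert np.max(np.abs(c - c.T)) < 1e-12
    assert np.linalg.eigvalsh(c).min() >= -1e-10


def test_doubling_gamma_halves_covariance(helix20):
    c1 = covariance_from_hessian(build_hessian(ElasticNetwork(helix20, gamma=0.5, cutoff=13.0)))
    c2 = covariance_from_hessian(build_hessian(ElasticNetwork(helix20, gamma=1.0, cutoff=13.0)))
    assert np.allclose(c2, c1 / 2.0, atol=1e-10)


def test_translation_invariance(helix20):
    a = build_hessian(ElasticNetwork(helix20, cutoff=13.0))
    b = build_hessian(ElasticNetwork(helix20 + np.array([3.0, -7.0, 11.0]), cutoff=13.0))
    assert np.max(np.abs(a - b)) < 1e-8


def _rotation(seed: int) -> np.ndarray:
    q, _ = np.linalg.qr(np.random.default_rng(seed).normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def test_rotation_equivariance_of_blocks(helix20):
    """Rotating the structure transforms each 3×3 super-element as R B Rᵀ."""
    r = _rotation(5)
    h = build_hessian(ElasticNetwork(helix20, cutoff=13.0))
    hr = build_hessian(ElasticNetwork(helix20 @ r.T, cutoff=13.0))
    n = len(helix20)
    blocks = h.reshape(n, 3, n, 3)
    blocks_r = hr.reshape(n, 3, n, 3)
    expected = np.einsum("ab,ibjc,dc->iajd", r, blocks, r)
    assert np.max(np.abs(blocks_r - expected)) < 1e-8


def test_prs_magnitudes_rotation_invariant(helix20):
    r = _rotation(6)
    m0 = prs_map(ElasticNetwork(helix20, cutoff=13.0), n_forces=0)
    mr = prs_map(ElasticNetwork(helix20 @ r.T, cutoff=13.0), n_forces=0)
    assert np.max(np.abs(m0.response - mr.response)) < 1e-8


def test_prs_deterministic_and_nonnegative(helix20):
    net = ElasticNetwork(helix20, cutoff=13.0)
    a = prs_map(net, n_forces=5, seed=42)
    b = prs_map(net, n_forces=5, seed=42)
    assert np.array_equal(a.response, b.response)
    assert a.response.min() >= 0.0


def test_prs_rejects_negative_forces(helix20):
    with pytest.raises(ValueError):
        prs_map(ElasticNetwork(helix20, cutoff=13.0), n_forces=-1)


def test_prs_matches_dense_solve_oracle():
    """For small N the PRS response equals the RMS displacement from an
    independent constrained least-squares solve of H x = f."""
    rng = np.random.default_rng(17)
    coords = rng.normal(scale=3.0, size=(5, 3))
    net = ElasticNetwork(coords, gamma=0.7, cutoff=50.0)
    h = build_hessian(net)
    got = prs_map(net, n_forces=0).response
    n = len(coords)
    expected = np.zeros((n, n))
    for i in range(n):
        disp2 = np.zeros(n)
        for axis in range(3):
            f = np.zeros(3 * n)
            f[3 * i + axis] = 1.0
            x, *_ = np.linalg.lstsq(h, f, rcond=1e-8)  # min-norm solution
            disp2 += np.sum(x.reshape(n, 3) ** 2, axis=1)
        expected[i] = np.sqrt(disp2 / 3.0)
    assert np.max(np.abs(got - expected)) < 1e-8


@pytest.mark.filterwarnings("ignore:.*disconnected")
def test_bound_condition_contact_properties(helix20):
    net = ElasticNetwork(helix20, cutoff=13.0)
    unbound = prs_map(net, n_forces=0).response
    receptor_springs = contact_count(net)

    lig = make_ligand_blob(SyntheticConfig(seed=2), helix20.mean(axis=0), n_atoms=4)
    bnet = bound_condition(net, lig)
    assert contact_count(bnet) >= receptor_springs  # no receptor spring removed
    sub = prs_map(bnet, n_forces=0).submap(receptor_mask(bnet, len(helix20)))
    assert np.linalg.norm(sub.response - unbound) > 0.0

    with pytest.warns(UserWarning, match="no contact"):
        far = bound_condition(net, lig + 500.0)
    far_sub = prs_map(far, n_forces=0).submap(receptor_mask(far, len(helix20)))
    assert np.max(np.abs(far_sub.response - unbound)) < 1e-10


def test_contacting_ligand_perturbs_contact_row(helix20):
    net = ElasticNetwork(helix20, cutoff=13.0)
    unbound = prs_map(net, n_forces=0).response
    bnet = bound_condition(net, helix20[7] + np.array([2.0, 0.0, 0.0]))
    sub = prs_map(bnet, n_forces=0).submap(receptor_mask(bnet, len(helix20)))
    assert np.max(np.abs(sub.response[7] - unbound[7])) > 0.0


# --- PDB input ------------------------------------------------------------

def test_pdb_roundtrip(tmp_path, helix_cfg):
    coords, _ = make_helix_structure(helix_cfg, tmp_path / "helix.pdb")
    xyz, labels = read_calpha_pdb(tmp_path / "helix.pdb")
    assert xyz.shape == (helix_cfg.n_residues, 3)
    assert np.max(np.abs(xyz - np.round(coords, 3))) < 1e-5
    assert labels[0].startswith("A:ALA")


def test_pdb_altloc_rule(tmp_path):
    text = (
        "ATOM      1  CA AALA A   1      1.000   2.000   3.000  0.50  0.00           C  \n"
        "ATOM      2  CA BALA A   1      9.000   9.000   9.000  0.50  0.00           C  \n"
        "ATOM      3  CA  ALA A   2      4.000   5.000   6.000  1.00  0.00           C  \n"
    )
    p = tmp_path / "alt.pdb"
    p.write_text(text)
    xyz, labels = read_calpha_pdb(p)
    assert len(labels) == 2
    assert np.allclose(xyz[0], [1.0, 2.0, 3.0])  # altloc A wins over B


def test_pdb_malformed_coordinates_report_line(tmp_path):
    text = (
        "ATOM      1  CA  ALA A   1      1.000   2.000   3.000  1.00  0.00           C  \n"
        "ATOM      2  CA  ALA A   2      4.000   xxxxx   6.000  1.00  0.00           C  \n"
    )
    p = tmp_path / "bad.pdb"
    p.write_text(text)
    with pytest.raises(PDBFormatError, match="line 2"):
        read_calpha_pdb(p)


def test_pdb_without_ca_raises(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("HEADER  nothing here\nEND\n")
    with pytest.raises(PDBFormatError):
        read_calpha_pdb(p)
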