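"""Atom masking and NT-Xent loss contracts."""

import numpy as np
import pytest

from aampnn.contrastive import ContrastiveConfig, ContrastiveConfigError, \
    cosine_similarity, mask_atoms, nt_xent_loss, pretrain
from aampnn.encoder import EncoderConfig
from aampnn.featurization import featurize_molecule, mask_token
from aampnn.tensor import Tensor
from oracle_utils import oracle_nt_xent


# ----------------------------------------------------------------------
# masking
# ----------------------------------------------------------------------

def hundred_atom_graph():
    return featurize_molecule("C" * 100)


def test_quarter_ratio_masks_exactly_25_of_100(rng):
    view = mask_atoms(hundred_atom_graph(), 0.25, rng)
    assert len(view.masked_atom_indices) == 25


def test_minimum_one_atom_masked(rng):
    view = mask_atoms(featurize_molecule("C"), 0.25, rng)
    assert len(view.masked_atom_indices) == 1


def test_masking_is_seed_reproducible():
    g = hundred_atom_graph()
    v1 = mask_atoms(g, 0.25, np.random.Generator(np.random.PCG64(5)))
    v2 = mask_atoms(g, 0.25, np.random.Generator(np.random.PCG64(5)))
    np.testing.assert_array_equal(v1.masked_atom_indices,
                                  v2.masked_atom_indices)


def test_masked_view_differs_exactly_on_masked_rows(rng):
    g = featurize_molecule("CC(=O)Oc1ccccc1C(=O)O")
    view = mask_atoms(g, 0.25, rng)
    token = mask_token()
    for i in range(g.n_atoms):
        if i in view.masked_atom_indices:
            np.testing.assert_array_equal(view.graph.atom_features[i], token)
        else:
            np.testing.assert_array_equal(view.graph.atom_features[i],
                                          g.atom_features[i])
    np.testing.assert_array_equal(view.graph.bond_features, g.bond_features)


def test_invalid_mask_ratio_rejected(rng):
    with pytest.raises(ContrastiveConfigError):
        mask_atoms(featurize_molecule("CC"), 1.5, rng)
    with pytest.raises(ContrastiveConfigError):
        ContrastiveConfig(mask_ratio=0.0)


# ----------------------------------------------------------------------
# cosine similarity
# ----------------------------------------------------------------------

def test_cosine_similarity_analytic_cases():
    z = np.array([0.3, -1.2, 0.5])
    assert cosine_similarity(z, z) == pytest.approx(1.0)
    assert cosine_similarity(z, -z) == pytest.approx(-1.0)
    assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        cosine_similarity([0, 0], [1, 0])


# ----------------------------------------------------------------------
# NT-Xent
# ----------------------------------------------------------------------

def test_single_pair_loss_is_log_two():
    z = np.array([[0.4, 1.7, -0.3]])
    for tau in (0.05, 0.1, 1.0):
        assert nt_xent_loss(z, z * 2.0, tau).item() == \
            pytest.approx(np.log(2.0), abs=1e-9)


def test_two_identical_pairs_loss_is_log_four():
    z = np.tile([[1.0, 2.0, 3.0]], (2, 1))
    assert nt_xent_loss(z, z, 0.1).item() == pytest.approx(np.log(4.0),
                                                           abs=1e-9)


@pytest.mark.parametrize("n,dim,tau", [(3, 4, 0.5), (5, 8, 0.1),
                                       (2, 3, 1.0), (8, 16, 0.07)])
def test_loss_matches_double_loop_oracle(n, dim, tau, rng):
    z = rng.normal(size=(n, dim))
    zp = rng.normal(size=(n, dim))
    assert nt_xent_loss(z, zp, tau).item() == \
        pytest.approx(oracle_nt_xent(z, zp, tau), abs=1e-6)


def test_loss_oracle_agreement_many_random_configs():
    rng = np.random.Generator(np.random.PCG64(99))
    for _ in range(50):
        n = int(rng.integers(2, 9))
        dim = int(rng.integers(2, 12))
        tau = float(rng.uniform(0.05, 2.0))
        z, zp = rng.normal(size=(n, dim)), rng.normal(size=(n, dim))
        assert nt_xent_loss(z, zp, tau).item() == \
            pytest.approx(oracle_nt_xent(z, zp, tau), abs=1e-6)


def test_loss_invariant_under_common_rotation(rng):
    z, zp = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
    q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    base = nt_xent_loss(z, zp, 0.2).item()
    rotated = nt_xent_loss(z @ q, zp @ q, 0.2).item()
    assert rotated == pytest.approx(base, abs=1e-9)


def test_loss_decreases_with_positive_similarity(rng):
    """Raising positive-pair similarity with negatives fixed lowers loss."""
    z = rng.normal(size=(4, 6))
    far = rng.normal(size=(4, 6))
    near = z + 0.01 * rng.normal(size=(4, 6))
    assert nt_xent_loss(z, near, 0.2).item() < nt_xent_loss(z, far, 0.2).item()


def test_loss_is_differentiable(rng):
    z = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    zp = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    nt_xent_loss(z, zp, 0.5).backward()
    assert np.isfinite(z.grad).all() and np.isfinite(zp.grad).all()


def test_invalid_temperature_rejected(rng):
    with pytest.raises(ContrastiveConfigError):
        nt_xent_loss(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)), 0.0)


# ----------------------------------------------------------------------
# pretraining loop
# ----------------------------------------------------------------------

SMALL_ENC = EncoderConfig(hidden_dim=16, n_attention_heads=2,
                          message_iterations=2)


def small_cfg(**kw):
    defaults = dict(epochs=2, batch_size=4, seed=0, projection_dims=(16, 8))
    defaults.update(kw)
    return ContrastiveConfig(**defaults)


def test_pretrain_small_corpus_boundary_batches(fixture_smiles):
    result = pretrain(fixture_smiles[:10], SMALL_ENC, small_cfg())
    assert len(result.train_losses) == 2
    assert len(result.val_losses) == 3          # init + 2 epochs
    assert np.isfinite(result.train_losses).all()


def test_pretrain_reproducible_loss_trajectory(fixture_smiles):
    r1 = pretrain(fixture_smiles[:20], SMALL_ENC, small_cfg())
    r2 = pretrain(fixture_smiles[:20], SMALL_ENC, small_cfg())
    assert r1.train_losses == r2.train_losses
    assert r1.val_losses == r2.val_losses


def test_pretrain_discards_projection_head(fixture_smiles):
    result = pretrain(fixture_smiles[:10], SMALL_ENC, small_cfg())
    assert not any(k.startswith("proj") for k in result.encoder_params)


def test_pretrain_rejects_empty_corpus():
    with pytest.raises(ValueError):
        pretrain(["not-a-smiles", "also-bad"], SMALL_ENC, small_cfg())
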