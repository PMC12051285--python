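"""Encoder correctness: analytic cases, brute-force oracle, invariances."""

import numpy as np
import pytest

from aampnn.encoder import BatchGraph, ConfigurationError, EncoderConfig, \
    atom_aggregate, atom_attention, bond_message_step, encode_batch, \
    encode_molecule, init_bond_states, init_encoder_params, load_encoder, \
    save_encoder
from aampnn.featurization import featurize_molecule
from aampnn.tensor import Tensor
from oracle_utils import oracle_encode


def np_params(params):
    return {k: v.data for k, v in params.items()}


def zeroed(params, names):
    out = dict(params)
    for n in names:
        out[n] = Tensor(np.zeros_like(params[n].data))
    return out


# ----------------------------------------------------------------------
# init_bond_states
# ----------------------------------------------------------------------

def test_zero_input_map_gives_zero_states(small_params):
    g = featurize_molecule("CCO")
    h0 = init_bond_states(g, zeroed(small_params, ["W_i"]))
    assert np.all(h0.data == 0.0)


def test_identity_input_map_reproduces_features(small_config):
    g = featurize_molecule("CCO")
    width = small_config.atom_width + small_config.bond_width
    params = {"W_i": Tensor(np.eye(width))}
    h0 = init_bond_states(g, params)
    expected = np.hstack([g.atom_features[g.bond_sources], g.bond_features])
    np.testing.assert_array_equal(h0.data, expected)


def test_init_states_match_dense_oracle(small_params):
    g = featurize_molecule("CCO")
    h0 = init_bond_states(g, small_params)
    W = small_params["W_i"].data
    for b, (v, w) in enumerate(g.directed_bonds):
        ref = np.maximum(
            np.concatenate([g.atom_features[v], g.bond_features[b]]) @ W, 0)
        np.testing.assert_allclose(h0.data[b], ref, rtol=1e-12)


def test_shape_mismatch_raises_configuration_error(small_params):
    g = featurize_molecule("CCO")
    bad = dict(small_params)
    bad["W_i"] = Tensor(np.zeros((3, 16)))
    with pytest.raises(ConfigurationError):
        init_bond_states(g, bad)


# ----------------------------------------------------------------------
# bond_message_step
# ----------------------------------------------------------------------

def test_terminal_atom_bond_is_fixed_point(small_params):
    """A terminal atom's outgoing bond receives only its own reverse,
    which cancels: its state never changes."""
    g = featurize_molecule("CC")          # both atoms terminal
    h0 = init_bond_states(g, small_params)
    h1 = bond_message_step(g, h0, h0, small_params)
    np.testing.assert_allclose(h1.data, h0.data, rtol=1e-12)


def test_chain_message_is_single_incoming_bond(small_params):
    """On A-B-C the message into bond B→C at t=1 is h⁰ of A→B alone."""
    g = featurize_molecule("CCO")
    h0 = init_bond_states(g, small_params)
    h1 = bond_message_step(g, h0, h0, small_params)
    bonds = g.directed_bonds
    b_ab = bonds.index((0, 1))
    b_bc = bonds.index((1, 2))
    ref = np.maximum(
        h0.data[b_bc] + h0.data[b_ab] @ small_params["W_h"].data, 0)
    np.testing.assert_allclose(h1.data[b_bc], ref, rtol=1e-12)


def test_message_step_matches_loop_oracle_on_ring(small_params, small_config):
    g = featurize_molecule("C1CC1")
    _, _ = small_config, None
    h_vec, _ = encode_molecule(g, small_params, small_config)
    ref, _ = oracle_encode(g, np_params(small_params),
                           small_config.message_iterations,
                           small_config.n_attention_heads)
    np.testing.assert_allclose(h_vec.data, ref, rtol=1e-9)


# ----------------------------------------------------------------------
# atom_aggregate
# ----------------------------------------------------------------------

def test_methane_empty_sum_convention(small_params, small_config):
    g = featurize_molecule("C")
    h0 = init_bond_states(g, small_params)
    m = atom_aggregate(g, h0, small_params)
    ref = np.maximum(np.concatenate(
        [g.atom_features[0], np.zeros(small_config.hidden_dim)]
    ) @ small_params["W_0"].data, 0)
    np.testing.assert_allclose(m.data[0], ref, rtol=1e-12)


def test_ethane_carbons_get_identical_messages(small_params, small_config):
    g = featurize_molecule("CC")
    h = init_bond_states(g, small_params)
    for _ in range(small_config.message_iterations):
        h = bond_message_step(g, h, h, small_params)
    m = atom_aggregate(g, h, small_params)
    np.testing.assert_allclose(m.data[0], m.data[1], rtol=1e-12)


# ----------------------------------------------------------------------
# atom_attention
# ----------------------------------------------------------------------

def test_zero_logits_give_uniform_attention(small_params, small_config):
    params = zeroed(small_params, [f"W_Q.{k}" for k in range(2)]
                    + [f"W_K.{k}" for k in range(2)])
    m = Tensor(np.random.default_rng(0).normal(size=(5, 16)))
    out, weights = atom_attention(m, params, small_config.n_attention_heads)
    for w in weights:
        np.testing.assert_allclose(w, np.full((5, 5), 0.2), atol=1e-12)
    # attention output per atom = mean of value vectors (+ residual)
    for k, w in enumerate(weights):
        v = m.data @ params[f"W_V.{k}"].data
        np.testing.assert_allclose(w @ v, np.tile(v.mean(0), (5, 1)),
                                   atol=1e-12)


def test_single_atom_attention_weight_is_one(small_params, small_config):
    m = Tensor(np.random.default_rng(1).normal(size=(1, 16)))
    out, weights = atom_attention(m, small_params,
                                  small_config.n_attention_heads)
    for w in weights:
        np.testing.assert_allclose(w, [[1.0]], atol=1e-15)
    # h_v = W_o-combined value + residual m_v
    vals = np.concatenate(
        [m.data @ small_params[f"W_V.{k}"].data for k in range(2)], axis=1)
    np.testing.assert_allclose(
        out.data, vals @ small_params["W_o"].data + m.data, rtol=1e-12)


def test_attention_rows_stochastic_random_case(small_params, small_config):
    rng = np.random.default_rng(2)
    m = Tensor(rng.normal(size=(4, 16)))
    _, weights = atom_attention(m, small_params, 2)
    for w in weights:
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)


def test_empty_molecule_rejected(small_params):
    with pytest.raises(ConfigurationError):
        atom_attention(Tensor(np.zeros((0, 16))), small_params, 2)


# ----------------------------------------------------------------------
# encode_molecule / encode_batch
# ----------------------------------------------------------------------

def test_permutation_invariance_simple(small_params, small_config):
    h1, _ = encode_molecule(featurize_molecule("CCO"), small_params,
                            small_config)
    h2, _ = encode_molecule(featurize_molecule("OCC"), small_params,
                            small_config)
    np.testing.assert_allclose(h1.data, h2.data, rtol=1e-9)


def test_all_zero_params_give_zero_vector(small_params, small_config):
    params = zeroed(small_params, list(small_params))
    h, _ = encode_molecule(featurize_molecule("CCO"), params, small_config)
    assert np.all(h.data == 0.0)


@pytest.mark.parametrize("smiles", ["C", "CC", "CCO", "C1CC1", "CC(N)=O",
                                    "C1CCC1", "CC#N", "OCC=O"])
def test_full_encoder_matches_bruteforce_oracle(smiles, small_params,
                                                small_config):
    g = featurize_molecule(smiles)
    assert g.n_atoms <= 6
    h, weights = encode_molecule(g, small_params, small_config)
    ref_h, ref_w = oracle_encode(g, np_params(small_params),
                                 small_config.message_iterations,
                                 small_config.n_attention_heads)
    np.testing.assert_allclose(h.data, ref_h, rtol=1e-5)
    for a, b in zip(weights, ref_w):
        np.testing.assert_allclose(a, b, atol=1e-9)


def test_batch_encoding_equals_per_molecule(small_params, small_config):
    smiles = ["CCO", "c1ccccc1", "CC(=O)N", "C1CC1C"]
    graphs = [featurize_molecule(s) for s in smiles]
    hb, _ = encode_batch(BatchGraph.from_graphs(graphs), small_params,
                         small_config)
    for i, g in enumerate(graphs):
        hi, _ = encode_molecule(g, small_params, small_config)
        np.testing.assert_allclose(hb.data[i], hi.data, rtol=1e-9)


def test_encoder_is_differentiable_end_to_end(small_params, small_config):
    g = featurize_molecule("CCO")
    h, _ = encode_molecule(g, small_params, small_config)
    (h * h).sum().backward()
    assert small_params["W_i"].grad is not None
    assert np.isfinite(small_params["W_i"].grad).all()


def test_config_validation():
    with pytest.raises(ConfigurationError):
        EncoderConfig(hidden_dim=0)
    with pytest.raises(ConfigurationError):
        EncoderConfig(hidden_dim=10, n_attention_heads=3)
    with pytest.raises(ConfigurationError):
        EncoderConfig(message_iterations=0)


def test_checkpoint_roundtrip(tmp_path, small_params, small_config):
    path = tmp_path / "enc.npz"
    save_encoder(path, small_params, small_config)
    params2, config2, meta = load_encoder(path)
    assert config2 == small_config
    assert meta["kind"] == "encoder"
    for k in small_params:
        np.testing.assert_array_equal(params2[k].data, small_params[k].data)
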