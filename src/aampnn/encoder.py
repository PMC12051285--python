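"""Directed message-passing encoder with a multi-head atom-attention readout.

The encoder follows the directed-bond message-passing scheme: each
chemical bond holds two hidden states, one per direction, initialized
from the concatenated source-atom and bond features.  At every
iteration the state of bond v→w aggregates the states of all bonds
arriving at v *except* the reverse bond w→v, which prevents a message
from echoing straight back along the edge it came from:

    h⁰_vw = ReLU(W_i [x_v ; e_vw])
    m^t_vw = Σ_{k∈N(v)} h^{t−1}_kv − h^{t−1}_wv
    h^t_vw = ReLU(h⁰_vw + W_h m^t_vw)

After T iterations, per-atom messages are read out and passed through
scaled dot-product self-attention over the atoms of the molecule
(queries, keys and values are linear maps of the atom messages; the
softmax is scaled by the square root of the per-head width), with a
residual connection, and finally summed into a single molecule vector:

    m_v = ReLU(W_0 [x_v ; Σ_w h^T_vw])
    h_v = MultiHeadAttention(m_v) + m_v
    h   = Σ_v h_v

Attention never crosses molecule boundaries: in batched encoding each
molecule's atom block attends only to itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .featurization import ATOM_SCHEMA, BOND_SCHEMA, MolGraph
from .nn import load_params, save_params
from .tensor import Tensor, concat, gather_rows, relu, segment_sum, softmax

__all__ = ["EncoderConfig", "init_encoder_params", "init_bond_states",
           "bond_message_step", "atom_aggregate", "atom_attention",
           "encode_molecule", "encode_batch", "BatchGraph", "EncoderState",
           "save_encoder", "load_encoder", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised on invalid encoder configuration or parameter shapes."""


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the message-passing encoder.

    ``hidden_dim`` must be divisible by ``n_attention_heads``; the
    per-head width is their quotient.
    """

    hidden_dim: int = 300
    message_iterations: int = 3
    n_attention_heads: int = 4
    activation: str = "relu"
    atom_width: int = ATOM_SCHEMA.total_width + 1  # +1 mask slot
    bond_width: int = BOND_SCHEMA.total_width

    def __post_init__(self):
        if self.hidden_dim <= 0:
            raise ConfigurationError("hidden_dim must be positive")
        if self.message_iterations < 1:
            raise ConfigurationError("message_iterations must be >= 1")
        if self.hidden_dim % self.n_attention_heads != 0:
            raise ConfigurationError(
                "hidden_dim must be divisible by n_attention_heads")
        if self.activation != "relu":
            raise ConfigurationError("only the rectifier activation is "
                                     "supported")

    @property
    def head_dim(self) -> int:
        return self.hidden_dim // self.n_attention_heads


@dataclass
class EncoderState:
    """Intermediate quantities of one encoding pass (NumPy views)."""

    bond_hidden: np.ndarray
    atom_messages: np.ndarray
    atom_hidden: np.ndarray
    molecule_vector: np.ndarray
    attention_weights: list[np.ndarray] = field(default_factory=list)


def init_encoder_params(rng: np.random.Generator,
                        config: EncoderConfig) -> dict[str, Tensor]:
    """Glorot-initialized weight matrices for the encoder.

    Keys: ``W_i``, ``W_h``, ``W_0``, per-head ``W_Q.k``/``W_K.k``/``W_V.k``
    and the output-combining ``W_o``.  The pseudocode maps carry no bias
    terms.
    """
    from .nn import glorot

    d, dh = config.hidden_dim, config.head_dim
    params = {
        "W_i": Tensor(glorot(rng, config.atom_width + config.bond_width, d),
                      requires_grad=True),
        "W_h": Tensor(glorot(rng, d, d), requires_grad=True),
        "W_0": Tensor(glorot(rng, config.atom_width + d, d),
                      requires_grad=True),
        "W_o": Tensor(glorot(rng, d, d), requires_grad=True),
    }
    for k in range(config.n_attention_heads):
        for name in ("W_Q", "W_K", "W_V"):
            params[f"{name}.{k}"] = Tensor(glorot(rng, d, dh),
                                           requires_grad=True)
    return params


def _check_shapes(graph_atom_width: int, graph_bond_width: int,
                  params: dict[str, Tensor]) -> None:
    expect = graph_atom_width + graph_bond_width
    if params["W_i"].shape[0] != expect:
        raise ConfigurationError(
            f"W_i expects input width {params['W_i'].shape[0]}, "
            f"graph provides {expect}")


# ----------------------------------------------------------------------
# message passing
# ----------------------------------------------------------------------

def init_bond_states(graph: MolGraph, params: dict[str, Tensor]) -> Tensor:
    """h⁰_vw = ReLU(W_i [x_v ; e_vw]) for every directed bond."""
    _check_shapes(graph.atom_features.shape[1],
                  graph.bond_features.shape[1], params)
    if graph.n_directed_bonds == 0:
        return Tensor(np.zeros((0, params["W_i"].shape[1])))
    x_src = Tensor(graph.atom_features[graph.bond_sources])
    e = Tensor(graph.bond_features)
    return relu(concat([x_src, e], axis=1) @ params["W_i"])


def bond_message_step(graph: MolGraph, bond_hidden: Tensor, h0: Tensor,
                      params: dict[str, Tensor]) -> Tensor:
    """One directed message-passing update of all bond hidden states.

    The incoming sum at the source atom excludes the reverse bond, so a
    terminal atom's outgoing bond keeps its initial state (its only
    incoming message is the reverse bond, which cancels itself).
    """
    if graph.n_directed_bonds == 0:
        return bond_hidden
    # A[v] = Σ_{bonds k→v} h_kv, then m_vw = A[src] − h_rev
    arriving = segment_sum(bond_hidden, graph.bond_targets, graph.n_atoms)
    m = gather_rows(arriving, graph.bond_sources) \
        - gather_rows(bond_hidden, graph.reverse_index)
    return relu(h0 + m @ params["W_h"])


def atom_aggregate(graph: MolGraph, bond_hidden: Tensor,
                   params: dict[str, Tensor]) -> Tensor:
    """m_v = ReLU(W_0 [x_v ; Σ_{w∈N(v)} h^T_vw]); empty sums are zero."""
    d = params["W_0"].shape[1]
    if graph.n_directed_bonds == 0:
        outgoing = Tensor(np.zeros((graph.n_atoms, d)))
    else:
        outgoing = segment_sum(bond_hidden, graph.bond_sources, graph.n_atoms)
    x = Tensor(graph.atom_features)
    return relu(concat([x, outgoing], axis=1) @ params["W_0"])


# ----------------------------------------------------------------------
# attention readout
# ----------------------------------------------------------------------

def atom_attention(atom_messages: Tensor, params: dict[str, Tensor],
                   n_heads: int) -> tuple[Tensor, list[np.ndarray]]:
    """Multi-head scaled dot-product self-attention over a molecule's atoms.

    Returns the residual output ``MultiHead(m) W_o + m`` and the per-head
    row-stochastic M×M attention matrices (detached).
    """
    m_atoms = atom_messages.shape[0]
    if m_atoms == 0:
        raise ConfigurationError("attention over an empty molecule")
    head_outputs: list[Tensor] = []
    weights: list[np.ndarray] = []
    for k in range(n_heads):
        q = atom_messages @ params[f"W_Q.{k}"]
        key = atom_messages @ params[f"W_K.{k}"]
        v = atom_messages @ params[f"W_V.{k}"]
        dh = q.shape[1]
        logits = (q @ key.T) / np.sqrt(dh)
        attn = softmax(logits, axis=-1)
        weights.append(attn.data.copy())
        head_outputs.append(attn @ v)
    combined = concat(head_outputs, axis=1) @ params["W_o"]
    return combined + atom_messages, weights


# ----------------------------------------------------------------------
# full encoder
# ----------------------------------------------------------------------

def _run_message_passing(graph: MolGraph, params: dict[str, Tensor],
                         config: EncoderConfig) -> Tensor:
    h = init_bond_states(graph, params)
    h0 = h
    for _ in range(config.message_iterations):
        h = bond_message_step(graph, h, h0, params)
    return h


def encode_molecule(graph: MolGraph, params: dict[str, Tensor],
                    config: EncoderConfig,
                    return_state: bool = False):
    """Encode one molecule into its vector ``h = Σ_v h_v``.

    Returns ``(h, attention_weights)``, or an :class:`EncoderState`
    carrying all intermediates when ``return_state`` is true.
    """
    bond_hidden = _run_message_passing(graph, params, config)
    m_v = atom_aggregate(graph, bond_hidden, params)
    h_v, weights = atom_attention(m_v, params, config.n_attention_heads)
    h = h_v.sum(axis=0)
    if return_state:
        return EncoderState(bond_hidden=bond_hidden.data, atom_messages=m_v.data,
                            atom_hidden=h_v.data, molecule_vector=h.data,
                            attention_weights=weights)
    return h, weights


@dataclass
class BatchGraph:
    """Disjoint union of molecular graphs for batched encoding."""

    graph: MolGraph                      # concatenated graph
    atom_mol: np.ndarray                 # molecule id per atom
    atom_offsets: np.ndarray             # start index of each molecule
    n_molecules: int

    @classmethod
    def from_graphs(cls, graphs: list[MolGraph]) -> "BatchGraph":
        if not graphs:
            raise ValueError("empty batch")
        atom_off, bond_off = 0, 0
        bonds, feats, rev, mol_ids, offsets = [], [], [], [], []
        for i, g in enumerate(graphs):
            offsets.append(atom_off)
            bonds.extend((v + atom_off, w + atom_off)
                         for v, w in g.directed_bonds)
            feats.append(g.bond_features)
            rev.append(g.reverse_index + bond_off)
            mol_ids.extend([i] * g.n_atoms)
            atom_off += g.n_atoms
            bond_off += g.n_directed_bonds
        merged = MolGraph(
            n_atoms=atom_off,
            atom_features=np.vstack([g.atom_features for g in graphs]),
            directed_bonds=bonds,
            bond_features=np.vstack(feats) if bonds else feats[0][:0],
            reverse_index=np.concatenate(rev) if rev else np.zeros(0, np.intp),
            smiles_canonical="",
        )
        return cls(graph=merged, atom_mol=np.array(mol_ids, dtype=np.intp),
                   atom_offsets=np.array(offsets, dtype=np.intp),
                   n_molecules=len(graphs))


def encode_batch(batch: BatchGraph, params: dict[str, Tensor],
                 config: EncoderConfig,
                 dropout: float = 0.0,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[Tensor, list[list[np.ndarray]]]:
    """Encode a batch; attention runs per molecule (no cross-molecule mixing).

    Returns the (n_molecules × hidden_dim) matrix of molecule vectors
    and, per molecule, the per-head attention matrices.
    """
    from .nn import dropout_mask

    bond_hidden = _run_message_passing(batch.graph, params, config)
    m_all = atom_aggregate(batch.graph, bond_hidden, params)
    if dropout > 0.0 and rng is not None:
        m_all = m_all * dropout_mask(rng, m_all.shape, dropout)

    ends = np.append(batch.atom_offsets[1:], batch.graph.n_atoms)
    h_blocks: list[Tensor] = []
    all_weights: list[list[np.ndarray]] = []
    for lo, hi in zip(batch.atom_offsets, ends):
        m_mol = gather_rows(m_all, np.arange(lo, hi))
        h_v, w = atom_attention(m_mol, params, config.n_attention_heads)
        h_blocks.append(h_v.sum(axis=0).reshape(1, -1))
        all_weights.append(w)
    return concat(h_blocks, axis=0), all_weights


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------

def save_encoder(path, params: dict[str, Tensor], config: EncoderConfig,
                 extra_meta: dict | None = None) -> None:
    meta = {"kind": "encoder",
            "config": {"hidden_dim": config.hidden_dim,
                       "message_iterations": config.message_iterations,
                       "n_attention_heads": config.n_attention_heads,
                       "activation": config.activation,
                       "atom_width": config.atom_width,
                       "bond_width": config.bond_width}}
    meta.update(extra_meta or {})
    save_params(path, params, meta)


def load_encoder(path) -> tuple[dict[str, Tensor], EncoderConfig, dict]:
    params, meta = load_params(path)
    config = EncoderConfig(**meta["config"])
    return params, config, meta
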