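"""Full permeability classifier: encoder + feed-forward head.

The molecule vector h from the attention-readout encoder is optionally
concatenated with the molecule's ECFP bit vector and passed through a
feed-forward network whose sigmoid output is the permeability
probability; the binary label is taken at the 0.5 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import BatchGraph, EncoderConfig, encode_batch, \
    init_encoder_params
from .featurization import MolGraph, compute_ecfp, featurize_molecule
from .nn import Adam, load_params, mlp, mlp_params, save_params
from .tensor import Tensor, concat, relu, sigmoid

__all__ = ["PermeabilityModel", "Prediction", "bce_with_logits",
           "build_and_predict"]


@dataclass
class Prediction:
    smiles: str
    probability: float
    label: int
    attention_weights: list[np.ndarray] | None = None

    def __post_init__(self):
        self.label = int(self.probability >= 0.5)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on raw logits."""
    y = Tensor(np.asarray(targets, dtype=np.float64))
    abs_l = relu(logits) + relu(-logits)
    return (relu(logits) - logits * y + (1.0 + (-abs_l).exp()).log()).mean()


@dataclass
class PermeabilityModel:
    """Encoder + FFN classifier with shared parameter namespace.

    Encoder weights keep their native names (``W_i`` …); head weights
    are prefixed ``ffn``.  ``ffn_layers`` counts linear layers (2 = one
    hidden layer + output), matching the "two-layer FFN" head.
    """

    encoder_config: EncoderConfig
    params: dict[str, Tensor]
    ffn_layers: int = 2
    dropout: float = 0.0
    use_ecfp: bool = True
    ecfp_radius: int = 2
    ecfp_bits: int = 2048
    _fp_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def initialize(cls, rng: np.random.Generator,
                   encoder_config: EncoderConfig,
                   ffn_layers: int = 2, dropout: float = 0.0,
                   use_ecfp: bool = True, ecfp_radius: int = 2,
                   ecfp_bits: int = 2048,
                   pretrained_encoder: dict[str, Tensor] | None = None,
                   ) -> "PermeabilityModel":
        """Fresh model; optionally initialize the encoder from pretrained
        parameters (copied, then fine-tuned)."""
        if pretrained_encoder is not None:
            params = {k: Tensor(v.data.copy(), requires_grad=True)
                      for k, v in pretrained_encoder.items()}
        else:
            params = init_encoder_params(rng, encoder_config)
        d = encoder_config.hidden_dim
        in_dim = d + (ecfp_bits if use_ecfp else 0)
        dims = [in_dim] + [d] * (ffn_layers - 1) + [1]
        params.update(mlp_params(rng, dims, "ffn"))
        return cls(encoder_config=encoder_config, params=params,
                   ffn_layers=ffn_layers, dropout=dropout, use_ecfp=use_ecfp,
                   ecfp_radius=ecfp_radius, ecfp_bits=ecfp_bits)

    # ------------------------------------------------------------------
    def fingerprints(self, smiles: list[str]) -> np.ndarray:
        rows = []
        for s in smiles:
            if s not in self._fp_cache:
                self._fp_cache[s] = compute_ecfp(
                    s, self.ecfp_radius, self.ecfp_bits).bits
            rows.append(self._fp_cache[s])
        return np.array(rows)

    def forward_logits(self, graphs: list[MolGraph], smiles: list[str],
                       rng: np.random.Generator | None = None,
                       ecfp_rows: np.ndarray | None = None,
                       ) -> tuple[Tensor, list[list[np.ndarray]]]:
        """Logits for a batch; ``rng`` enables training-time dropout.

        ``ecfp_rows`` overrides the fingerprints computed from
        ``smiles`` (used by occlusion analysis on modified graphs).
        """
        batch = BatchGraph.from_graphs(graphs)
        drop = self.dropout if rng is not None else 0.0
        h, attn = encode_batch(batch, self.params, self.encoder_config,
                               dropout=drop, rng=rng)
        if self.use_ecfp:
            fps = ecfp_rows if ecfp_rows is not None \
                else self.fingerprints(smiles)
            h = concat([h, Tensor(fps)], axis=1)
        logits = mlp(self.params, "ffn", h, self.ffn_layers,
                     dropout=drop, rng=rng)
        return logits.reshape(-1), attn

    def predict_graphs(self, graphs: list[MolGraph], smiles: list[str],
                       ecfp_rows: np.ndarray | None = None) -> np.ndarray:
        logits, _ = self.forward_logits(graphs, smiles, ecfp_rows=ecfp_rows)
        return sigmoid(logits).data

    def predict_proba(self, smiles: list[str]) -> np.ndarray:
        graphs = [featurize_molecule(s) for s in smiles]
        return self.predict_graphs(graphs, smiles)

    def predict(self, smiles_list: list[str]) -> list[Prediction | Exception]:
        """Batch prediction with per-record skip-and-report on parse errors."""
        out: list[Prediction | Exception] = []
        for s in smiles_list:
            try:
                g = featurize_molecule(s)
                logits, attn = self.forward_logits([g], [s])
                p = float(sigmoid(logits).data[0])
                out.append(Prediction(smiles=s, probability=p, label=0,
                                      attention_weights=attn[0]))
            except ValueError as err:
                out.append(err)
        return out

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        meta = {"kind": "permeability_model",
                "config": {"hidden_dim": self.encoder_config.hidden_dim,
                           "message_iterations":
                               self.encoder_config.message_iterations,
                           "n_attention_heads":
                               self.encoder_config.n_attention_heads,
                           "activation": self.encoder_config.activation,
                           "atom_width": self.encoder_config.atom_width,
                           "bond_width": self.encoder_config.bond_width},
                "head": {"ffn_layers": self.ffn_layers,
                         "dropout": self.dropout,
                         "use_ecfp": self.use_ecfp,
                         "ecfp_radius": self.ecfp_radius,
                         "ecfp_bits": self.ecfp_bits}}
        save_params(path, self.params, meta)

    @classmethod
    def load(cls, path) -> "PermeabilityModel":
        params, meta = load_params(path)
        cfg = EncoderConfig(**meta["config"])
        head = meta["head"]
        return cls(encoder_config=cfg, params=params,
                   ffn_layers=head["ffn_layers"], dropout=head["dropout"],
                   use_ecfp=head["use_ecfp"],
                   ecfp_radius=head["ecfp_radius"],
                   ecfp_bits=head["ecfp_bits"])


def build_and_predict(model: PermeabilityModel, smiles: str) -> Prediction:
    """Predict one molecule; parse errors propagate."""
    g = featurize_molecule(smiles)
    logits, attn = model.forward_logits([g], [smiles])
    p = float(sigmoid(logits).data[0])
    return Prediction(smiles=smiles, probability=p, label=0,
                      attention_weights=attn[0])
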