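"""Contrastive pretraining of the encoder with atom-masked positive pairs.

Each molecule in a batch of N yields two views — the original graph and
a copy with 25% of its atoms replaced by a mask token — giving 2N
samples.  Both views are encoded, projected through a small MLP head,
and pulled together / pushed apart by the normalized temperature-scaled
cross-entropy (NT-Xent) loss on cosine similarities:

    L_i = −log  e^{sim(z_i, z_i′)/τ} /
               Σ_j ( e^{sim(z_i, z_j′)/τ} + e^{sim(z_i′, z_j)/τ} )

The denominator is implemented exactly in this form: it ranges over the
opposite view only (the positive pair included, no within-view
negatives), which differs from the SimCLR variant that also contrasts
within each view.  At N=1 the loss is identically log 2; with all
embeddings identical at N=2 it is log 4 — both limits are used as
analytic checks.  After pretraining only the encoder parameters are
returned; the projection head is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import BatchGraph, EncoderConfig, encode_batch, \
    init_encoder_params
from .featurization import MolGraph, featurize_molecule, mask_token
from .nn import Adam, mlp, mlp_params
from .tensor import Tensor

__all__ = ["ContrastiveConfig", "MaskedView", "mask_atoms",
           "cosine_similarity", "nt_xent_loss", "pretrain", "PretrainResult"]


class ContrastiveConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ContrastiveConfig:
    """Pretraining settings.

    ``mask_ratio`` is the fraction of atoms replaced by the mask token
    (floor, at least one).  ``temperature`` is the NT-Xent τ.
    ``projection_dims`` are the hidden/output widths of the projection
    head appended to the encoder output.
    """

    mask_ratio: float = 0.25
    temperature: float = 0.1
    projection_dims: tuple[int, ...] = (128, 64)
    batch_size: int = 32
    epochs: int = 10
    learning_rate: float = 1e-3
    validation_fraction: float = 0.10
    dual_masked_views: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.mask_ratio < 1.0:
            raise ContrastiveConfigError("mask_ratio must lie in (0, 1)")
        if self.temperature <= 0.0:
            raise ContrastiveConfigError("temperature must be positive")
        if self.batch_size < 2:
            raise ContrastiveConfigError("batch_size must be >= 2 for "
                                         "informative negatives")


@dataclass
class MaskedView:
    graph: MolGraph
    masked_atom_indices: np.ndarray


def mask_atoms(graph: MolGraph, mask_ratio: float,
               rng: np.random.Generator) -> MaskedView:
    """Replace a random ``max(1, floor(mask_ratio·M))`` atoms by the mask
    token; bond features are untouched."""
    if not 0.0 < mask_ratio < 1.0:
        raise ContrastiveConfigError("mask_ratio must lie in (0, 1)")
    m = graph.n_atoms
    count = max(1, int(np.floor(mask_ratio * m)))
    idx = rng.choice(m, size=count, replace=False)
    features = graph.atom_features.copy()
    features[idx] = mask_token()
    masked = MolGraph(
        n_atoms=m, atom_features=features,
        directed_bonds=list(graph.directed_bonds),
        bond_features=graph.bond_features,
        reverse_index=graph.reverse_index,
        smiles_canonical=graph.smiles_canonical,
        incoming_bonds=graph.incoming_bonds,
    )
    return MaskedView(graph=masked, masked_atom_indices=np.sort(idx))


def cosine_similarity(z1: np.ndarray, z2: np.ndarray) -> float:
    """sim(z1, z2) = z1ᵀz2 / (‖z1‖·‖z2‖); undefined for zero vectors."""
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    n1, n2 = np.linalg.norm(z1), np.linalg.norm(z2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(z1 @ z2 / (n1 * n2))


def _row_normalize(z: Tensor) -> Tensor:
    norms = ((z * z).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    return z / norms


def nt_xent_loss(z: Tensor | np.ndarray, z_prime: Tensor | np.ndarray,
                 temperature: float) -> Tensor:
    """Batch-mean NT-Xent loss between N originals and their N views."""
    if temperature <= 0.0:
        raise ContrastiveConfigError("temperature must be positive")
    z = z if isinstance(z, Tensor) else Tensor(z)
    z_prime = z_prime if isinstance(z_prime, Tensor) else Tensor(z_prime)
    n = z.shape[0]
    if z_prime.shape[0] != n:
        raise ValueError("view sets must have equal size")
    zn = _row_normalize(z)
    zpn = _row_normalize(z_prime)
    sims = zn @ zpn.T                       # sims[i, j] = sim(z_i, z_j′)
    inv_t = 1.0 / temperature
    pos = (sims * Tensor(np.eye(n))).sum(axis=1) * inv_t
    denom = (sims * inv_t).exp().sum(axis=1) \
        + (sims.T * inv_t).exp().sum(axis=1)
    return (denom.log() - pos).mean()


# ----------------------------------------------------------------------
# pretraining loop
# ----------------------------------------------------------------------

@dataclass
class PretrainResult:
    encoder_params: dict[str, Tensor]
    encoder_config: EncoderConfig
    train_losses: list[float]
    val_losses: list[float]          # index 0 = loss at random init
    n_train: int = 0
    n_val: int = 0


def _batch_indices(n: int, batch_size: int,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled full batches; a trailing incomplete batch is dropped
    (contrastive losses are batch-size sensitive), unless no full batch
    exists, in which case everything forms one batch."""
    order = rng.permutation(n)
    full = n // batch_size
    if full == 0:
        return [order]
    return [order[i * batch_size:(i + 1) * batch_size] for i in range(full)]


def _views_loss(graphs: list[MolGraph], params, proj, config: ContrastiveConfig,
                enc_config: EncoderConfig, rng: np.random.Generator) -> Tensor:
    if config.dual_masked_views:
        view1 = [mask_atoms(g, config.mask_ratio, rng).graph for g in graphs]
    else:
        view1 = graphs
    view2 = [mask_atoms(g, config.mask_ratio, rng).graph for g in graphs]
    all_params = {**params, **proj}
    n_layers = len(config.projection_dims)
    h1, _ = encode_batch(BatchGraph.from_graphs(view1), params, enc_config)
    h2, _ = encode_batch(BatchGraph.from_graphs(view2), params, enc_config)
    z1 = mlp(all_params, "proj", h1, n_layers)
    z2 = mlp(all_params, "proj", h2, n_layers)
    return nt_xent_loss(z1, z2, config.temperature)


def pretrain(corpus: list[str], encoder_config: EncoderConfig,
             config: ContrastiveConfig) -> PretrainResult:
    """Pretrain an encoder on an unlabeled SMILES corpus.

    The corpus is split 90:10 into train/validation under the config
    seed; validation NT-Xent loss is recorded before training (epoch 0)
    and after every epoch.  Invalid SMILES are skipped.
    """
    graphs = []
    for s in corpus:
        try:
            graphs.append(featurize_molecule(s))
        except ValueError:
            continue
    if len(graphs) < 2:
        raise ValueError("pretraining corpus has fewer than 2 valid molecules")

    rng = np.random.Generator(np.random.PCG64(config.seed))
    order = rng.permutation(len(graphs))
    n_val = max(1, int(round(config.validation_fraction * len(graphs))))
    val = [graphs[i] for i in order[:n_val]]
    train = [graphs[i] for i in order[n_val:]]
    if len(train) < 2:
        train, val = [graphs[i] for i in order], []

    params = init_encoder_params(rng, encoder_config)
    dims = [encoder_config.hidden_dim, *config.projection_dims]
    proj = mlp_params(rng, dims, "proj")
    opt = Adam({**params, **proj}, lr=config.learning_rate)

    def val_loss(epoch_seed: int) -> float:
        if not val:
            return float("nan")
        vrng = np.random.Generator(np.random.PCG64(config.seed + 10_000))
        losses = [
            _views_loss(
                [val[i] for i in b], params, proj, config, encoder_config,
                vrng).item()
            for b in _batch_indices(
                len(val), min(config.batch_size, len(val)),
                np.random.Generator(np.random.PCG64(epoch_seed)))
        ]
        return float(np.mean(losses))

    train_losses: list[float] = []
    val_losses: list[float] = [val_loss(0)]
    for epoch in range(config.epochs):
        epoch_losses = []
        for batch in _batch_indices(len(train), config.batch_size, rng):
            if len(batch) < 2:
                continue
            loss = _views_loss([train[i] for i in batch], params, proj,
                               config, encoder_config, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        train_losses.append(float(np.mean(epoch_losses)))
        val_losses.append(val_loss(epoch + 1))

    return PretrainResult(encoder_params=params,
                          encoder_config=encoder_config,
                          train_losses=train_losses, val_losses=val_losses,
                          n_train=len(train), n_val=len(val))
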