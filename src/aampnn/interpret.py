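"""Per-atom attention profiles, occlusion contributions and embeddings.

The attention readout yields row-stochastic per-head matrices over a
molecule's atoms; the aggregated per-atom weight is the mean (or max)
over heads of the attention each atom *receives* (column means),
renormalized to sum to one.  Because softmax weights are nonnegative
they carry no sign, so the signed per-atom contribution is defined by
single-atom occlusion: the drop in predicted permeability probability
when that atom's features are replaced by the pretraining mask token —
positive when the atom's presence pushes the prediction toward
permeable.  This occlusion definition is this package's interpretation
choice for coloring atoms by direction of effect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D

from .featurization import MolGraph, featurize_molecule, mask_token
from .model import PermeabilityModel

__all__ = ["AttentionReport", "atom_attention_profile", "export_heatmap",
           "embedding_map"]


@dataclass
class AttentionReport:
    smiles: str
    atom_symbols: list[str]
    weights: np.ndarray          # nonnegative, sums to 1
    contributions: np.ndarray    # signed occlusion scores
    probability: float


def _occlude(graph: MolGraph, atom_index: int) -> MolGraph:
    feats = graph.atom_features.copy()
    feats[atom_index] = mask_token()
    return MolGraph(n_atoms=graph.n_atoms, atom_features=feats,
                    directed_bonds=graph.directed_bonds,
                    bond_features=graph.bond_features,
                    reverse_index=graph.reverse_index,
                    smiles_canonical=graph.smiles_canonical,
                    incoming_bonds=graph.incoming_bonds)


def atom_attention_profile(model: PermeabilityModel, smiles: str,
                           head_aggregation: str = "mean") -> AttentionReport:
    """Aggregated attention weights and occlusion contributions per atom.

    Occlusion keeps the original ECFP fixed (only the graph channel is
    perturbed), isolating the encoder's view of the atom.
    """
    if head_aggregation not in ("mean", "max"):
        raise ValueError("head_aggregation must be 'mean' or 'max'")
    graph = featurize_molecule(smiles)
    logits, attn = model.forward_logits([graph], [smiles])
    prob = float(1.0 / (1.0 + np.exp(-logits.data[0])))

    heads = np.stack(attn[0])                    # (H, M, M), rows stochastic
    received = heads.mean(axis=1)                # column means per head
    agg = received.mean(axis=0) if head_aggregation == "mean" \
        else received.max(axis=0)
    weights = agg / agg.sum()

    fp = model.fingerprints([smiles]) if model.use_ecfp else None
    occluded = [_occlude(graph, i) for i in range(graph.n_atoms)]
    probs_occ = model.predict_graphs(
        occluded, [smiles] * graph.n_atoms,
        ecfp_rows=np.repeat(fp, graph.n_atoms, axis=0)
        if fp is not None else None)
    contributions = prob - probs_occ

    mol = Chem.MolFromSmiles(smiles)
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    return AttentionReport(smiles=smiles, atom_symbols=symbols,
                           weights=weights, contributions=contributions,
                           probability=prob)


def export_heatmap(report: AttentionReport, out_path, fmt: str = "svg",
                   size: tuple[int, int] = (400, 400)) -> Path:
    """Render a diverging atom-colored depiction and a per-atom CSV table.

    Atoms with positive contribution are green, negative red; color
    intensity scales with |contribution|.  The CSV (same stem, ``.csv``)
    holds atom index, element, weight and contribution and is
    byte-stable across repeated exports.
    """
    out_path = Path(out_path)
    if fmt not in ("svg", "png"):
        raise ValueError(f"unsupported depiction format: {fmt!r}")

    mol = Chem.MolFromSmiles(report.smiles)
    scale = np.abs(report.contributions).max()
    colors = {}
    for i, c in enumerate(report.contributions):
        intensity = float(abs(c) / scale) if scale > 0 else 0.0
        if c >= 0:   # green for positive, red for negative
            colors[i] = (1.0 - intensity, 1.0, 1.0 - intensity)
        else:
            colors[i] = (1.0, 1.0 - intensity, 1.0 - intensity)

    if fmt == "svg":
        drawer = rdMolDraw2D.MolDraw2DSVG(*size)
    else:
        try:
            drawer = rdMolDraw2D.MolDraw2DCairo(*size)
        except Exception as err:   # Cairo backend not built in
            raise ValueError("PNG depiction backend unavailable; "
                             "use fmt='svg'") from err
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol, highlightAtoms=list(range(mol.GetNumAtoms())),
        highlightAtomColors=colors)
    drawer.FinishDrawing()
    data = drawer.GetDrawingText()
    if fmt == "svg":
        out_path.write_text(data)
    else:
        out_path.write_bytes(data)

    table = out_path.with_suffix(".csv")
    with open(table, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["atom_index", "element", "weight", "contribution"])
        for i, (sym, w, c) in enumerate(zip(report.atom_symbols,
                                            report.weights,
                                            report.contributions)):
            writer.writerow([i, sym, f"{w:.8f}", f"{c:.8f}"])
    return out_path


def embedding_map(model: PermeabilityModel, smiles: list[str],
                  seed: int = 0, perplexity: float | None = None,
                  ) -> np.ndarray:
    """2-D t-SNE coordinates of molecule vectors h (one row per molecule)."""
    from sklearn.manifold import TSNE

    if len(smiles) < 2:
        raise ValueError("embedding map needs at least 2 molecules")
    from .encoder import BatchGraph, encode_batch

    graphs = [featurize_molecule(s) for s in smiles]
    h, _ = encode_batch(BatchGraph.from_graphs(graphs), model.params,
                        model.encoder_config)
    if perplexity is None:
        perplexity = min(30.0, (len(smiles) - 1) / 3.0)
    if perplexity >= len(smiles):
        raise ValueError("perplexity must be below the number of molecules")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(h.data)
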