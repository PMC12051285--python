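"""Dataset curation, diversity diagnostics and synthetic fixtures.

Curation follows the standard permeability-modeling pipeline: parse,
keep the largest organic fragment (salt/solvent stripping), neutralize
charges, drop records whose log Papp falls outside the reliable
[−8, −3.5] assay window, then derive a binary permeable/non-permeable
label by two-cluster k-means on the one-dimensional log Papp values.
In one dimension, two-cluster k-means induces a threshold: the reported
cut is the midpoint between the top of the lower cluster and the bottom
of the upper cluster, and the higher-permeability cluster is labeled
permeable.

The synthetic fixture generator assembles drug-like molecules from a
curated fragment grammar (ring scaffolds plus small substituents) so
the whole pipeline can be exercised without any external download.  In
the classification task the label is the presence of a planted
substructure (default: an aromatic nitrogen); in the permeability task
log Papp is drawn from a two-component Gaussian mixture whose component
is tied to that same substructure, giving a bimodal, structure-linked
distribution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.cluster import KMeans

from .featurization import compute_ecfp
from .io import PermeabilityRecord

__all__ = ["CurationReport", "curate_caco2", "murcko_scaffold_stats",
           "tanimoto_leakage_screen", "generate_fixture",
           "LOG_PAPP_RANGE"]

#: reliable log10(Papp / cm s^-1) window; values outside are excluded
LOG_PAPP_RANGE = (-8.0, -3.5)


class CurationError(ValueError):
    pass


@dataclass
class CurationReport:
    n_input: int
    n_removed_parse: int
    n_removed_range: int
    n_after_standardization: int
    threshold: float
    class_counts: tuple[int, int]        # (non-permeable, permeable)

    def to_dict(self) -> dict:
        return {"n_input": self.n_input,
                "n_removed_parse": self.n_removed_parse,
                "n_removed_range": self.n_removed_range,
                "n_after_standardization": self.n_after_standardization,
                "threshold": self.threshold,
                "class_counts": list(self.class_counts)}


def _standardize(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    return Chem.MolToSmiles(mol)


def curate_caco2(records: list[PermeabilityRecord],
                 log_papp_range: tuple[float, float] = LOG_PAPP_RANGE,
                 seed: int = 0,
                 ) -> tuple[list[PermeabilityRecord], CurationReport]:
    """Standardize, range-filter and k-means-label permeability records.

    Returns the retained records (labels assigned, 1 = permeable) and a
    report whose counts conserve the input size.
    """
    lo, hi = log_papp_range
    n_parse = n_range = 0
    kept: list[PermeabilityRecord] = []
    for rec in records:
        if rec.log_papp is None:
            raise CurationError(f"record {rec.source_id!r} lacks log_papp")
        std = _standardize(rec.smiles)
        if std is None:
            n_parse += 1
            continue
        if not lo <= rec.log_papp <= hi:
            n_range += 1
            continue
        kept.append(PermeabilityRecord(smiles=std, log_papp=rec.log_papp,
                                       source_id=rec.source_id))

    values = np.array([r.log_papp for r in kept])
    if len(np.unique(values)) < 2:
        raise CurationError("need at least 2 distinct log_papp values to "
                            "cluster")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    assign = km.fit_predict(values.reshape(-1, 1))
    upper_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    labels = (assign == upper_cluster).astype(int)
    threshold = 0.5 * (values[labels == 0].max() + values[labels == 1].min())
    for rec, lab in zip(kept, labels):
        rec.label = int(lab)

    report = CurationReport(
        n_input=len(records), n_removed_parse=n_parse, n_removed_range=n_range,
        n_after_standardization=len(kept), threshold=float(threshold),
        class_counts=(int((labels == 0).sum()), int((labels == 1).sum())))
    return kept, report


# ----------------------------------------------------------------------
# diversity / leakage diagnostics
# ----------------------------------------------------------------------

def murcko_scaffold_stats(smiles_list: list[str]) -> dict:
    """Murcko-scaffold diversity summary.

    Acyclic molecules map to the empty scaffold, counted in its own
    bucket.  Invalid SMILES are skipped and reported.
    """
    counts: Counter[str] = Counter()
    n_skipped = 0
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            n_skipped += 1
            continue
        counts[Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol))] += 1
    n_scaffolds = len(counts)
    small = sum(1 for c in counts.values() if c <= 2)
    return {
        "n_unique_scaffolds": n_scaffolds,
        "scaffold_counts": dict(counts),
        "singleton_doubleton_fraction": (small / n_scaffolds
                                         if n_scaffolds else 0.0),
        "n_skipped": n_skipped,
    }


def tanimoto_leakage_screen(set_a: list[str], set_b: list[str],
                            threshold: float = 0.85,
                            radius: int = 2, n_bits: int = 2048) -> dict:
    """Per-molecule max Tanimoto of ``set_a`` against ``set_b``.

    Pairs at or above ``threshold`` are flagged as potential leakage.
    """
    if not set_a or not set_b:
        raise ValueError("leakage screen requires two non-empty sets")
    fa = np.array([compute_ecfp(s, radius, n_bits).bits for s in set_a])
    fb = np.array([compute_ecfp(s, radius, n_bits).bits for s in set_b])
    inter = fa @ fb.T
    union = fa.sum(1)[:, None] + fb.sum(1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    max_sim = sims.max(axis=1)
    argmax = sims.argmax(axis=1)
    flagged = [(i, int(argmax[i]), float(max_sim[i]))
               for i in range(len(set_a)) if max_sim[i] >= threshold]
    return {"max_similarity": max_sim, "flagged_pairs": flagged}


# ----------------------------------------------------------------------
# synthetic fixtures
# ----------------------------------------------------------------------

# scaffolds carrying the default planted substructure (aromatic nitrogen)
_N_SCAFFOLDS = ["c1ccncc1", "c1cncnc1", "c1cc[nH]c1", "c1c[nH]cn1",
                "c1ccc2ncccc2c1", "c1ccc2[nH]ccc2c1", "c1cnc2ccccc2c1"]
# scaffolds without it
_PLAIN_SCAFFOLDS = ["c1ccccc1", "C1CCCCC1", "c1ccoc1", "c1ccsc1",
                    "c1ccc2ccccc2c1", "C1CCOCC1", "C1CCCC1", "C1CCSCC1"]
# substituents: atom 0 is the attachment point; aliphatic only, so the
# planted aromatic-nitrogen signal lives exclusively in the scaffold
_SUBSTITUENTS = ["C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "F", "Cl",
                 "Br", "C#N", "C(F)(F)F", "C(=O)O", "C(=O)OC", "C(=O)N",
                 "CO", "CCO", "S(=O)(=O)C", "N(C)C", "CN"]

#: SMARTS of the default planted label-defining substructure
DEFAULT_SUBSTRUCTURE = "[n]"


def _attach(core: Chem.Mol, sub_smiles: str,
            rng: np.random.Generator) -> Chem.Mol | None:
    """Bond atom 0 of the substituent to a random C-H site of the core."""
    sub = Chem.MolFromSmiles(sub_smiles)
    sites = [a.GetIdx() for a in core.GetAtoms()
             if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1]
    if not sites:
        return None
    site = int(rng.choice(sites))
    combo = Chem.RWMol(Chem.CombineMols(core, sub))
    combo.AddBond(site, core.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
        return mol
    except Exception:
        return None


def _sample_molecule(rng: np.random.Generator, with_substructure: bool) -> str | None:
    pool = _N_SCAFFOLDS if with_substructure else _PLAIN_SCAFFOLDS
    mol = Chem.MolFromSmiles(str(rng.choice(pool)))
    n_subs = int(rng.integers(0, 4))
    for _ in range(n_subs):
        nxt = _attach(mol, str(rng.choice(_SUBSTITUENTS)), rng)
        if nxt is not None:
            mol = nxt
    # occasionally fuse in a second plain ring for extra diversity
    if rng.random() < 0.3:
        nxt = _attach(mol, str(rng.choice(_PLAIN_SCAFFOLDS)), rng)
        if nxt is not None:
            mol = nxt
    return Chem.MolToSmiles(mol)


def generate_fixture(n: int, seed: int, task: str = "classification",
                     substructure: str = DEFAULT_SUBSTRUCTURE,
                     label_noise: float = 0.0,
                     modes: tuple[float, float] = (-6.5, -4.5),
                     sigma: float = 0.3,
                     balance: float = 0.5) -> pd.DataFrame:
    """Generate ``n`` unique labeled drug-like SMILES.

    task "classification": columns ``smiles, label`` with
    label = presence of ``substructure`` (before optional noise flips).
    task "permeability": columns ``smiles, log_papp``; log Papp is
    normal around ``modes[0]`` when the substructure is present (low
    permeability) and ``modes[1]`` otherwise.  Deterministic under
    ``seed``.
    """
    if task not in ("classification", "permeability"):
        raise ValueError(f"unknown fixture task: {task!r}")
    if n < 10:
        raise ValueError("fixture size must be at least 10")
    rng = np.random.Generator(np.random.PCG64(seed))
    pattern = Chem.MolFromSmarts(substructure)
    if pattern is None:
        raise ValueError(f"invalid substructure SMARTS: {substructure!r}")

    seen: set[str] = set()
    smiles: list[str] = []
    has_sub: list[bool] = []
    attempts = 0
    while len(smiles) < n and attempts < 200 * n:
        attempts += 1
        want = rng.random() < balance
        s = _sample_molecule(rng, want)
        if s is None or s in seen:
            continue
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        present = mol.HasSubstructMatch(pattern)
        if present != want:
            continue
        seen.add(s)
        smiles.append(s)
        has_sub.append(present)
    if len(smiles) < n:
        raise RuntimeError(f"fragment grammar exhausted at {len(smiles)} "
                           f"unique molecules (requested {n})")

    if task == "classification":
        labels = np.array(has_sub, dtype=int)
        if label_noise > 0.0:
            flips = rng.random(n) < label_noise
            labels = np.where(flips, 1 - labels, labels)
        return pd.DataFrame({"smiles": smiles, "label": labels})

    comp = np.where(has_sub, modes[0], modes[1])
    log_papp = rng.normal(comp, sigma)
    return pd.DataFrame({"smiles": smiles, "log_papp": log_papp})
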