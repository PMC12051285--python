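"""Readers and writers for SMILES lists, labeled CSV tables and SDF."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from rdkit import Chem


@dataclass
class PermeabilityRecord:
    """One compound: SMILES plus a continuous log Papp and/or binary label.

    ``log_papp`` is log10 of the apparent permeability in cm/s.
    """

    smiles: str
    log_papp: float | None = None
    label: int | None = None
    source_id: str = ""

    def __post_init__(self):
        if self.log_papp is None and self.label is None:
            raise ValueError(f"record {self.source_id or self.smiles!r} "
                             "carries neither log_papp nor label")


def read_smiles_file(path) -> list[str]:
    """Plain-text SMILES list, one per line; blank lines and '#' comments
    are skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s.split()[0])
    return out


def read_csv(path, smiles_col: str = "smiles", label_col: str | None = "label",
             log_papp_col: str | None = None) -> list[PermeabilityRecord]:
    """Labeled CSV reader with configurable column names."""
    df = pd.read_csv(path)
    if smiles_col not in df.columns:
        raise ValueError(f"column {smiles_col!r} not in {list(df.columns)}")
    records = []
    for i, row in df.iterrows():
        label = None
        if label_col and label_col in df.columns and pd.notna(row[label_col]):
            label = int(row[label_col])
        log_papp = None
        if log_papp_col and log_papp_col in df.columns \
                and pd.notna(row[log_papp_col]):
            log_papp = float(row[log_papp_col])
        records.append(PermeabilityRecord(
            smiles=str(row[smiles_col]), log_papp=log_papp, label=label,
            source_id=str(i)))
    return records


def read_sdf(path) -> list[str]:
    """SMILES of the first molecule block per SDF record (invalid skipped)."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    return [Chem.MolToSmiles(mol) for mol in supplier if mol is not None]


def write_predictions_csv(path, smiles: list[str], probabilities,
                          labels) -> None:
    pd.DataFrame({"smiles": smiles, "probability": probabilities,
                  "label": labels}).to_csv(path, index=False)
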