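"""Curate a bimodal log Papp sample into binary permeability labels.

The synthetic sample mixes two Gaussian modes at −6.5 and −4.5 log
units; two-cluster k-means on the retained values induces a threshold
between them (on real Caco-2 data this kind of derived cut lands near
−5.5), and every molecule above the cut is labeled permeable.
"""

from aampnn import curate_caco2, generate_fixture
from aampnn.io import PermeabilityRecord

df = generate_fixture(400, seed=2, task="permeability",
                      modes=(-6.5, -4.5), sigma=0.3)
records = [PermeabilityRecord(smiles=s, log_papp=float(v), source_id=str(i))
           for i, (s, v) in enumerate(zip(df["smiles"], df["log_papp"]))]

kept, report = curate_caco2(records)
print(f"input records:        {report.n_input}")
print(f"removed (parse):      {report.n_removed_parse}")
print(f"removed (range):      {report.n_removed_range}")
print(f"retained:             {report.n_after_standardization}")
print(f"derived threshold:    {report.threshold:.3f} log Papp units")
print(f"class counts (non-permeable, permeable): {report.class_counts}")
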