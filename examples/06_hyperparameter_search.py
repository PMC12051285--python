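"""Bayesian hyperparameter search over the standard tuning grid.

A tree-structured Parzen estimator proposes configurations (message
depth, batch size, dropout, FFN depth, learning rate), each scored by
validation ROC-AUC after a short training run; the best configuration
and the full trial log come back.  Kept deliberately tiny here — real
searches use 20 epochs x 20 iterations.
"""

from aampnn import ModelConfig, bayes_optimize, generate_fixture

dataset = generate_fixture(150, seed=4)
base = ModelConfig(hidden_dim=16, n_attention_heads=4, ecfp_bits=256)
best, trials = bayes_optimize(dataset, n_epochs=2, n_iterations=4, seed=0,
                              base_config=base)

for i, t in enumerate(trials):
    c = t["config"]
    print(f"trial {i}: T={c['message_iterations']} batch={c['batch_size']} "
          f"dropout={c['dropout']:.2f} ffn={c['ffn_layers']} "
          f"lr={c['learning_rate']:.2e} -> val ROC-AUC {t['score']:.3f}")
print(f"best: T={best.message_iterations}, batch={best.batch_size}, "
      f"dropout={best.dropout}, ffn_layers={best.ffn_layers}, "
      f"lr={best.learning_rate:.2e}")
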