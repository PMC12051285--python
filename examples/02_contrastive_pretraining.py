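"""Contrastive pretraining on an unlabeled synthetic corpus.

Each molecule is paired with a 25%-atom-masked view; the NT-Xent loss
pulls the two views together against the rest of the batch.  The
validation loss at epoch 0 is the random-initialization baseline — it
should drop over the epochs as the encoder learns to recognize a
molecule from its unmasked parts.
"""

from aampnn import ContrastiveConfig, EncoderConfig, generate_fixture, \
    pretrain

corpus = generate_fixture(200, seed=0)["smiles"].tolist()
result = pretrain(
    corpus,
    EncoderConfig(hidden_dim=32, n_attention_heads=4),
    ContrastiveConfig(epochs=3, batch_size=16, seed=0,
                      projection_dims=(32, 16)),
)
print(f"corpus: {result.n_train} train / {result.n_val} validation")
for epoch, v in enumerate(result.val_losses):
    tag = "(random init)" if epoch == 0 else ""
    print(f"epoch {epoch}: validation NT-Xent {v:.4f} {tag}")
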