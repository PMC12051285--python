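"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with plain Python loops and dense NumPy on
purpose: no index arrays, no segment sums, no autodiff — so that
agreement with the vectorized implementation is a meaningful check.
"""

import numpy as np


def relu_np(x):
    return np.maximum(x, 0.0)


def oracle_encode(graph, params, T, n_heads):
    """Loop-based re-implementation of the full molecule encoder.

    ``params`` maps names to plain ndarrays.  Returns the molecule
    vector and the per-head attention matrices.
    """
    x = graph.atom_features
    e = graph.bond_features
    bonds = list(graph.directed_bonds)
    d = params["W_h"].shape[0]

    h0 = {b: relu_np(np.concatenate([x[v], e[b]]) @ params["W_i"])
          for b, (v, w) in enumerate(bonds)}
    h = dict(h0)
    for _ in range(T):
        new = {}
        for b, (v, w) in enumerate(bonds):
            m = np.zeros(d)
            for b2, (k, tgt) in enumerate(bonds):
                if tgt == v:                       # h_kv, k ∈ N(v)
                    m = m + h[b2]
            for b2, (k, tgt) in enumerate(bonds):
                if k == w and tgt == v:            # minus the reverse bond
                    m = m - h[b2]
        # note: the subtraction loop finds exactly one bond (w, v)
            new[b] = relu_np(h0[b] + m @ params["W_h"])
        h = new

    m_atoms = np.zeros((graph.n_atoms, d))
    for v in range(graph.n_atoms):
        s = np.zeros(d)
        for b, (src, tgt) in enumerate(bonds):
            if src == v:
                s = s + h[b]
        m_atoms[v] = relu_np(np.concatenate([x[v], s]) @ params["W_0"])

    heads, weights = [], []
    for k in range(n_heads):
        q = m_atoms @ params[f"W_Q.{k}"]
        key = m_atoms @ params[f"W_K.{k}"]
        val = m_atoms @ params[f"W_V.{k}"]
        dh = q.shape[1]
        logits = q @ key.T / np.sqrt(dh)
        a = np.zeros_like(logits)
        for i in range(logits.shape[0]):
            row = np.exp(logits[i] - logits[i].max())
            a[i] = row / row.sum()
        weights.append(a)
        heads.append(a @ val)
    h_v = np.concatenate(heads, axis=1) @ params["W_o"] + m_atoms
    return h_v.sum(axis=0), weights


def oracle_nt_xent(z, z_prime, tau):
    """Double-loop evaluation of the contrastive loss definition."""
    z = np.asarray(z, float)
    z_prime = np.asarray(z_prime, float)
    n = len(z)

    def cos(a, b):
        return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

    losses = []
    for i in range(n):
        num = np.exp(cos(z[i], z_prime[i]) / tau)
        den = 0.0
        for j in range(n):
            den += np.exp(cos(z[i], z_prime[j]) / tau)
            den += np.exp(cos(z_prime[i], z[j]) / tau)
        losses.append(-np.log(num / den))
    return float(np.mean(losses))


def oracle_roc_auc(scores, labels):
    """Pairwise concordance count; ties contribute one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
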