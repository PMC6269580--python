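"""Independent reference implementations used by several test modules."""

import numpy as np


def brute_force_kennard_stone(x, n_train):
    """Loop-based Kennard-Stone: exhaustive scan for the farthest pair, then
    stepwise maximin additions, lowest index winning ties."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    best, pair = -1.0, None
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.sqrt(((x[i] - x[j]) ** 2).sum()))
            if d > best:
                best, pair = d, (i, j)
    selected = list(pair)
    while len(selected) < n_train:
        cand, cand_d = None, -1.0
        for i in range(n):
            if i in selected:
                continue
            dmin = min(float(np.sqrt(((x[i] - x[s]) ** 2).sum())) for s in selected)
            if dmin > cand_d:
                cand, cand_d = i, dmin
        selected.append(cand)
    return selected


def gram_schmidt_chain(x, start, max_len):
    """Projection-chain oracle: at every step build an explicit orthonormal
    basis of the chain's span and append the column with the largest
    residual norm."""
    x = np.asarray(x, dtype=float)
    chain = [start]
    for _ in range(1, max_len):
        q, _ = np.linalg.qr(x[:, chain])
        resid = x - q @ (q.T @ x)
        norms = np.linalg.norm(resid, axis=0)
        norms[chain] = -1
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-10 * np.linalg.norm(x, axis=0).max():
            break
        chain.append(nxt)
    return chain
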