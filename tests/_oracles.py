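"""Independent brute-force oracles for the feature encoders and AUC.

These are literal, loop-by-loop transcriptions of the descriptor
definitions, kept deliberately naive and separate from the package's
vectorized implementations so the two can be compared on random inputs.
All operate on the canonical alphabetical residue order.
"""

import numpy as np

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

RPSSM_GROUPS = ("FYW", "ML", "IV", "ATS", "NH", "QED", "RK", "C", "G", "P")


def oracle_aac(seq):
    L = len(seq)
    out = np.zeros(20)
    for i, a in enumerate(AA_ORDER):
        count = 0
        for res in seq:
            if res == a:
                count += 1
        out[i] = count / L
    return out


def oracle_dpc(seq):
    L = len(seq)
    out = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            count = 0
            for k in range(L - 1):
                if seq[k] == a and seq[k + 1] == b:
                    count += 1
            out[i, j] = count / (L - 1)
    return out.ravel()


def oracle_pssm_composition(P, seq):
    """R_i = (1/L) sum_k r_k * delta_k, delta_k = 1 iff seq[k] == a_i."""
    L = len(seq)
    R = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        for k in range(L):
            delta = 1.0 if seq[k] == a else 0.0
            for j in range(20):
                R[i, j] += P[k, j] * delta
    return R.ravel() / L


def oracle_dpc_pssm(P):
    """y[i,j] = (1/(L-1)) sum_k P[k,i] * P[k+1,j]."""
    L = P.shape[0]
    Y = np.zeros((20, 20))
    for i in range(20):
        for j in range(20):
            s = 0.0
            for k in range(L - 1):
                s += P[k, i] * P[k + 1, j]
            Y[i, j] = s / (L - 1)
    return Y.ravel()


def oracle_pssm_ac(P, lag):
    """AC(j, lg) = sum_i (P[i,j]-mean_j)(P[i+lg,j]-mean_j) / (L-lg)."""
    L = P.shape[0]
    out = np.zeros((20, lag))
    for j in range(20):
        mean_j = sum(P[i, j] for i in range(L)) / L
        for lg in range(1, lag + 1):
            s = 0.0
            for i in range(L - lg):
                s += (P[i, j] - mean_j) * (P[i + lg, j] - mean_j)
            out[j, lg - 1] = s / (L - lg)
    return out.ravel()


def oracle_reduce_pssm(P):
    L = P.shape[0]
    reduced = np.zeros((L, 10))
    for g, group in enumerate(RPSSM_GROUPS):
        cols = [AA_ORDER.index(a) for a in group]
        for i in range(L):
            reduced[i, g] = sum(P[i, c] for c in cols) / len(cols)
    return reduced


def oracle_rpssm(P):
    """[D[1,1] .. D[10,10], D[1] .. D[10]] on the reduced matrix."""
    reduced = oracle_reduce_pssm(P)
    L = reduced.shape[0]
    D_st = np.zeros((10, 10))
    for s in range(10):
        for t in range(10):
            total = 0.0
            for i in range(L - 1):
                total += (reduced[i, s] - reduced[i + 1, t]) ** 2 / 2.0
            D_st[s, t] = total / (L - 1)
    D_s = np.zeros(10)
    for s in range(10):
        mean_s = sum(reduced[i, s] for i in range(L)) / L
        D_s[s] = sum((reduced[i, s] - mean_s) ** 2 for i in range(L)) / L
    return np.concatenate([D_st.ravel(), D_s])


def oracle_pairwise_auc(scores, labels):
    """AUC as the positive-outscores-negative probability, ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
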