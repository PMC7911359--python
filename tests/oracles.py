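"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops over the mathematical
definitions, deliberately sharing no code with the package internals.
"""

import numpy as np


def brute_longest_gap_run(row: str) -> int:
    runs = [len(seg) for seg in row.split("-") if True]
    # lengths of gap segments = lengths between non-gap segments
    best = 0
    cur = 0
    for c in row:
        cur = cur + 1 if c == "-" else 0
        best = max(best, cur)
    return best


def brute_weights(matrix: np.ndarray, threshold: float):
    M, L = matrix.shape
    w = np.zeros(M)
    for s in range(M):
        n = 0
        for t in range(M):
            ident = np.mean(matrix[s] == matrix[t])
            if ident >= threshold:
                n += 1
        w[s] = 1.0 / n
    return w, w.sum()


def brute_frequencies(matrix: np.ndarray, weights: np.ndarray, q: int, lam: float):
    M, L = matrix.shape
    m_eff = weights.sum()
    f1 = np.full((L, q), lam / q)
    for s in range(M):
        for i in range(L):
            f1[i, matrix[s, i]] += weights[s]
    f1 /= lam + m_eff
    f2 = np.full((L, L, q, q), lam / q**2)
    for s in range(M):
        for i in range(L):
            for j in range(L):
                f2[i, j, matrix[s, i], matrix[s, j]] += weights[s]
    f2 /= lam + m_eff
    for i in range(L):
        f2[i, i] = np.diag(f1[i])
    return f1, f2


def brute_hamiltonian(couplings, fields, seq) -> float:
    L = len(seq)
    total = 0.0
    for i in range(L):
        total -= fields[i][seq[i]]
        for j in range(i + 1, L):
            total -= couplings[i][j][seq[i]][seq[j]]
    return total


def brute_htcs(couplings, fields, mask_pairs, hk_seq, rr_seq, l_hk) -> float:
    s = list(hk_seq) + list(rr_seq)
    total = 0.0
    for i, j in mask_pairs:
        total -= couplings[i][j][s[i]][s[j]]
    for i in range(len(s)):
        total -= fields[i][s[i]]
    return total


def brute_contacts(res_a, res_b, cutoff):
    """res_a/res_b: lists of (resnum, coords array). All-pairs min distance."""
    out = []
    for na, ca in res_a:
        for nb, cb in res_b:
            dmin = min(
                float(np.sqrt(((x - y) ** 2).sum())) for x in ca for y in cb
            )
            if dmin < cutoff:
                out.append((na, nb))
    return out


def brute_classify(scores, hk_ids, rr_ids, cognates, tol=1e-9):
    """Argmin scan: verdicts per cognate pair as (positive, negative)."""
    out = {}
    for hk_id, rr_id in cognates.items():
        if hk_id not in hk_ids or rr_id not in rr_ids:
            continue
        h, r = hk_ids.index(hk_id), rr_ids.index(rr_id)
        v = scores[h, r]
        positive = all(scores[h, c] > v + tol for c in range(len(rr_ids)) if c != r)
        negative = all(scores[x, r] > v + tol for x in range(len(hk_ids)) if x != h)
        out[(hk_id, rr_id)] = (positive, negative)
    return out


def brute_top_k_overlap(di, mask_pairs, l_hk, k):
    L = di.shape[0]
    inter = [(i, j) for i in range(l_hk) for j in range(l_hk, L)]
    inter.sort(key=lambda p: (-di[p[0], p[1]], p[0], p[1]))
    return sum(1 for p in inter[:k] if p in mask_pairs)


def random_potts_model(rng, L, q, scale=0.5):
    """Random symmetric couplings (zero diagonal) and fields, raw gauge."""
    from tcspec.dca import PottsModel

    e = rng.normal(0, scale, size=(L, L, q, q))
    e = 0.5 * (e + e.transpose(1, 0, 3, 2))
    for i in range(L):
        e[i, i] = 0.0
    h = rng.normal(0, scale, size=(L, q))
    return PottsModel(couplings=e, fields=h, gauge_tag="raw", provenance="cognate")


def random_mask(rng, l_hk, l_rr, n_pairs):
    from tcspec.contacts import ContactMask

    all_pairs = [(i, j) for i in range(l_hk) for j in range(l_hk, l_hk + l_rr)]
    idx = rng.choice(len(all_pairs), size=min(n_pairs, len(all_pairs)), replace=False)
    return ContactMask(
        pairs=frozenset(all_pairs[k] for k in idx), l_hk=l_hk, l_rr=l_rr,
        cutoff_a=12.0, metric_tag="synthetic",
    )
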