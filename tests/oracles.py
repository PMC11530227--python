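"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles and deliberately shares no
code path with the package: a three-matrix affine-gap local DP (Gotoh) kept
as plain nested loops over explicit matrices, a quadratic all-vs-all
clustering oracle, exhaustive subset enumeration for interval tiling, and
an independently entered standard codon table.
"""

import itertools

NEG = float("-inf")


def sw_affine_score(q, t, score_of, gap_open, gap_extend):
    """Best local alignment score; gap of length k costs open + k*extend.

    ``score_of(q_res, t_pos)`` returns the substitution gain, so the same
    oracle covers sequence-sequence (t_pos indexes target residues) and
    sequence-profile (t_pos indexes PSSM columns) alignment.
    """
    n, m = len(t), len(q)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          F[i][j - 1] - gap_extend)
            H[i][j] = max(0.0,
                          H[i - 1][j - 1] + score_of(q[j - 1], i - 1),
                          E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def sw_score_sequences(q, t, matrix_lookup, gap_open=11, gap_extend=1):
    """Sequence-vs-sequence local score; matrix_lookup(a, b) -> int."""
    return sw_affine_score(
        q, t, lambda qa, ti: matrix_lookup(qa, t[ti]), gap_open, gap_extend)


def sw_score_profile(q, pssm_rows, aa_order, gap_open=11, gap_extend=1):
    """Sequence-vs-PSSM local score; pssm_rows[i] maps residue -> gain."""
    idx = {a: k for k, a in enumerate(aa_order)}

    def gain(qa, ti):
        row = pssm_rows[ti]
        k = idx.get(qa)
        return row[k] if k is not None else 0.0

    return sw_affine_score(q, pssm_rows, gain, gap_open, gap_extend)


def all_vs_all_identity_groups(records, min_identity, min_cov, identity_fn):
    """Ground-truth clustering by single-linkage over verified pairs.

    identity_fn(a, b) -> (identity_fraction, cov_a, cov_b) or None.
    Returns a frozenset of frozensets of record ids.
    """
    ids = [r.id for r in records]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(records, 2):
        res = identity_fn(a, b)
        if res is None:
            continue
        ident, cov_a, cov_b = res
        if ident >= min_identity and cov_a >= min_cov and cov_b >= min_cov:
            parent[find(a.id)] = find(b.id)
    groups = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())


def greedy_tiling_reference(intervals, max_overlap=0):
    """Re-simulation of the greedy non-overlap selection on raw tuples.

    ``intervals`` is a list of (e_value, bit_score, q_start, q_end,
    target_id, key); returns the selected keys in acceptance order.
    """
    order = sorted(intervals, key=lambda h: (h[0], -h[1], h[2], h[4]))
    accepted = []
    for ev, bit, qs, qe, tid, key in order:
        ok = True
        for _, _, aqs, aqe, _, _ in accepted:
            overlap = min(qe, aqe) - max(qs, aqs)
            if overlap > max_overlap:
                ok = False
                break
        if ok:
            accepted.append((ev, bit, qs, qe, tid, key))
    return [a[5] for a in accepted]


def all_nonoverlapping_subsets(intervals, max_overlap=0):
    """Every subset of intervals that is pairwise overlap-bounded."""
    out = []
    for r in range(len(intervals) + 1):
        for combo in itertools.combinations(range(len(intervals)), r):
            ok = True
            for a, b in itertools.combinations(combo, 2):
                qs1, qe1 = intervals[a]
                qs2, qe2 = intervals[b]
                if min(qe1, qe2) - max(qs1, qs2) > max_overlap:
                    ok = False
                    break
            if ok:
                out.append(frozenset(combo))
    return out


# Standard genetic code, entered independently (RNA-style table transcribed
# by codon family rather than generated).
CODON_TABLE = {}
_bases = "TCAG"
_aas = ("FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG")
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_bases, repeat=3)):
    CODON_TABLE[_b1 + _b2 + _b3] = _aas[_i]


def translate_brute(seq, frame):
    """Six-frame translation oracle (codons with N -> X, stops -> *)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    if frame < 0:
        seq = "".join(comp[c] for c in reversed(seq))
    s = seq[abs(frame) - 1:]
    out = []
    for i in range(0, len(s) - 2, 3):
        codon = s[i:i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


def stop_free_runs(protein, min_len):
    """All (start_aa, stretch) runs without '*' of length >= min_len."""
    runs = []
    cur = []
    start = 0
    for i, ch in enumerate(protein + "*"):
        if ch == "*":
            if len(cur) >= min_len:
                runs.append((start, "".join(cur)))
            cur = []
            start = i + 1
        else:
            cur.append(ch)
    return runs
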