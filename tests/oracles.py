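"""Independent brute-force oracles used by the test suite.

These are written against the stated scoring/matching rules directly and
share no code with the implementation paths they check.
"""
import itertools
import math


def gotoh_local_score(query, target, matrix, gap_open=11, gap_extend=1):
    """Quadratic local-alignment DP with affine gaps.

    A gap of length k costs gap_open + k * gap_extend (BLAST convention).
    """
    n, m = len(query), len(target)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - (gap_open + gap_extend),
                          E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - (gap_open + gap_extend),
                          F[i][j - 1] - gap_extend)
            s = matrix[query[i - 1], target[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def brute_force_disulfides(atoms, threshold):
    """All-pairs greedy nearest-pair matching on (chain, resnum, x, y, z).

    Returns a set of frozensets of (chain, resnum) keys.
    """
    pairs = []
    for a, b in itertools.combinations(atoms, 2):
        d = math.dist(a[2:], b[2:])
        if d <= threshold:
            pairs.append((d, (a[0], a[1]), (b[0], b[1])))
    pairs.sort()
    used = set()
    bonds = set()
    for d, ka, kb in pairs:
        if ka in used or kb in used:
            continue
        used.update({ka, kb})
        bonds.add(frozenset({ka, kb}))
    return bonds
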