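"""Independent reference implementations used only as test oracles.

Deliberately simple and written without reference to the package
internals: an O(nm) affine-gap global aligner (score only), a
per-window guide-match scanner, and a quadratic interval-overlap check.
"""

import math


def gotoh_score(a: str, b: str, match: int = 2, mismatch: int = -2,
                gap_open: int = -7, gap_ext: int = -1) -> float:
    """Global affine-gap alignment score; a gap of length L scores
    gap_open + (L-1)*gap_ext."""
    n, m = len(a), len(b)
    neg = -math.inf
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_ext
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_ext
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_ext,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_ext,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


_RC = str.maketrans("ACGTN", "TGCAN")


def _pam_ok(pam: str, pattern: str) -> bool:
    if len(pam) != 3 or "N" in pam:
        return False
    second = "AG" if pattern == "NRG" else "G"
    return pam[1] in second and pam[2] == "G"


def naive_scan(seq_id: str, seq: str, protospacer: str, max_mismatches: int = 6,
               seed_len: int = 10, pam_pattern: str = "NRG"):
    """Test every 23-mer window on both strands; returns
    (seq_id, start, strand, n_mm, seed_perfect) tuples sorted like scan_sites."""
    n = len(protospacer)
    hits = []
    for oriented, strand in ((seq, "+"), (seq.translate(_RC)[::-1], "-")):
        for i in range(len(oriented) - n - 2):
            site = oriented[i : i + n]
            pam = oriented[i + n : i + n + 3]
            if not _pam_ok(pam, pam_pattern):
                continue
            mm = sum(1 for x, y in zip(site, protospacer) if x != y)
            if "N" in site:
                mm = sum(1 for x, y in zip(site, protospacer) if x != y or x == "N")
            seed = site[n - seed_len :] == protospacer[n - seed_len :]
            if mm <= max_mismatches or seed:
                start = i if strand == "+" else len(seq) - i - n
                hits.append((seq_id, start, strand, mm, seed))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits


def naive_overlap(variant_span, intervals, chrom):
    """O(n*m) half-open interval overlap."""
    lo, hi = variant_span
    return any(c == chrom and lo < end and hi > start
               for c, start, end in intervals)
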