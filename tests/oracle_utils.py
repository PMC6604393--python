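"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: the scanner oracle
checks every window letter by letter on both explicit strands; the digest
oracle lays out fragments per sampled cut subset; the gap oracle paints a
coverage array.
"""

from __future__ import annotations

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _window_matches(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        b in IUPAC[p] for b, p in zip(window, pattern)
    )


def brute_force_scan(seq: str, pattern: str, circular: bool):
    """All (start, strand) motif occurrences, 1-based, minus-strand starts
    given as the leftmost forward coordinate of the occurrence."""
    n, k = len(seq), len(pattern)
    hits = set()
    ext = seq + seq[: k - 1] if circular and k > 1 else seq
    for i in range(min(n, len(ext) - k + 1)):
        window = ext[i : i + k]
        if _window_matches(window, pattern):
            hits.add((i + 1, "+"))
        # minus strand: the reverse complement of this window read 5'->3'
        if _window_matches(revcomp(window), pattern):
            hits.add((i + 1, "-"))
    return hits


def brute_force_gaps(footprints, n: int, circular: bool):
    """Maximal uncovered intervals from a painted coverage array.

    Returns (start, length) pairs; circular gaps spanning the origin appear
    once with their unwrapped start.
    """
    covered = np.zeros(n, dtype=bool)
    for s, e in footprints:
        for p in range(s, e + 1):
            covered[(p - 1) % n] = True
    if not covered.any():
        return [(1, n)]
    if covered.all():
        return []
    gaps = []
    free = ~covered
    i = 0
    runs = []
    while i < n:
        if free[i]:
            j = i
            while j < n and free[j]:
                j += 1
            runs.append((i, j - i))  # 0-based start, length
            i = j
        else:
            i += 1
    if circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][0] + runs[-1][1] == n:
        first = runs.pop(0)
        last = runs.pop()
        runs.append((last[0], last[1] + first[1]))
    for s0, ln in runs:
        gaps.append((s0 + 1, ln))
    return gaps


def subset_fragments(cut_positions, subset, n: int, circular: bool):
    """Fragment (start, end) layout for one realised set of cuts.

    ``cut_positions`` are cut-after coordinates; ``subset`` a boolean mask.
    """
    cuts = sorted(c for c, on in zip(cut_positions, subset) if on)
    if not cuts:
        return [(1, n)]
    if circular:
        out = []
        for a, b in zip(cuts, cuts[1:] + [cuts[0] + n]):
            out.append((a + 1, b))
        return out
    bounds = [0] + cuts + [n]
    return [(a + 1, b) for a, b in zip(bounds, bounds[1:]) if b > a]


def mc_partial_digest(cut_positions, probs, n: int, circular: bool,
                      trials: int, rng) -> dict:
    """Monte-Carlo band frequencies: sample cut subsets, lay out fragments.

    With k sites there are 2^k distinct outcomes, so subsets are tallied via
    a multinomial over trials and fragments accumulated per subset.
    """
    k = len(probs)
    freqs: dict = {}
    draws = rng.random((trials, k)) < np.asarray(probs)
    codes = draws @ (1 << np.arange(k))
    counts = np.bincount(codes, minlength=1 << k)
    for code, cnt in enumerate(counts):
        if cnt == 0:
            continue
        subset = [(code >> i) & 1 for i in range(k)]
        for frag in subset_fragments(cut_positions, subset, n, circular):
            freqs[frag] = freqs.get(frag, 0) + cnt
    return {f: c / trials for f, c in freqs.items()}
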