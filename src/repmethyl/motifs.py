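"""IUPAC motif scanning, densities, and motif-free-region (gap) detection.

Scans both strands of linear or circular replicons.  A minus-strand instance
is a match of the reverse-complement pattern in the forward sequence; its
``start`` is the forward-strand coordinate of the leftmost base of that
match, so for palindromic motifs the plus and minus instance coordinate sets
coincide and each site counts once per strand — the convention used when the
per-strand count of a palindromic motif is reported.

Gap ("motif desert") detection works on motif *footprints* (start..start+len-1,
either strand): a gap is a maximal interval no footprint touches.  Gap
significance uses a Poisson null: with per-position motif rate lambda, a fixed
window of length L is motif-free with probability exp(-lambda*L); a
Bonferroni-style correction over the N-L+1 window placements gives a
genome-wide p-value.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .replicon import Replicon, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT_CODE = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_revcomp(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT_CODE)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern:
        letters = IUPAC.get(ch)
        if letters is None:
            raise ValueError(f"non-IUPAC character {ch!r} in pattern {pattern!r}")
        # an N in the *sequence* never matches a non-N pattern letter
        parts.append(f"[{letters}]" if len(letters) < 4 else "[ACGT]")
    return re.compile("(?=(" + "".join(parts) + "))")


@dataclass(frozen=True)
class MotifSpec:
    """A named IUPAC recognition motif with its methylatable positions.

    ``methylatable`` lists (offset, strand, modification) triples giving, for
    a plus-strand match, which base is modified: offset is 0-based within the
    pattern, strand is the strand carrying the modified base, modification is
    one of ``m5C``/``m4C``/``m6A``.  For palindromic motifs the symmetric
    events on the other strand arise from the minus-strand instance.
    """

    name: str
    pattern: str
    methylatable: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty pattern")
        pat = self.pattern.upper()
        for ch in pat:
            if ch not in IUPAC:
                raise ValueError(f"non-IUPAC character {ch!r} in pattern")
        object.__setattr__(self, "pattern", pat)
        object.__setattr__(self, "methylatable", tuple(tuple(m) for m in self.methylatable))
        for off, strand, mod in self.methylatable:
            if not 0 <= off < len(pat):
                raise ValueError(f"methylatable offset {off} outside pattern")
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
            want = {"m5C": "C", "m4C": "C", "m6A": "A"}[mod]
            allowed = set(IUPAC[pat[off]])
            if strand == "-":
                allowed = {b.translate(_COMPLEMENT_CODE) for b in allowed}
            if want not in allowed:
                raise ValueError(
                    f"offset {off} strand {strand} cannot carry {mod} (pattern base {pat[off]})"
                )

    @property
    def palindromic(self) -> bool:
        return iupac_revcomp(self.pattern) == self.pattern

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifInstance:
    """One motif occurrence; ``start`` is 1-based on the forward strand."""

    replicon: str
    start: int
    strand: str
    motif: str
    length: int

    @property
    def end(self) -> int:
        """Last footprint coordinate; may exceed N for origin-spanning matches."""
        return self.start + self.length - 1


@dataclass(frozen=True)
class GapRegion:
    """Maximal motif-free interval with Poisson-null significance."""

    start: int
    end: int
    length: int
    expected: float
    p_single: float
    p_genomewide: float


# Built-in motif specifications for the Synechocystis 6803 methyltransferases:
# M.Ssp6803I methylates the first C of CGATCG (m5C), M.Ssp6803III the A of
# GATC (m6A, Dam-like), M.Ssp6803II the first C of GGCC (m4C).  All three
# recognition sequences are palindromic.
CGATCG = MotifSpec("CGATCG", "CGATCG", ((0, "+", "m5C"), (2, "+", "m6A")))
GATC = MotifSpec("GATC", "GATC", ((1, "+", "m6A"),))
GGCC = MotifSpec("GGCC", "GGCC", ((2, "+", "m4C"),))
HIP1 = MotifSpec("HIP1", "GCGATCGC", ((1, "+", "m5C"), (3, "+", "m6A")))

BUILTIN_MOTIFS = {m.name: m for m in (CGATCG, GATC, GGCC, HIP1)}

MOTIF_ENZYME = {
    ("CGATCG", "m5C"): "M.Ssp6803I",
    ("HIP1", "m5C"): "M.Ssp6803I",
    ("GGCC", "m4C"): "M.Ssp6803II",
    ("CGATCG", "m6A"): "M.Ssp6803III",
    ("HIP1", "m6A"): "M.Ssp6803III",
    ("GATC", "m6A"): "M.Ssp6803III",
}


def _strand_matches(seq: str, pattern: str, circular: bool, n: int) -> list[int]:
    """1-based start positions of pattern matches; includes origin-spanning
    starts (start <= n) when circular."""
    k = len(pattern)
    search_in = seq + seq[: k - 1] if circular and k > 1 else seq
    rx = _iupac_regex(pattern)
    return [m.start() + 1 for m in rx.finditer(search_in) if m.start() < n]


def scan_motifs(replicon: Replicon, spec: MotifSpec) -> list[MotifInstance]:
    """Locate every occurrence of ``spec`` on both strands.

    Overlapping occurrences are all reported.  Minus-strand instances carry
    the forward coordinate of their leftmost base.  Palindromic motifs yield
    a ``+`` and a ``-`` instance at each site.
    """
    n = len(replicon)
    if n == 0 or len(spec) > n:
        return []
    seq = replicon.sequence
    out = []
    for start in _strand_matches(seq, spec.pattern, replicon.circular, n):
        out.append(MotifInstance(replicon.name, start, "+", spec.name, len(spec)))
    for start in _strand_matches(seq, iupac_revcomp(spec.pattern), replicon.circular, n):
        out.append(MotifInstance(replicon.name, start, "-", spec.name, len(spec)))
    out.sort(key=lambda i: (i.start, i.strand))
    return out


def motif_density(instances, n: int, strand: str = "+") -> float:
    """Nucleotides per motif on one strand: N / per-strand count.

    Returns ``math.inf`` when the strand carries no instance.
    """
    if n <= 0:
        raise ValueError("replicon length must be positive")
    count = sum(1 for i in instances if i.strand == strand)
    if count == 0:
        return math.inf
    return n / count


def gap_pvalue(length: int, rate: float, n: int) -> tuple[float, float]:
    """Poisson-null significance of a motif-free window.

    ``p_single = exp(-rate*length)`` is the probability a *fixed* window of
    this length carries no motif start; the genome-wide value corrects for
    the N - L + 1 possible placements.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not 0 < length <= n:
        raise ValueError("need 0 < length <= N")
    p_single = math.exp(-rate * length)
    n_windows = n - length + 1
    p_gw = 1.0 - (1.0 - p_single) ** n_windows
    return p_single, min(max(p_gw, 0.0), 1.0)


def find_gaps(
    instances,
    n: int,
    circular: bool = False,
    min_len: int = 1,
    rate: float | None = None,
) -> list[GapRegion]:
    """Maximal intervals not overlapped by any motif footprint (either strand).

    On circular replicons the interval spanning the origin is merged into a
    single gap whose ``end`` exceeds ``n`` (end = start + L - 1 in unwrapped
    coordinates).  Gaps shorter than ``min_len`` are dropped; results are
    sorted by length descending.  When ``rate`` (motifs per nt per strand) is
    given, Poisson-null p-values are attached.
    """
    covered_intervals = []
    n_inst = 0
    for inst in instances:
        n_inst += 1
        s, e = inst.start, inst.end
        if circular and e > n:
            covered_intervals.append((s, n))
            covered_intervals.append((1, e - n))
        else:
            covered_intervals.append((s, min(e, n)))

    if rate is None:
        rate = n_inst / (2 * n) if n_inst else 0.0

    def _mk(start: int, length: int) -> GapRegion:
        if rate > 0:
            p1, pgw = gap_pvalue(length, rate, n)
        else:
            p1, pgw = 1.0, 1.0
        return GapRegion(start, start + length - 1, length, rate * length, p1, pgw)

    if not covered_intervals:
        gaps = [_mk(1, n)] if n >= min_len else []
        return gaps

    covered_intervals.sort()
    merged = [list(covered_intervals[0])]
    for s, e in covered_intervals[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    gaps = []
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        if s2 > e1 + 1:
            gaps.append((e1 + 1, s2 - e1 - 1))
    head = merged[0][0] - 1          # positions 1..first covered - 1
    tail = n - merged[-1][1]         # positions last covered + 1..N
    if circular:
        if head + tail > 0:
            s = merged[-1][1] + 1
            if s > n:
                s -= n
            gaps.append((s, head + tail))
    else:
        if head > 0:
            gaps.append((1, head))
        if tail > 0:
            gaps.append((merged[-1][1] + 1, tail))

    out = [_mk(s, ln) for s, ln in gaps if ln >= min_len]
    out.sort(key=lambda g: (-g.length, g.start))
    return out


def instances_to_bed(instances, path) -> None:
    """Write instances as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for i in instances:
            fh.write(f"{i.replicon}\t{i.start - 1}\t{i.end}\t{i.motif}\t0\t{i.strand}\n")


def gaps_to_bed(gaps, replicon_name: str, path) -> None:
    with open(path, "w") as fh:
        for g in gaps:
            fh.write(
                f"{replicon_name}\t{g.start - 1}\t{g.end}\tgap_L{g.length}"
                f"\t{g.p_genomewide:.3g}\t.\n"
            )
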