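"""CRISPR repeat-spacer array annotation and methylation-event inventory.

Repeat finding is tandem matching against a supplied repeat consensus
(seed-and-extend with a Hamming-distance budget), not de-novo CRISPR
discovery: the repeat sequence of the system under study is known.  A run of
consensus matches separated by spacer-sized gaps is an array; the longest
run wins.

The event inventory enumerates every methylatable (position, strand,
modification) triple inside the array, attributes it to a repeat, a spacer
or neither, and names the responsible methyltransferase.  A repeat carrying
one palindromic CGATCG contributes four events (5mC and 6mA on each strand),
so 50 repeats contribute 200 — the density that makes the array a methylation
hotspot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import MOTIF_ENZYME, MotifSpec, scan_motifs
from .replicon import Replicon

# offset (1-based, within the repeat, counted on the transcribed strand) of
# the endoribonucleolytic maturation cut; recorded as annotation only
CAS6_CUT_OFFSET_FROM_3PRIME = 8


@dataclass
class RepeatArray:
    """A located tandem repeat-spacer array (all coordinates 1-based)."""

    replicon: str
    start: int
    end: int
    repeat_seq: str
    n_repeats: int
    repeats: list            # [(start, end)] per repeat copy
    spacers: list            # [(start, end)] interior gaps
    mismatches: list         # per-repeat Hamming distance to the consensus
    metadata: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.n_repeats == 0


@dataclass(frozen=True)
class MethylationEvent:
    position: int
    strand: str
    modification: str
    enzyme: str
    motif: str
    container: str           # "repeat" | "spacer" | "other"
    container_index: int     # 1-based repeat/spacer number, 0 for "other"


def _match_positions(seq: str, consensus: str, max_mismatch: int) -> np.ndarray:
    """0-based start positions where consensus matches with <= max_mismatch."""
    n, k = len(seq), len(consensus)
    if k > n:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
    n_windows = n - k + 1
    mismatches = np.zeros(n_windows, dtype=np.int32)
    for j in range(k):
        mismatches += arr[j : j + n_windows] != cons[j]
    return np.flatnonzero(mismatches <= max_mismatch)


def locate_repeats(
    replicon: Replicon,
    repeat_seq: str,
    max_mismatch: int = 0,
    spacer_window: tuple[int, int] = (30, 45),
) -> RepeatArray:
    """Find the longest tandem array of ``repeat_seq`` copies.

    Consecutive matches whose gap (spacer length) falls within
    ``spacer_window`` are chained; the longest chain is returned.  With no
    match at all an empty-array sentinel is returned.
    """
    repeat_seq = repeat_seq.upper()
    if len(repeat_seq) < 20:
        raise ValueError("repeat consensus shorter than 20 nt")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    k = len(repeat_seq)
    starts0 = _match_positions(replicon.sequence, repeat_seq, max_mismatch)
    if starts0.size == 0:
        return RepeatArray(replicon.name, 0, 0, repeat_seq, 0, [], [], [])

    lo, hi = spacer_window
    chains = []
    current = [int(starts0[0])]
    for s in starts0[1:]:
        gap = int(s) - (current[-1] + k)          # spacer length between copies
        if lo <= gap <= hi:
            current.append(int(s))
        elif gap < 0:
            continue                               # overlapping spurious match
        else:
            chains.append(current)
            current = [int(s)]
    chains.append(current)
    best = max(chains, key=len)

    repeats = [(s + 1, s + k) for s in best]
    spacers = [(a_end + 1, b_start - 1) for (_, a_end), (b_start, _)
               in zip(repeats, repeats[1:])]
    arr = np.frombuffer(replicon.sequence.encode(), dtype=np.uint8)
    cons = np.frombuffer(repeat_seq.encode(), dtype=np.uint8)
    mism = [int((arr[s : s + k] != cons).sum()) for s in best]
    return RepeatArray(
        replicon.name,
        repeats[0][0],
        repeats[-1][1],
        repeat_seq,
        len(repeats),
        repeats,
        spacers,
        mism,
        metadata={"cas6_cut_offset_from_3prime": CAS6_CUT_OFFSET_FROM_3PRIME},
    )


def _container_of(array: RepeatArray, pos: int) -> tuple[str, int]:
    for i, (s, e) in enumerate(array.repeats, start=1):
        if s <= pos <= e:
            return "repeat", i
    for i, (s, e) in enumerate(array.spacers, start=1):
        if s <= pos <= e:
            return "spacer", i
    return "other", 0


def enumerate_events(replicon: Replicon, array: RepeatArray,
                     specs) -> tuple[list[MethylationEvent], dict]:
    """Inventory all methylation events inside the array interval.

    Distinct (position, strand, modification) triples are counted once even
    when motifs overlap (a CGATCG contains a GATC whose 6mA events coincide).
    Returns the events and per-container totals.
    """
    n = len(replicon)
    seen = {}
    for spec in specs:
        plen = len(spec)
        for inst in scan_motifs(replicon, spec):
            for off, mstrand, mod in spec.methylatable:
                if inst.strand == "+":
                    pos, strand = inst.start + off, mstrand
                else:
                    pos = inst.start + plen - 1 - off
                    strand = "-" if mstrand == "+" else "+"
                pos = (pos - 1) % n + 1
                if not array.start <= pos <= array.end:
                    continue
                key = (pos, strand, mod)
                if key in seen:
                    continue
                container, idx = _container_of(array, pos)
                enzyme = MOTIF_ENZYME.get((spec.name, mod), "unknown")
                seen[key] = MethylationEvent(pos, strand, mod, enzyme,
                                             spec.name, container, idx)
    events = sorted(seen.values(), key=lambda e: (e.position, e.strand, e.modification))
    totals = {"repeat": 0, "spacer": 0, "other": 0, "total": len(events)}
    for e in events:
        totals[e.container] += 1
    return events, totals


def map_motif_in_repeat(repeat_seq: str, spec: MotifSpec) -> list[dict]:
    """Offsets of a motif within the repeat consensus, with HIP1 context.

    For each match reports the 0-based offset and whether the extended
    octamer context equals the cognate HIP1 element GCGATCGC exactly, is the
    single-substitution variant GCGATCGG, or neither.
    """
    repeat_seq = repeat_seq.upper()
    from .motifs import _iupac_regex  # same matcher as the scanner

    out = []
    for m in _iupac_regex(spec.pattern).finditer(repeat_seq):
        off = m.start()
        report = {"offset": off, "match": repeat_seq[off : off + len(spec)]}
        if spec.pattern == "CGATCG":
            octamer = repeat_seq[max(off - 1, 0) : off + 7]
            if octamer == "GCGATCGC":
                report["hip1_status"] = "exact"
            elif octamer == "GCGATCGG":
                report["hip1_status"] = "1-nt deviation"
            else:
                report["hip1_status"] = "divergent"
            report["preceded_by_G"] = off > 0 and repeat_seq[off - 1] == "G"
        out.append(report)
    return out


def per_repeat_methylation(array: RepeatArray, sites: pd.DataFrame) -> pd.DataFrame:
    """Per-repeat, per-strand methylation summary.

    One row per repeat copy x strand with the mean called fraction over the
    repeat's covered cytosine sites, pooled counts, and a pooled Wilson CI.
    """
    from .calling import wilson_interval

    rows = []
    for i, (s, e) in enumerate(array.repeats, start=1):
        in_rep = sites[(sites["position"] >= s) & (sites["position"] <= e)]
        for strand in "+-":
            sel = in_rep[(in_rep["strand"] == strand) & in_rep["fraction"].notna()]
            n_meth = int(sel["n_meth"].sum())
            n_total = int(sel["n_meth"].sum() + sel["n_unmeth"].sum())
            frac = float(sel["fraction"].mean()) if len(sel) else float("nan")
            lo, hi = wilson_interval(n_meth, n_total)
            rows.append({
                "repeat": i, "start": s, "end": e, "strand": strand,
                "n_sites": len(sel), "n_meth": n_meth, "n_total": n_total,
                "fraction": frac, "ci_low": lo, "ci_high": hi,
            })
    return pd.DataFrame(rows)


def lowest_repeats(per_repeat: pd.DataFrame, k: int = 2,
                   strand: str | None = None) -> pd.DataFrame:
    """The k least-methylated repeat copies (ties broken by coordinate)."""
    df = per_repeat[per_repeat["fraction"].notna()]
    if strand is not None:
        df = df[df["strand"] == strand]
    return (df.sort_values(["fraction", "start"], kind="stable")
              .head(k).reset_index(drop=True))


def array_to_gff3(array: RepeatArray, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if array.empty:
            return
        fh.write(f"{array.replicon}\trepmethyl\trepeat_region\t{array.start}"
                 f"\t{array.end}\t.\t+\t.\tID=crispr_array;n_repeats={array.n_repeats}\n")
        for i, (s, e) in enumerate(array.repeats, start=1):
            fh.write(f"{array.replicon}\trepmethyl\tdirect_repeat\t{s}\t{e}"
                     f"\t.\t+\t.\tID=repeat_{i};Parent=crispr_array\n")
        for i, (s, e) in enumerate(array.spacers, start=1):
            fh.write(f"{array.replicon}\trepmethyl\tspacer\t{s}\t{e}"
                     f"\t.\t+\t.\tID=spacer_{i};Parent=crispr_array\n")


def events_to_tsv(events, path) -> None:
    pd.DataFrame([e.__dict__ for e in events]).to_csv(path, sep="\t", index=False)
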