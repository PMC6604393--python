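"""Synthetic pSYSA-like replicons with known methylation ground truth, and a
bisulfite read simulator.

The generator emulates the study system: a ~103 kb circular plasmid carrying

* a CRISPR repeat-spacer array (default 50 repeats of a 37-nt consensus with
  exactly one palindromic CGATCG, embedded in the extended context GCGATCGG,
  separated by 49 random ~36-nt spacers kept free of methylation motifs);
* a planted ~11 kb region entirely free of GGCC on either strand (the motif
  "desert" covering the interference/maturation cas genes);
* a controlled background GGCC density (default one per 420 nt per strand);
* a handful of planted CGATCG sites with prescribed methylation levels,
  mimicking the hypomethylated and methylated sites inside the cas3' gene
  that the restriction/Southern validation interrogates.

Ground truth assigns every motif-borne methylatable base a methylation
fraction; the read simulator then draws pre-aligned bisulfite reads:
an unmethylated C on the read's strand of origin converts C->T with the
bisulfite conversion rate, 5mC is protected, 4mC is protected only with the
detection efficiency eta (bisulfite is partially blind to 4mC), and 6mA never
changes base identity.  Reads are emitted in a minimal SAM dialect with their
origin coordinates, i.e. "pre-aligned"; read mapping is out of scope.

The default repeat consensus is a synthetic 37-mer (the real CRISPR1 repeat
sequence is not reproduced here); it preserves the features that matter for
the analysis: length, one CGATCG preceded by G, no GGCC, no extra GATC.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import CGATCG, GATC, GGCC, MotifSpec, scan_motifs
from .replicon import Replicon, reverse_complement

# Synthetic stand-in for the CRISPR1 repeat consensus (37 nt, one CGATCG in
# GCGATCGG context, GGCC-free, no GATC outside the motif).
DEFAULT_REPEAT = "GTTTCCATTAACCTATTAATCCCTATTAGCGATCGGC"

MODIFICATIONS = ("m5C", "m4C", "m6A")


class PlacementError(ValueError):
    """Raised when requested features cannot be placed on the replicon."""


@dataclass
class RepliconSpec:
    """Blueprint for a synthetic plasmid.

    Lengths/coordinates are nt, 1-based inclusive.  Methylation fractions are
    per-strand probabilities in [0, 1]; ``(forward, reverse)`` pairs.
    """

    name: str = "pSYSA_syn"
    length: int = 103_307
    circular: bool = True
    array_start: int = 16_310
    n_repeats: int = 50
    repeat_seq: str = DEFAULT_REPEAT
    spacer_len: int = 36
    desert_interval: tuple[int, int] | None = (3_537, 14_544)
    background_density: dict = field(default_factory=lambda: {"GGCC": 1 / 420})
    gc_content: float = 0.48
    exclude_motifs_in_spacers: bool = True
    # planted CGATCG sites: motif start -> true m5C fraction (both strands);
    # defaults mimic the cas3' sites probed by the Southern validation
    planted_cgatcg: dict = field(
        default_factory=lambda: {4_053: 0.46, 7_392: 0.02, 7_839: 0.95, 7_998: 0.02}
    )
    cas_region: tuple[int, int] | None = (5_000, 16_100)
    cas_m5c: tuple[float, float] = (0.634, 0.663)
    repeat_m5c: tuple[float, float] = (0.976, 0.925)
    background_m5c: tuple[float, float] = (0.95, 0.93)
    low_repeats: dict = field(default_factory=lambda: {22: 0.5, 44: 0.5})
    low_repeat_strand: str = "-"
    m6a_fraction: float = 1.0
    m4c_fraction: float = 1.0
    seed: int = 0

    @property
    def array_span(self) -> int:
        return self.n_repeats * len(self.repeat_seq) + (self.n_repeats - 1) * self.spacer_len

    @property
    def array_end(self) -> int:
        return self.array_start + self.array_span - 1

    def validate(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.repeat_seq.count("CGATCG") != 1:
            raise ValueError("repeat_seq must contain exactly one CGATCG")
        if self.array_end > self.length:
            raise PlacementError("repeat-spacer array extends past replicon end")
        if self.desert_interval is not None:
            d0, d1 = self.desert_interval
            if not (1 <= d0 <= d1 <= self.length):
                raise ValueError("desert_interval outside [1, length]")
            if not (self.array_end < d0 or self.array_start > d1):
                raise PlacementError("repeat-spacer array overlaps the desert interval")
        for p in self.planted_cgatcg:
            if not 1 <= p <= self.length - 5:
                raise PlacementError(f"planted CGATCG at {p} outside replicon")


@dataclass
class SimRead:
    """One simulated bisulfite read, pre-aligned to its origin.

    ``sequence`` is forward-reference oriented (SAM convention): bisulfite
    conversion on a minus-strand read appears as G->A here.
    """

    id: str
    strand: str
    start: int
    length: int
    sequence: str


@dataclass
class SimReadSet:
    replicon: str
    replicon_length: int
    circular: bool
    reads: list
    coverage: float
    read_len: int
    conversion_rate: float
    error_rate: float
    seed: int

    def __len__(self) -> int:
        return len(self.reads)


_FORBIDDEN = ("CGATCG", "GGCC", "GATC")


def _contains_motif(window: str, motifs=_FORBIDDEN) -> bool:
    for m in motifs:
        if m in window or reverse_complement(m) in window:
            return True
    return False


def _motif_overlaps_interval(window: str, lo: int, hi: int,
                             motifs=_FORBIDDEN) -> bool:
    """True if any motif occurrence in ``window`` overlaps [lo, hi) (0-based)."""
    pats = set()
    for m in motifs:
        pats.add(m)
        pats.add(reverse_complement(m))
    for m in pats:
        j = window.find(m)
        while j != -1:
            if j < hi and j + len(m) > lo:
                return True
            j = window.find(m, j + 1)
    return False


def _random_seq(rng, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _spacer(rng, length: int, gc: float, flank_left: str, flank_right: str,
            exclude: bool) -> str:
    for _ in range(200):
        s = _to_str(_random_seq(rng, length, gc))
        if not exclude:
            return s
        left = flank_left[-7:]
        win = left + s + flank_right[:7]
        if not _motif_overlaps_interval(win, len(left), len(left) + length):
            return s
    raise PlacementError("could not generate a motif-free spacer")


def _scrub_ggcc(seq: np.ndarray, rng, protected: np.ndarray, circular: bool) -> None:
    """Mutate away every GGCC whose footprint touches no protected position."""
    n = len(seq)
    for _ in range(50):
        s = _to_str(seq)
        search = s + s[:3] if circular else s
        hits = []
        idx = search.find("GGCC")
        while idx != -1:
            if idx < n:
                hits.append(idx)
            idx = search.find("GGCC", idx + 1)
        dirty = False
        for h in hits:
            foot = np.arange(h, h + 4) % n
            free = foot[~protected[foot]]
            if free.size == 0:
                raise PlacementError("GGCC inside a protected feature")
            dirty = True
            # flip one unprotected base to a different letter; the rescan
            # loop catches any occurrence recreated at a shifted offset
            target = int(free[0])
            choices = [b for b in b"ACGT" if b != seq[target]]
            seq[target] = rng.choice(np.array(choices, dtype=np.uint8))
        if not dirty:
            return
    raise PlacementError("could not scrub spontaneous GGCC occurrences")


def build_replicon(spec: RepliconSpec):
    """Construct the synthetic replicon, its methylation truth, and annotations.

    Returns
    -------
    replicon : Replicon
    truth : pandas.DataFrame
        Columns ``position, strand, modification, fraction, motif`` — one row
        per methylatable motif-borne base with its true methylated fraction.
    annotations : dict
        ``repeats`` / ``spacers`` DataFrames of 1-based intervals, the
        ``array`` interval, ``desert`` interval and ``planted`` site map.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.length

    seq = _random_seq(rng, n, spec.gc_content)

    # --- repeat-spacer array -------------------------------------------------
    repeat = spec.repeat_seq.upper()
    rep_len = len(repeat)
    parts = [repeat]
    repeats = [(spec.array_start, spec.array_start + rep_len - 1)]
    spacers = []
    pos = spec.array_start + rep_len
    for _ in range(spec.n_repeats - 1):
        sp = _spacer(rng, spec.spacer_len, spec.gc_content, repeat, repeat,
                     spec.exclude_motifs_in_spacers)
        parts.append(sp)
        spacers.append((pos, pos + spec.spacer_len - 1))
        pos += spec.spacer_len
        parts.append(repeat)
        repeats.append((pos, pos + rep_len - 1))
        pos += rep_len
    array_seq = "".join(parts)
    a0 = spec.array_start - 1
    seq[a0 : a0 + len(array_seq)] = np.frombuffer(array_seq.encode(), dtype=np.uint8)

    # keep the array boundaries free of straddling motifs
    for boundary in (a0, a0 + len(array_seq)):
        for _ in range(50):
            lo = max(boundary - 7, 0)
            hi = min(boundary + 7, n)
            win = _to_str(seq[lo:hi])
            bad = None
            for m in _FORBIDDEN:
                j = win.find(m)
                while j != -1:
                    if lo + j < boundary <= lo + j + len(m):  # straddles
                        bad = (lo + j, len(m))
                        break
                    j = win.find(m, j + 1)
                if bad:
                    break
            if bad is None:
                break
            # mutate the background-side base of the straddling motif
            b0, blen = bad
            target = b0 if b0 < a0 or b0 >= a0 + len(array_seq) else b0 + blen - 1
            seq[target] = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8))

    # --- planted CGATCG sites ------------------------------------------------
    protected = np.zeros(n, dtype=bool)
    protected[a0 : a0 + len(array_seq)] = True
    for p in spec.planted_cgatcg:
        seq[p - 1 : p + 5] = np.frombuffer(b"CGATCG", dtype=np.uint8)
        protected[p - 1 : p + 5] = True

    # --- GGCC landscape: scrub spontaneous, then plant at the target rate ----
    _scrub_ggcc(seq, rng, protected, spec.circular)
    ggcc_rate = spec.background_density.get("GGCC", 0.0)
    if ggcc_rate > 0:
        eligible = np.ones(n - 3, dtype=bool)
        anchors = []
        if spec.desert_interval is not None:
            d0, d1 = spec.desert_interval
            # exclude the desert, but anchor its boundaries with a motif
            # footprint on each side so the motif-free gap is exactly the
            # planted interval
            eligible[max(d0 - 8, 0) : d1 + 4] = False
            if d0 - 5 >= 0:
                anchors.append(d0 - 5)        # footprint d0-4 .. d0-1 (1-based)
            if d1 + 3 < n - 3:
                anchors.append(d1)            # footprint d1+1 .. d1+4 (1-based)
        eligible[max(a0 - 3, 0) : a0 + len(array_seq)] = False
        for p in spec.planted_cgatcg:
            eligible[max(p - 5, 0) : p + 5] = False
        idx_pool = np.flatnonzero(eligible)
        # density target counts the whole replicon (desert included in the
        # denominator), matching how a genome-wide motif rate is quoted
        n_plant = int(rng.poisson(ggcc_rate * n))
        n_plant = max(n_plant - len(anchors), 0)
        n_plant = min(n_plant, idx_pool.size)
        chosen = list(anchors)
        taken = np.zeros(n, dtype=bool)
        for c in anchors:
            taken[max(c - 3, 0) : c + 4] = True
        for cand in rng.permutation(idx_pool):
            if len(chosen) - len(anchors) == n_plant:
                break
            if not taken[cand : cand + 4].any():
                chosen.append(cand)
                taken[max(cand - 3, 0) : cand + 4] = True
        for c in chosen:
            seq[c : c + 4] = np.frombuffer(b"GGCC", dtype=np.uint8)

    replicon = Replicon(spec.name, _to_str(seq), circular=spec.circular)

    # --- verify the hard placement guarantees --------------------------------
    if spec.desert_interval is not None:
        d0, d1 = spec.desert_interval
        region = replicon.fetch(d0, d1 - d0 + 1)
        if "GGCC" in region:
            raise PlacementError("desert interval is not GGCC-free")
    for s, e in repeats:
        if replicon.fetch(s, rep_len) != repeat:
            raise PlacementError("repeat copy corrupted during construction")

    truth = _build_truth(replicon, spec, repeats)
    annotations = {
        "repeats": pd.DataFrame(repeats, columns=["start", "end"]),
        "spacers": pd.DataFrame(spacers, columns=["start", "end"]),
        "array": (spec.array_start, spec.array_end),
        "desert": spec.desert_interval,
        "planted": dict(spec.planted_cgatcg),
    }
    return replicon, truth, annotations


def _interval_index(intervals, pos: int) -> int | None:
    for i, (s, e) in enumerate(intervals):
        if s <= pos <= e:
            return i
    return None


def _build_truth(replicon: Replicon, spec: RepliconSpec, repeats) -> pd.DataFrame:
    rows = {}

    def add(pos, strand, mod, frac, motif):
        key = (pos, strand, mod)
        if key not in rows:
            rows[key] = (pos, strand, mod, float(frac), motif)

    def m5c_fraction(pos: int, strand: str, motif_start: int) -> float:
        if motif_start in spec.planted_cgatcg:
            return spec.planted_cgatcg[motif_start]
        ridx = _interval_index(repeats, pos)
        if ridx is not None:
            if (ridx + 1) in spec.low_repeats and strand == spec.low_repeat_strand:
                return spec.low_repeats[ridx + 1]
            return spec.repeat_m5c[0] if strand == "+" else spec.repeat_m5c[1]
        if spec.cas_region is not None and spec.cas_region[0] <= pos <= spec.cas_region[1]:
            return spec.cas_m5c[0] if strand == "+" else spec.cas_m5c[1]
        return spec.background_m5c[0] if strand == "+" else spec.background_m5c[1]

    n = len(replicon)
    for inst in scan_motifs(replicon, CGATCG):
        if inst.strand == "+":
            c_pos, a_pos = inst.start, inst.start + 2
        else:
            c_pos, a_pos = inst.start + 5, inst.start + 3
        c_pos = (c_pos - 1) % n + 1
        a_pos = (a_pos - 1) % n + 1
        add(c_pos, inst.strand, "m5C", m5c_fraction(c_pos, inst.strand, inst.start), "CGATCG")
        add(a_pos, inst.strand, "m6A", spec.m6a_fraction, "CGATCG")
    for inst in scan_motifs(replicon, GATC):
        a_pos = inst.start + 1 if inst.strand == "+" else inst.start + 2
        a_pos = (a_pos - 1) % n + 1
        add(a_pos, inst.strand, "m6A", spec.m6a_fraction, "GATC")
    for inst in scan_motifs(replicon, GGCC):
        c_pos = inst.start + 2 if inst.strand == "+" else inst.start + 1
        c_pos = (c_pos - 1) % n + 1
        add(c_pos, inst.strand, "m4C", spec.m4c_fraction, "GGCC")

    df = pd.DataFrame(
        sorted(rows.values()),
        columns=["position", "strand", "modification", "fraction", "motif"],
    )
    return df


# --------------------------------------------------------------------------- #
# bisulfite read simulation
# --------------------------------------------------------------------------- #

def _protection_arrays(replicon: Replicon, truth: pd.DataFrame,
                       m4c_efficiency: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-position probability that a C on each strand reads as protected."""
    n = len(replicon)
    prot_plus = np.zeros(n, dtype=np.float32)
    prot_minus = np.zeros(n, dtype=np.float32)
    for row in truth.itertuples(index=False):
        if row.modification == "m6A":
            continue
        eff = m4c_efficiency if row.modification == "m4C" else 1.0
        p = float(row.fraction) * eff
        if row.strand == "+":
            prot_plus[row.position - 1] = p
        else:
            prot_minus[row.position - 1] = p
    return prot_plus, prot_minus


def simulate_bisulfite_reads(
    replicon: Replicon,
    truth: pd.DataFrame,
    coverage: float = 100.0,
    read_len: int = 100,
    conversion_rate: float = 0.99,
    error_rate: float = 0.0,
    seed: int = 0,
    m4c_efficiency: float = 0.42,
) -> SimReadSet:
    """Draw pre-aligned bisulfite reads over the replicon.

    Each read originates from one strand.  Per covered cytosine on that
    strand the read shows C with probability ``m_eff + (1 - m_eff) * (1 - c)``
    (m_eff = truth fraction, scaled by ``m4c_efficiency`` for 4mC sites) and
    T otherwise; a uniform sequencing error then substitutes bases at rate
    ``error_rate``.  On circular replicons reads may span the origin.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not (0 <= conversion_rate <= 1 and 0 <= error_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    n = len(replicon)
    if read_len > n:
        if not replicon.circular:
            raise ValueError("read_len exceeds linear replicon length")
        raise ValueError("read_len exceeds replicon length")

    rng = np.random.default_rng(seed)
    n_reads = max(1, int(round(coverage * n / read_len)))
    if replicon.circular:
        starts = rng.integers(1, n + 1, size=n_reads)
    else:
        starts = rng.integers(1, n - read_len + 2, size=n_reads)
    minus = rng.random(n_reads) < 0.5

    seq_arr = np.frombuffer(replicon.sequence.encode(), dtype=np.uint8)
    prot_plus, prot_minus = _protection_arrays(replicon, truth, m4c_efficiency)

    posmat = (starts[:, None] - 1 + np.arange(read_len)[None, :]) % n
    obs = seq_arr[posmat].copy()

    C, G, T, A = (np.uint8(ord(b)) for b in "CGTA")
    u = rng.random(posmat.shape, dtype=np.float32)
    conv = rng.random(posmat.shape, dtype=np.float32) < conversion_rate

    plus_rows = ~minus
    mask = plus_rows[:, None] & (obs == C)
    unprotected = u >= prot_plus[posmat]
    obs[mask & unprotected & conv] = T

    mask = minus[:, None] & (obs == G)
    unprotected = u >= prot_minus[posmat]
    obs[mask & unprotected & conv] = A

    if error_rate > 0:
        err = rng.random(posmat.shape) < error_rate
        shift = rng.integers(1, 4, size=posmat.shape)
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        code = np.searchsorted(np.sort(lut), obs)  # A,C,G,T -> 0..3
        obs = np.where(err, lut[(code + shift) % 4], obs)

    reads = [
        SimRead(
            id=f"read{i}",
            strand="-" if minus[i] else "+",
            start=int(starts[i]),
            length=read_len,
            sequence=obs[i].tobytes().decode("ascii"),
        )
        for i in range(n_reads)
    ]
    return SimReadSet(
        replicon=replicon.name,
        replicon_length=n,
        circular=replicon.circular,
        reads=reads,
        coverage=coverage,
        read_len=read_len,
        conversion_rate=conversion_rate,
        error_rate=error_rate,
        seed=seed,
    )


# --------------------------------------------------------------------------- #
# on-disk interchange
# --------------------------------------------------------------------------- #

TRUTH_COLUMNS = ["position", "strand", "modification", "fraction", "motif"]


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"position": int, "fraction": float})
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns and c != "motif"]
    if missing:
        raise ValueError(f"truth table missing columns: {missing}")
    if len(df):
        if df["fraction"].min() < 0 or df["fraction"].max() > 1:
            raise ValueError("truth fractions outside [0, 1]")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("bad strand values in truth table")
        if not df["modification"].isin(MODIFICATIONS).all():
            raise ValueError("unknown modification in truth table")
    return df


def write_reads(readset: SimReadSet, path) -> None:
    """Write reads in a minimal SAM dialect.

    Standard 11-column SAM lines with FLAG 0/16 for origin strand and CIGAR
    ``<len>M``.  On circular replicons a read may wrap the origin, in which
    case POS + length exceeds the reference length declared in the header —
    a deliberate extension of plain SAM for circular templates.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{readset.replicon}\tLN:{readset.replicon_length}"
                 f"\tTP:{'circular' if readset.circular else 'linear'}\n")
        for r in readset.reads:
            flag = 16 if r.strand == "-" else 0
            fh.write(
                f"{r.id}\t{flag}\t{readset.replicon}\t{r.start}\t255"
                f"\t{r.length}M\t*\t0\t0\t{r.sequence}\t*\n"
            )


def read_reads(path) -> SimReadSet:
    """Parse the minimal SAM dialect back into a read set."""
    reads = []
    rname, rlen, circular = None, 0, False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for fld in line.split("\t")[1:]:
                        if fld.startswith("SN:"):
                            rname = fld[3:]
                        elif fld.startswith("LN:"):
                            rlen = int(fld[3:])
                        elif fld.startswith("TP:"):
                            circular = fld[3:] == "circular"
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"malformed SAM line: {line[:80]!r}")
            qname, flag, ref, pos, _, cigar = fields[:6]
            seq = fields[9]
            if not cigar.endswith("M") or not cigar[:-1].isdigit():
                raise ValueError(f"unsupported CIGAR {cigar!r} (minimal dialect is <len>M)")
            length = int(cigar[:-1])
            if length != len(seq):
                raise ValueError(f"CIGAR length {length} != SEQ length {len(seq)}")
            reads.append(SimRead(qname, "-" if int(flag) & 16 else "+",
                                 int(pos), length, seq.upper()))
    if rname is None:
        raise ValueError("missing @SQ header line")
    read_len = reads[0].length if reads else 0
    return SimReadSet(rname, rlen, circular, reads, coverage=float("nan"),
                      read_len=read_len, conversion_rate=float("nan"),
                      error_rate=float("nan"), seed=-1)


def content_hash(readset: SimReadSet) -> str:
    h = hashlib.sha256()
    for r in readset.reads:
        h.update(f"{r.id}|{r.strand}|{r.start}|{r.sequence}\n".encode())
    return h.hexdigest()
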