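"""Per-site bisulfite methylation calling, aggregation and classification.

The counting contract: for a cytosine on the forward strand, reads that
originate from the forward strand and show C at that position are methylated
calls and reads showing T are unmethylated; for a cytosine on the reverse
strand (a G in forward-reference orientation) the informative reads are the
reverse-strand ones, with G = methylated and A = unmethylated.  Any other
observed base is excluded from the fraction and tallied separately as an
error.  Confidence intervals are Wilson score intervals at 95%, which stay
sensible at fractions near 0 and 1 — the regime hypomethylation calls live in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .motifs import MotifSpec
from .replicon import Replicon
from .synthetic import SimReadSet

SITE_COLUMNS = [
    "position", "strand", "motif", "modification",
    "n_meth", "n_unmeth", "n_other", "fraction", "ci_low", "ci_high",
]


@dataclass
class Pileup:
    """Strand-split methylation pileup over a replicon.

    Arrays are 0-indexed by ``position - 1``; ``meth``/``unmeth`` count reads
    supporting the protected (C/G) and converted (T/A) base on each strand,
    ``other`` counts excluded mismatching bases at reference C/G positions.
    """

    replicon: str
    length: int
    meth: dict          # strand -> int array
    unmeth: dict
    other: dict

    def counts(self, position: int, strand: str) -> tuple[int, int, int]:
        i = (position - 1) % self.length
        return (int(self.meth[strand][i]), int(self.unmeth[strand][i]),
                int(self.other[strand][i]))


def build_pileup(reads: SimReadSet, replicon: Replicon) -> Pileup:
    """Vectorised strand-split pileup of C/T (forward) and G/A (reverse) calls."""
    if reads.replicon != replicon.name:
        raise ValueError(f"read set is for {reads.replicon!r}, not {replicon.name!r}")
    n = len(replicon)
    seq_arr = np.frombuffer(replicon.sequence.encode(), dtype=np.uint8)
    C, G, T, A = (np.uint8(ord(b)) for b in "CGTA")

    meth = {"+": np.zeros(n, dtype=np.int64), "-": np.zeros(n, dtype=np.int64)}
    unmeth = {"+": np.zeros(n, dtype=np.int64), "-": np.zeros(n, dtype=np.int64)}
    other = {"+": np.zeros(n, dtype=np.int64), "-": np.zeros(n, dtype=np.int64)}

    by_key: dict = {}
    for r in reads.reads:
        by_key.setdefault((r.length, r.strand), []).append(r)

    for (length, strand), group in by_key.items():
        starts = np.array([r.start for r in group], dtype=np.int64)
        obs = np.frombuffer(
            "".join(r.sequence for r in group).encode(), dtype=np.uint8
        ).reshape(len(group), length)
        posmat = (starts[:, None] - 1 + np.arange(length)[None, :]) % n
        ref = seq_arr[posmat]
        ref_base, meth_base, unmeth_base = (C, C, T) if strand == "+" else (G, G, A)
        at_site = ref == ref_base
        flat = posmat.ravel()
        np.add.at(meth[strand], flat, (at_site & (obs == meth_base)).ravel())
        np.add.at(unmeth[strand], flat, (at_site & (obs == unmeth_base)).ravel())
        np.add.at(other[strand], flat,
                  (at_site & (obs != meth_base) & (obs != unmeth_base)).ravel())
    return Pileup(replicon.name, n, meth, unmeth, other)


def count_site_calls(pileup_or_reads, replicon: Replicon, position: int,
                     strand: str) -> tuple[int, int]:
    """Methylated/unmethylated read counts at one cytosine site."""
    expected = "C" if strand == "+" else "G"
    if replicon.base(position) != expected:
        raise ValueError(
            f"position {position} strand {strand} is not a cytosine on that strand"
        )
    pileup = (pileup_or_reads if isinstance(pileup_or_reads, Pileup)
              else build_pileup(pileup_or_reads, replicon))
    n_meth, n_unmeth, _ = pileup.counts(position, strand)
    return n_meth, n_unmeth


def wilson_interval(n_meth: int, n_total: int) -> tuple[float, float]:
    if n_total == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(n_meth, n_total, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def call_sites(reads, replicon: Replicon, instances, spec: MotifSpec) -> pd.DataFrame:
    """Per-site methylation table for every methylatable offset of every instance.

    One row per (instance, methylatable offset).  6mA sites are inventoried
    but carry NA fractions: bisulfite chemistry does not report adenine
    methylation (their status in the study is inferred from DpnI digestion).
    """
    pileup = reads if isinstance(reads, Pileup) else build_pileup(reads, replicon)
    n = len(replicon)
    plen = len(spec)
    rows = []
    for inst in instances:
        if not 1 <= inst.start <= n:
            raise ValueError(f"instance start {inst.start} outside replicon")
        for off, mstrand, mod in spec.methylatable:
            if inst.strand == "+":
                pos, strand = inst.start + off, mstrand
            else:
                pos = inst.start + plen - 1 - off
                strand = "-" if mstrand == "+" else "+"
            pos = (pos - 1) % n + 1
            if mod == "m6A":
                rows.append((pos, strand, spec.name, mod, 0, 0, 0,
                             float("nan"), float("nan"), float("nan")))
                continue
            n_meth, n_unmeth, n_other = pileup.counts(pos, strand)
            total = n_meth + n_unmeth
            frac = n_meth / total if total else float("nan")
            lo, hi = wilson_interval(n_meth, total)
            rows.append((pos, strand, spec.name, mod, n_meth, n_unmeth, n_other,
                         frac, lo, hi))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return df.sort_values(["position", "strand"], kind="stable").reset_index(drop=True)


def classify_sites(sites: pd.DataFrame, hypo_max: float = 0.2,
                   hyper_min: float = 0.8) -> pd.DataFrame:
    """Label each site hypo / intermediate / hyper by its called fraction.

    ``hypo`` means fraction strictly below ``hypo_max``; ``hyper`` means
    fraction >= ``hyper_min``; NA fractions stay NA.  Thresholds are recorded
    in ``df.attrs``.
    """
    if not 0 <= hypo_max < hyper_min <= 1:
        raise ValueError("need 0 <= hypo_max < hyper_min <= 1")
    out = sites.copy()
    frac = out["fraction"]
    label = np.select(
        [frac.isna(), frac < hypo_max, frac >= hyper_min],
        ["NA", "hypo", "hyper"],
        default="intermediate",
    )
    out["label"] = label
    out.attrs["hypo_max"] = hypo_max
    out.attrs["hyper_min"] = hyper_min
    return out


@dataclass
class RegionSummary:
    start: int
    end: int
    strand: str
    n_sites: int
    n_covered: int
    mean_fraction: float
    label_counts: dict


def summarize_region(sites: pd.DataFrame, interval: tuple[int, int],
                     strand: str) -> RegionSummary:
    """Unweighted mean of site fractions over covered sites in an interval."""
    s, e = interval
    sel = sites[(sites["position"] >= s) & (sites["position"] <= e)
                & (sites["strand"] == strand)]
    covered = sel[sel["fraction"].notna()]
    mean = float(covered["fraction"].mean()) if len(covered) else float("nan")
    labels = (covered["label"].value_counts().to_dict()
              if "label" in covered.columns else {})
    return RegionSummary(s, e, strand, len(sel), len(covered), mean, labels)


def correct_m4c(observed: float, efficiency: float = 0.42) -> tuple[float, bool]:
    """Rescale an observed 4mC fraction by the bisulfite detection efficiency.

    Bisulfite only partially detects N4-methylcytosine; the true fraction is
    estimated as observed/efficiency, capped at 1.  Returns the estimate and
    a saturation flag set when the cap was applied.
    """
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    if not 0 <= observed <= 1:
        raise ValueError("observed fraction must be in [0, 1]")
    est = observed / efficiency
    return (1.0, True) if est > 1.0 else (est, False)


def sites_to_tsv(sites: pd.DataFrame, replicon_name: str, path) -> None:
    """bedGraph-like per-site output (0-based half-open start/end on disk)."""
    out = sites.copy()
    out.insert(0, "chrom", replicon_name)
    out.insert(1, "start", out["position"] - 1)
    out.insert(2, "end", out["position"])
    out.drop(columns=["position"]).to_csv(path, sep="\t", index=False)
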