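"""Methylation-sensitive restriction digestion in silico.

Each enzyme rule names a recognition sequence, cut offsets, and the
modifications that block or are required for cleavage.  Per recognition site
the cleavage probability is

    p_cut = prod(1 - f_b over blocking mods) * prod(f_r over required mods)

with f the methylated fraction of the relevant base/strand — strands act
independently, so a hemimethylated site blocks only partially.  A complete
digest keeps sites with p_cut = 1; a partial digest enumerates every possible
fragment with its band probability: the fragment between cut sites i < j
occurs when both are cut and everything between is not, so its probability is
p_i * p_j * prod_{i<k<j}(1 - p_k).  For every fixed nucleotide those
probabilities sum to 1, the in-silico analogue of mass conservation on a
Southern blot.

Built-in rules model the enzymes of the validation experiment: PvuI cuts
CGATCG only when the cytosines are unmethylated (insensitive to the internal
6mA); DpnI cuts GATC only when Dam-methylated (G6mATC on both strands);
Sau3AI cuts GATC regardless of methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .motifs import MotifSpec, iupac_revcomp, scan_motifs
from .replicon import Replicon

MAX_EXACT_SITES = 20


@dataclass(frozen=True)
class EnzymeRule:
    """Cleavage specification for one restriction enzyme.

    ``blocking`` / ``required`` are (offset, strand, modification) triples on
    the recognition sequence as matched on the forward strand; offsets are
    0-based.  ``cut_offset_top`` of k puts the top-strand cut between
    recognition bases k and k+1 (1-based), i.e. after forward coordinate
    ``site_start + k - 1``.
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int
    blocking: tuple = field(default_factory=tuple)
    required: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        L = len(self.recognition)
        object.__setattr__(self, "blocking", tuple(tuple(x) for x in self.blocking))
        object.__setattr__(self, "required", tuple(tuple(x) for x in self.required))
        for off, strand, mod in self.blocking + self.required:
            if not 0 <= off < L:
                raise ValueError(f"{self.name}: modification offset {off} outside recognition")
        if set(self.blocking) & set(self.required):
            raise ValueError(f"{self.name}: blocking and required sets overlap")
        if not (0 <= self.cut_offset_top <= L and 0 <= self.cut_offset_bottom <= L):
            raise ValueError(f"{self.name}: cut offset outside recognition")

    @property
    def spec(self) -> MotifSpec:
        return MotifSpec(self.name, self.recognition)


PVUI = EnzymeRule(
    "PvuI", "CGATCG", cut_offset_top=4, cut_offset_bottom=2,
    blocking=((0, "+", "m5C"), (5, "-", "m5C")),
)
DPNI = EnzymeRule(
    "DpnI", "GATC", cut_offset_top=2, cut_offset_bottom=2,
    required=((1, "+", "m6A"), (2, "-", "m6A")),
)
SAU3AI = EnzymeRule("Sau3AI", "GATC", cut_offset_top=0, cut_offset_bottom=4)

BUILTIN_ENZYMES = {e.name: e for e in (PVUI, DPNI, SAU3AI)}


def load_enzyme_config(path) -> dict:
    """Read enzyme rules from a YAML/JSON mapping name -> rule fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, d in raw.items():
        out[name] = EnzymeRule(
            name=name,
            recognition=d["recognition"],
            cut_offset_top=d.get("cut_offset_top", 0),
            cut_offset_bottom=d.get("cut_offset_bottom", len(d["recognition"])),
            blocking=tuple((m["offset"], m["strand"], m["modification"])
                           for m in d.get("blocking", [])),
            required=tuple((m["offset"], m["strand"], m["modification"])
                           for m in d.get("required", [])),
        )
    return out


@dataclass(frozen=True)
class CutSite:
    enzyme: str
    site_start: int          # 1-based first base of the recognition site
    cut_after: int           # top-strand cut falls after this coordinate
    p_cut: float


@dataclass(frozen=True)
class Fragment:
    start: int               # 1-based; end may exceed N on circular wrap
    end: int
    length: int
    probability: float = 1.0
    uncut_circle: bool = False


class MethylationState:
    """Lookup of methylated fraction per (position, strand, modification).

    Accepts a truth/called table with columns position, strand, modification
    and either ``fraction`` (truth) or a called ``fraction``; unknown sites
    default to fraction 0 (unmethylated).
    """

    def __init__(self, table: pd.DataFrame | None = None):
        self._map: dict = {}
        if table is not None and len(table):
            for row in table.itertuples(index=False):
                frac = float(row.fraction)
                if pd.isna(frac):
                    continue
                self._map[(int(row.position), row.strand, row.modification)] = frac

    def fraction(self, position: int, strand: str, modification: str) -> float:
        return self._map.get((position, strand, modification), 0.0)


def find_cut_sites(replicon: Replicon, rule: EnzymeRule,
                   state: MethylationState | None = None,
                   drop_blocked: bool = False) -> list[CutSite]:
    """Locate recognition sites and their cleavage probabilities.

    A double-stranded recognition site is identified once by the forward
    coordinate of its leftmost base (for the palindromic recognition
    sequences modelled here forward matches already enumerate every site).
    """
    state = state or MethylationState()
    n = len(replicon)
    spec = rule.spec
    starts = sorted({i.start for i in scan_motifs(replicon, spec) if i.strand == "+"})
    if iupac_revcomp(rule.recognition) != rule.recognition:
        # non-palindromic recognition: minus-strand sites cut too
        starts = sorted(set(starts) | {
            i.start for i in scan_motifs(replicon, spec) if i.strand == "-"
        })
    sites = []
    for s in starts:
        p = 1.0
        for off, strand, mod in rule.blocking:
            pos = (s + off - 1) % n + 1
            p *= 1.0 - state.fraction(pos, strand, mod)
        for off, strand, mod in rule.required:
            pos = (s + off - 1) % n + 1
            p *= state.fraction(pos, strand, mod)
        if drop_blocked and p == 0.0:
            continue
        cut_after = (s + rule.cut_offset_top - 2) % n + 1
        sites.append(CutSite(rule.name, s, cut_after, p))
    return sites


def complete_digest(replicon: Replicon, sites) -> list[Fragment]:
    """Fragments from cutting at every site with p_cut = 1.

    Linear: k cuts give k + 1 fragments (terminal ones included).  Circular:
    k cuts give exactly k fragments; zero cuts give the full-length circle
    flagged ``uncut_circle``.
    """
    n = len(replicon)
    cuts = sorted({s.cut_after for s in sites if s.p_cut == 1.0})
    if replicon.circular:
        if not cuts:
            return [Fragment(1, n, n, 1.0, uncut_circle=True)]
        frags = []
        for a, b in zip(cuts, cuts[1:] + [cuts[0] + n]):
            frags.append(Fragment(a + 1, b, b - a, 1.0))
        return frags
    bounds = [0] + cuts + [n]
    return [Fragment(a + 1, b, b - a, 1.0)
            for a, b in zip(bounds, bounds[1:]) if b > a]


def partial_digest(replicon: Replicon, sites, probability_floor: float | None = None
                   ) -> list[Fragment]:
    """All possible fragments of a partial digest with their band probabilities.

    Exact enumeration (O(k^2) fragments) up to ``MAX_EXACT_SITES`` sites;
    beyond that a ``probability_floor`` must be supplied and fragments below
    it are dropped.
    """
    n = len(replicon)
    sites = sorted(sites, key=lambda s: s.cut_after)
    for s in sites:
        if not 0.0 <= s.p_cut <= 1.0:
            raise ValueError("cut probabilities must be in [0, 1]")
    if len(sites) > MAX_EXACT_SITES and probability_floor is None:
        raise ValueError(
            f"{len(sites)} sites exceed the exact-enumeration limit "
            f"({MAX_EXACT_SITES}); supply probability_floor to truncate"
        )
    floor = probability_floor or 0.0
    p = [s.p_cut for s in sites]
    cut = [s.cut_after for s in sites]
    k = len(sites)
    frags = []

    def add(start, end, prob, uncut=False):
        if prob > floor:
            length = end - start + 1
            frags.append(Fragment(start, end, length, prob, uncut))

    none_cut = 1.0
    for pi in p:
        none_cut *= 1.0 - pi

    if k == 0:
        return [Fragment(1, n, n, 1.0, uncut_circle=replicon.circular)]

    if replicon.circular:
        add(1, n, none_cut, uncut=True)
        for i in range(k):
            # clockwise from cut i to the next cut that fires
            prob_run = p[i]
            for step in range(1, k):
                j = (i + step) % k
                start = cut[i] + 1
                end = cut[j] if cut[j] > cut[i] else cut[j] + n
                add(start, end, prob_run * p[j])
                prob_run *= 1.0 - p[j]
            # all the way around: site i is the only one cut, giving the
            # full-length linearised molecule; prob_run is already
            # p_i * prod_{m != i}(1 - p_m)
            add(cut[i] + 1, cut[i] + n, prob_run)
    else:
        # terminal fragment before the first cut that fires
        for j in range(k):
            prob = p[j]
            for m in range(j):
                prob *= 1.0 - p[m]
            add(1, cut[j], prob)
        # internal fragments
        for i in range(k):
            prob_run = p[i]
            for j in range(i + 1, k):
                add(cut[i] + 1, cut[j], prob_run * p[j])
                prob_run *= 1.0 - p[j]
        # terminal fragment after the last cut that fires
        for i in range(k):
            prob = p[i]
            for m in range(i + 1, k):
                prob *= 1.0 - p[m]
            add(cut[i] + 1, n, prob)
        add(1, n, none_cut)

    frags.sort(key=lambda f: (-f.probability, f.start))
    return frags


def probe_filter(fragments, probe: tuple[int, int], n: int | None = None) -> list[Fragment]:
    """Keep fragments overlapping the probe interval by >= 1 nt, sorted by length.

    ``n`` (replicon length) is needed to resolve overlap for fragments that
    wrap the origin (end > n).
    """
    p0, p1 = probe
    out = []
    for f in fragments:
        hit = max(f.start, p0) <= min(f.end, p1)
        if not hit and n is not None and f.end > n:
            # wrapped tail occupies 1..(end - n)
            hit = p0 <= f.end - n
        if hit:
            out.append(f)
    out.sort(key=lambda f: f.length)
    return out


def merge_bands(fragments, resolution: float = 0.05) -> list[dict]:
    """Group fragments whose lengths differ by < ``resolution`` (gel comigration).

    Returns band dicts with the member fragments, a length range, summed
    probability, and a ``merged`` flag — mimicking bands that run together on
    an agarose gel.
    """
    frags = sorted(fragments, key=lambda f: f.length)
    bands = []
    for f in frags:
        if bands and f.length <= bands[-1]["max_length"] * (1 + resolution):
            b = bands[-1]
            b["fragments"].append(f)
            b["max_length"] = max(b["max_length"], f.length)
            b["probability"] += f.probability
            b["merged"] = True
        else:
            bands.append({
                "fragments": [f], "min_length": f.length, "max_length": f.length,
                "probability": f.probability, "merged": False,
            })
    return bands


def fragments_to_tsv(fragments, path, probe: tuple[int, int] | None = None,
                     n: int | None = None) -> None:
    probe_hits = set()
    if probe is not None:
        probe_hits = {(f.start, f.end) for f in probe_filter(fragments, probe, n)}
    rows = [
        {
            "start": f.start, "end": f.end, "length": f.length,
            "probability": f.probability,
            "probe_hit": (f.start, f.end) in probe_hits if probe else "",
        }
        for f in fragments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
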