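# Methods

## Coordinate and strand conventions

All in-memory coordinates are 1-based inclusive, matching how positions are
printed in bacterial genomics (a motif "starting at 7392" occupies
7392..7397). On-disk BED output is 0-based half-open and converted only at
the I/O boundary. Circular replicons wrap modulo their length; motif
matches, reads and digest fragments may span the origin, in which case an
interval's `end` may exceed N in unwrapped coordinates.

A minus-strand motif instance is a match of the reverse-complement pattern
in the forward sequence, reported at the forward coordinate of its leftmost
base. For palindromic recognition sequences (CGATCG, GGCC, GATC, HIP1) the
plus- and minus-strand coordinate sets coincide and each site counts once
per strand; per-strand densities are `N / per-strand count`. `N` bases in a
sequence never satisfy a pattern letter; ambiguity codes are allowed in
patterns only.

## Motif-free regions

A gap is a maximal interval touched by no motif *footprint*
(start..start+len−1, either strand) — being "free of the motif" is a
footprint statement, not a start-coordinate statement. On circular
replicons the two intervals flanking the origin merge. Significance uses
the simplest defensible null: motif starts as a homogeneous Poisson process
of per-position rate λ (estimated from the observed per-strand count unless
supplied), so a fixed window of length L is empty with probability
e^(−λL); a Bonferroni-style correction over the N−L+1 placements gives a
conservative genome-wide p-value. This is a screening statistic, not a
selection test.

## Synthetic replicons

The generator emulates the study system and its defaults are the study
conditions: a 103,307 nt circular replicon; a repeat-spacer array starting
at 16,310 with 50 copies of a 37-nt repeat and 36-nt spacers; an 11,008 nt
GGCC-free region at 3,537..14,544; background GGCC planted at one site per
420 nt per strand (Poisson count over the whole length, placed outside the
desert; the desert boundaries are anchored by a motif footprint on each
side so the maximal gap equals the planted interval exactly); four planted
CGATCG sites at 4,053/7,392/7,839/7,998 with true ⁵ᵐC fractions
0.46/0.02/0.95/0.02 mimicking the hypomethylated cas3′-gene sites; repeat
⁵ᵐC at 0.976 (forward) and 0.925 (reverse) with repeats 22 and 44 lowered
to 0.5 on the reverse strand; a cas-like region (5,000..16,100) at
0.634/0.663; remaining background CGATCG at 0.95/0.93; GATC ⁶ᵐA and GGCC
⁴ᵐC fully methylated. Background GC content is 0.48.

The repeat consensus is a **synthetic** 37-mer (the real repeat sequence is
not reproduced); it preserves what the analysis depends on: exactly one
CGATCG preceded by G (the `GCGATCGG` single-substitution HIP1 variant), no
GGCC, and no GATC outside the motif. Spacers are uniform random with all
three motifs excluded by default (junction windows included), so the
array's event total is exactly 4 × n_repeats; real spacers carry extra
GGCC/GATC sites, which the inventory attributes separately when present.
Spontaneous GGCC occurrences are scrubbed by single-base mutation before
planting, giving exact control of the per-strand count; spontaneous CGATCG
and GATC occurrences are left in place and receive background truth
fractions.

## Bisulfite read simulation

Reads are drawn uniformly (wrapping on circular templates), strand of
origin Bernoulli(½), and emitted pre-aligned in a minimal SAM dialect
(QNAME/FLAG/RNAME/POS/CIGAR=`<len>M`/SEQ, FLAG 16 = minus origin, SEQ in
forward-reference orientation). Read mapping is external tooling and out of
scope. Per covered cytosine on the read's origin strand, the read shows the
protected base with probability m_eff + (1−m_eff)(1−c), where c is the
bisulfite conversion rate (default 0.99) and m_eff is the true methylated
fraction — scaled by the ⁴ᵐC detection efficiency η (default 0.42) at ⁴ᵐC
sites, since bisulfite only partially deaminates N4-methylcytosine. ⁶ᵐA
never changes base identity. Uniform sequencing errors substitute bases at
rate e (default 0). Coverage is total across both strands, so per-strand
site depth is about half the nominal coverage. Defaults of 100 nt reads at
100× are a choice of convenience; the quantities analysed are insensitive
to read length. Quality strings, indels, PCR duplicates and mapper
artefacts are deliberately not modelled — recovery results on synthetic
data therefore bound counting/estimation error only, not alignment error.

## Methylation calling

Counting contract per cytosine site: forward-strand sites use
forward-origin reads (C = methylated, T = converted); reverse-strand sites
use reverse-origin reads (G = methylated, A = converted, in
forward-reference orientation). Any other observed base is excluded from
the fraction and tallied separately, so n_meth + n_unmeth never exceeds
the covering reads. Intervals are Wilson score at 95% (well-behaved near 0
and 1, exactly the hypomethylation regime); region means are unweighted
across covered sites, matching per-site plotting conventions. Hypo/hyper
thresholds default to 0.2/0.8 with strict inequality for hypo (a fraction
equal to the threshold is intermediate); both are exposed. Duplicate reads
are not collapsed (the simulator emits none; real-data deduplication is out
of scope). ⁶ᵐA records carry NA fractions — their status is inferred from
DpnI digestion, not bisulfite.

## Restriction digestion

Cleavage probability per site is the product rule
`∏(1 − f_b) · ∏ f_r` over blocking and required modifications, strands
independent. Hemimethylated PvuI sites are therefore partially cleavable —
the enzyme's true behaviour on hemimethylated CGATCG is not established,
and the product rule is this package's modelling choice. DpnI requires ⁶ᵐA
on both strands; Sau3AI carries no methylation terms. Cut offsets are
PvuI CGAT^CG (top offset 4), DpnI GA^TC (2), Sau3AI ^GATC (0); distances
between same-enzyme cuts equal differences of motif start coordinates, so
fragment-length arithmetic is invariant to the offset convention.

Partial digestion enumerates fragments exactly: a fragment delimited by
sites i < j occurs with probability p_i·p_j·∏_{i<k<j}(1−p_k); linear
templates add terminal fragments and the uncut molecule, circular templates
add the single-cut full-length linearised molecule and the uncut circle.
For every fixed nucleotide the probabilities of fragments covering it sum
to 1. Enumeration is O(k²) and allowed up to 20 sites; beyond that a
probability floor must be supplied and sub-floor bands are dropped.
Probe filtering keeps fragments overlapping the probe by ≥ 1 nt; band
merging groups lengths within 5% to mimic gel comigration. Gel-migration
physics and star activity are not modelled.

## Repeat arrays and events

Repeat finding is tandem matching of a known consensus with a Hamming
mismatch budget (vectorised shift-and-compare), chaining matches whose
gaps fall in a spacer window (default 30–45 nt) and returning the longest
chain — not de-novo CRISPR discovery. Events are distinct
(position, strand, modification) triples, deduplicated across motif specs
(the GATC inside every CGATCG would otherwise double-count its ⁶ᵐA), each
attributed to a repeat, spacer, or neither, and to its methyltransferase.
The per-repeat table pools read counts within each repeat × strand for a
Wilson interval and reports lowest-k repeats with coordinate-ascending tie
breaks. The maturation-nuclease cleavage offset is recorded as metadata
only; RNA secondary structure is not predicted.

## Efficiency statistics

Normalisation divides every replicate count by the reference-cell mean
(wild type × non-target plasmid), so the reference is 1 by construction;
SE = sd/√n with plug-in normalisation (reference uncertainty not
propagated, matching the usual bar-plot presentation). Interference is
called per strain × PAM when the pT/pNT mean ratio falls below a threshold
(default 0.1); plate assays of this kind are near all-or-nothing, so
verdicts are insensitive to the threshold over a wide range. The bundled
simulator draws Poisson counts with functional PAMs at λ_pT and the
non-PAM behaving like the control.

## Problem sizes and numerics

Tests and the acceptance script run on synthetic data at desk scale: the
full 103 kb replicon with 100× reads for landscape/region quantities,
500-site panels at 100× for accuracy (MAE target < 0.05 with per-strand
depth ≈ 50×), 10⁵-trial Monte-Carlo cross-checks for partial digestion
(≤ 6 sites, 3-SE agreement), and 1000-case brute-force equivalence for the
scanner. Fractions at zero coverage are NA, never 0; density of a motif
with zero instances is reported as infinity; gap p-values are clamped to
[0, 1]. All randomness flows through numpy Generators seeded explicitly;
identical seeds give byte-identical replicons, truths and read sets.
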