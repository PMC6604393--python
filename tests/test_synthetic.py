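"""Synthetic replicon construction, read simulation and round-trip I/O."""

import numpy as np
import pandas as pd
import pytest

from repmethyl import (
    GGCC, PlacementError, Replicon, RepliconSpec, build_replicon,
    read_reads, read_truth, scan_motifs, simulate_bisulfite_reads,
    write_reads, write_truth, wilson_interval,
)
from repmethyl.synthetic import content_hash


class TestBuildReplicon:
    def test_array_span_arithmetic(self):
        spec = RepliconSpec(n_repeats=5, spacer_len=36)
        assert len(spec.repeat_seq) == 37
        assert spec.array_span == 5 * 37 + 4 * 36 == 329

    def test_deterministic_for_fixed_seed(self):
        a = build_replicon(RepliconSpec(length=30_000, array_start=20_000,
                                        n_repeats=3, desert_interval=(2_000, 6_000),
                                        planted_cgatcg={}, cas_region=None, seed=42))
        b = build_replicon(RepliconSpec(length=30_000, array_start=20_000,
                                        n_repeats=3, desert_interval=(2_000, 6_000),
                                        planted_cgatcg={}, cas_region=None, seed=42))
        assert a[0].sequence == b[0].sequence
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_desert_has_no_ggcc_by_rescan(self, small_build):
        spec, rep, truth, ann = small_build
        d0, d1 = spec.desert_interval
        inst = scan_motifs(rep, GGCC)
        assert not any(i.start <= d1 and i.end >= d0 for i in inst)
        assert "GGCC" not in rep.fetch(d0, d1 - d0 + 1)

    def test_repeats_verbatim_and_truth_covers_motifs(self, small_build):
        spec, rep, truth, ann = small_build
        for s, e in ann["repeats"].itertuples(index=False):
            assert rep.fetch(s, e - s + 1) == spec.repeat_seq
        # every planted CGATCG has its m5C truth rows on both strands
        for p, frac in ann["planted"].items():
            sub = truth[(truth.modification == "m5C")
                        & truth.position.isin([p, p + 5])]
            assert set(sub.strand) == {"+", "-"}
            assert (sub.fraction == frac).all()

    def test_array_overlapping_desert_rejected(self):
        with pytest.raises(PlacementError):
            RepliconSpec(length=30_000, array_start=3_000, n_repeats=5,
                         desert_interval=(2_000, 10_000)).validate()

    def test_bad_repeat_rejected(self):
        with pytest.raises(ValueError):
            RepliconSpec(repeat_seq="ACGT" * 10).validate()


class TestSimulateReads:
    def _one_site_replicon(self):
        # single CGATCG in an A/T background: the C at position 51 is the site
        seq = "AT" * 25 + "CGATCG" + "TA" * 25
        return Replicon("one", seq, circular=False)

    def _truth(self, frac):
        return pd.DataFrame({
            "position": [51, 56], "strand": ["+", "-"],
            "modification": ["m5C", "m5C"], "fraction": [frac, frac],
            "motif": ["CGATCG", "CGATCG"],
        })

    def test_full_conversion_unmethylated(self):
        rep = self._one_site_replicon()
        rs = simulate_bisulfite_reads(rep, self._truth(0.0), coverage=50,
                                      read_len=40, conversion_rate=1.0,
                                      error_rate=0.0, seed=1)
        for r in rs.reads:
            if r.strand == "+" and r.start <= 51 <= r.start + r.length - 1:
                assert r.sequence[51 - r.start] == "T"

    def test_full_protection_methylated(self):
        rep = self._one_site_replicon()
        rs = simulate_bisulfite_reads(rep, self._truth(1.0), coverage=50,
                                      read_len=40, conversion_rate=0.9,
                                      error_rate=0.0, seed=1)
        for r in rs.reads:
            if r.strand == "+" and r.start <= 51 <= r.start + r.length - 1:
                assert r.sequence[51 - r.start] == "C"

    def test_called_fraction_within_binomial_interval(self):
        """m=0.9, c=0.99: observed protection should match m + (1-m)(1-c)."""
        rep = self._one_site_replicon()
        rs = simulate_bisulfite_reads(rep, self._truth(0.9), coverage=200,
                                      read_len=40, conversion_rate=0.99,
                                      error_rate=0.0, seed=5)
        n_c = n_t = 0
        for r in rs.reads:
            if r.strand == "+" and r.start <= 51 <= r.start + r.length - 1:
                base = r.sequence[51 - r.start]
                n_c += base == "C"
                n_t += base == "T"
        frac = n_c / (n_c + n_t)
        expected = 0.9 + 0.1 * 0.01
        lo, hi = wilson_interval(n_c, n_c + n_t)
        assert lo <= expected <= hi, (frac, expected)

    def test_m6a_never_alters_reads(self):
        seq = "TT" * 20 + "GATC" + "TT" * 20
        rep = Replicon("r", seq, circular=False)
        truth = pd.DataFrame({"position": [42, 43], "strand": ["+", "-"],
                              "modification": ["m6A", "m6A"],
                              "fraction": [1.0, 1.0], "motif": ["GATC", "GATC"]})
        rs = simulate_bisulfite_reads(rep, truth, coverage=30, read_len=30,
                                      conversion_rate=1.0, error_rate=0.0, seed=3)
        for r in rs.reads:
            ref = rep.fetch(r.start, r.length)
            for i, (o, e) in enumerate(zip(r.sequence, ref)):
                pos = r.start + i
                if pos in (41, 42, 43, 44) and e in "GA":
                    if r.strand == "+" and e == "A":
                        assert o == "A"
                    if r.strand == "-" and e == "A":
                        assert o == "A"

    def test_m4c_partial_detection(self):
        """Fully 4mC-methylated GGCC reads ~ eta protected under bisulfite."""
        rng = np.random.default_rng(0)
        seq = "".join("AT" * 10 + "GGCC" + "AT" * 10 for _ in range(50))
        rep = Replicon("r", seq, circular=False)
        positions = [i + 1 for i in range(len(seq)) if seq[i:i + 4] == "GGCC"]
        truth = pd.DataFrame({
            "position": [p + 2 for p in positions], "strand": "+",
            "modification": "m4C", "fraction": 1.0, "motif": "GGCC"})
        rs = simulate_bisulfite_reads(rep, truth, coverage=60, read_len=44,
                                      conversion_rate=1.0, error_rate=0.0,
                                      seed=9, m4c_efficiency=0.42)
        n_c = n_t = 0
        site_set = {p + 2 for p in positions}
        for r in rs.reads:
            if r.strand != "+":
                continue
            for i, b in enumerate(r.sequence):
                if r.start + i in site_set:
                    n_c += b == "C"
                    n_t += b == "T"
        obs = n_c / (n_c + n_t)
        assert obs == pytest.approx(0.42, abs=0.03)

    def test_read_len_longer_than_replicon_rejected(self):
        rep = Replicon("r", "ACGT" * 10, circular=False)
        with pytest.raises(ValueError):
            simulate_bisulfite_reads(rep, pd.DataFrame(columns=["position", "strand",
                                                                "modification", "fraction"]),
                                     coverage=1, read_len=100, seed=0)

    def test_determinism(self, small_build):
        spec, rep, truth, ann = small_build
        a = simulate_bisulfite_reads(rep, truth, coverage=5, read_len=50, seed=4)
        b = simulate_bisulfite_reads(rep, truth, coverage=5, read_len=50, seed=4)
        assert content_hash(a) == content_hash(b)

    def test_circular_reads_wrap_origin(self, small_build):
        spec, rep, truth, ann = small_build
        rs = simulate_bisulfite_reads(rep, truth, coverage=3, read_len=80, seed=8)
        wrapped = [r for r in rs.reads if r.start + r.length - 1 > len(rep)]
        assert wrapped, "expected some origin-spanning reads on a circular replicon"
        r = wrapped[0]
        ref = rep.fetch(r.start, r.length)
        same = sum(a == b for a, b in zip(r.sequence, ref))
        assert same >= 0.6 * r.length  # mostly reference bases survive bisulfite

    def test_parameter_recovery_within_wilson(self):
        """Called fractions match m + (1-m)(1-c) within the Wilson CI for
        >= 93% of 200 uniformly-methylated sites at 100x."""
        rng = np.random.default_rng(12)
        blocks = []
        fracs = rng.uniform(0, 1, size=200)
        for _ in fracs:
            blocks.append("AT" * 12 + "CGATCG" + "TA" * 12)
        seq = "".join(blocks)
        rep = Replicon("r", seq, circular=False)
        positions = [i + 1 for i in range(len(seq)) if seq[i:i + 6] == "CGATCG"]
        assert len(positions) == 200
        truth = pd.DataFrame({"position": positions, "strand": "+",
                              "modification": "m5C", "fraction": fracs,
                              "motif": "CGATCG"})
        c = 0.99
        rs = simulate_bisulfite_reads(rep, truth, coverage=100, read_len=54,
                                      conversion_rate=c, error_rate=0.0, seed=13)
        nm = {p: 0 for p in positions}
        nt = {p: 0 for p in positions}
        for r in rs.reads:
            if r.strand != "+":
                continue
            for p in positions:
                if r.start <= p <= r.start + r.length - 1:
                    b = r.sequence[p - r.start]
                    nm[p] += b == "C"
                    nt[p] += b == "T"
        hits = 0
        for p, m in zip(positions, fracs):
            tot = nm[p] + nt[p]
            lo, hi = wilson_interval(nm[p], tot)
            expected = m + (1 - m) * (1 - c)
            hits += lo <= expected <= hi
        assert hits / len(positions) >= 0.93


class TestRoundTrips:
    def test_truth_roundtrip(self, small_build, tmp_path):
        spec, rep, truth, ann = small_build
        p = tmp_path / "truth.tsv"
        write_truth(truth, p)
        back = read_truth(p)
        pd.testing.assert_frame_equal(truth.reset_index(drop=True), back)

    def test_empty_truth_header_only(self, tmp_path):
        import pandas as pd
        empty = pd.DataFrame(columns=["position", "strand", "modification",
                                      "fraction", "motif"])
        p = tmp_path / "e.tsv"
        write_truth(empty, p)
        assert p.read_text().strip() == "position\tstrand\tmodification\tfraction\tmotif"

    def test_malformed_truth_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("position\tstrand\tmodification\tfraction\tmotif\n"
                     "10\t+\tm5C\t1.7\tCGATCG\n")
        with pytest.raises(ValueError):
            read_truth(p)

    def test_sam_roundtrip_hash_equality(self, small_reads, tmp_path):
        p = tmp_path / "reads.sam"
        write_reads(small_reads, p)
        back = read_reads(p)
        assert back.replicon == small_reads.replicon
        assert back.circular == small_reads.circular
        assert content_hash(back) == content_hash(small_reads)

    def test_malformed_sam_rejected(self, tmp_path):
        p = tmp_path / "bad.sam"
        p.write_text("@SQ\tSN:r\tLN:100\nr1\t0\tr\t1\t255\t5M\t*\t0\t0\tACG\t*\n")
        with pytest.raises(ValueError):
            read_reads(p)
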