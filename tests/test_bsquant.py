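"""Bisulfite reference frames, adapter trimming, read assignment and
per-CpG methylation extraction."""

import numpy as np
import pandas as pd
import pytest

from methylmark.bsquant import (
    FRAMES,
    FormatError,
    assign_reads,
    build_bisulfite_reference,
    coverage_stats,
    extract_methylation,
    find_adapter_start,
    paired_records,
    read_fastq,
    revcomp,
    trim_adapters,
    trim_read,
    write_fastq,
)
from methylmark.io import Amplicon, PanelDefinition, PanelError, TargetLocus
from methylmark.simulate import ReadSimSpec, simulate_panel, simulate_reads

ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


def _panel_from_seq(seq, cpg_offset, primer_spans=()):
    amp = Amplicon("ampX", seq, "chr1", 1000, tuple(primer_spans))
    loc = TargetLocus("LX", "chr1", 1000 + cpg_offset, "ampX", cpg_offset)
    return PanelDefinition(loci=[loc], amplicons={"ampX": amp})


class TestReferenceFrames:
    def test_hand_converted_frames(self):
        seq = "AACGTT" + "A" * 124
        ref = build_bisulfite_reference(_panel_from_seq(seq, 2))
        assert ref.frames[("ampX", "OT")] == "AATGTT" + "A" * 124
        assert ref.frames[("ampX", "OB")] == "AACATT" + "A" * 124
        assert ref.frames[("ampX", "CTOT")] == revcomp("AATGTT" + "A" * 124)
        assert ref.frames[("ampX", "CTOB")] == revcomp("AACATT" + "A" * 124)

    def test_cpg_interrogation_offsets(self):
        seq = "AACGTT" + "A" * 124
        n = len(seq)
        ref = build_bisulfite_reference(_panel_from_seq(seq, 2))
        by_frame = {
            fr: ref.cpg_sites[("ampX", fr)][0] for fr in FRAMES
        }
        assert (by_frame["OT"].frame_offset, by_frame["OT"].meth_base) == (2, "C")
        assert (by_frame["CTOT"].frame_offset, by_frame["CTOT"].meth_base) == (
            n - 3,
            "G",
        )
        assert (by_frame["OB"].frame_offset, by_frame["OB"].meth_base) == (3, "G")
        assert (by_frame["CTOB"].frame_offset, by_frame["CTOB"].meth_base) == (
            n - 4,
            "C",
        )

    def test_cytosine_free_sequence_is_fixed_point_of_top_conversion(self):
        seq = "AG" + "CG" + "T" * 120  # single C is the CpG itself
        ref = build_bisulfite_reference(_panel_from_seq(seq, 2))
        assert "C" not in ref.frames[("ampX", "OT")]
        assert "G" not in ref.frames[("ampX", "OB")]

    def test_random_panel_frame_invariants(self):
        panel = simulate_panel([f"mk{i}" for i in range(6)], seed=4)
        ref = build_bisulfite_reference(panel)
        for amp_id, amp in panel.amplicons.items():
            ot = ref.frames[(amp_id, "OT")]
            ob = ref.frames[(amp_id, "OB")]
            assert "C" not in ot
            assert "G" not in ob
            assert ref.frames[(amp_id, "CTOT")] == revcomp(ot)
            assert ref.frames[(amp_id, "CTOB")] == revcomp(ob)
            assert ot == amp.sequence.upper().replace("C", "T")
            assert ob == amp.sequence.upper().replace("G", "A")

    def test_primer_overlapping_cpg_rejected_at_panel_construction(self):
        seq = "AACG" + "A" * 126
        with pytest.raises(PanelError):
            _panel_from_seq(seq, 2, primer_spans=((0, 10),))

    def test_primer_cytosines_excluded_from_conversion_sites(self):
        seq = "CC" + "ACA" + "CG" + "A" * 118 + "CCCCC"
        panel = _panel_from_seq(seq, 5, primer_spans=((0, 2), (125, 130)))
        ref = build_bisulfite_reference(panel)
        # the only non-primer non-CpG cytosine sits at offset 3
        offs = [s.frame_offset for s in ref.conversion_sites[("ampX", "OT")]]
        assert offs == [3]

    def test_ambiguity_codes_rejected(self):
        seq = "AACG" + "A" * 120 + "RYKMWS"
        amp = Amplicon("ampX", seq, "chr1", 1000)
        panel = PanelDefinition(
            loci=[TargetLocus("LX", "chr1", 1002, "ampX", 2)],
            amplicons={"ampX": amp},
        )
        with pytest.raises(ValueError):
            build_bisulfite_reference(panel)


class TestAdapterTrimming:
    def test_internal_exact_occurrence_found_at_planted_offset(self):
        seq = "C" * 40 + ADAPTER + "C" * 10
        assert find_adapter_start(seq, ADAPTER) == 40
        t, q = trim_read(seq, "I" * len(seq), [ADAPTER])
        assert t == "C" * 40
        assert len(q) == 40

    def test_three_prime_partial_overlap_found(self):
        seq = "C" * 50 + ADAPTER[:8]
        assert find_adapter_start(seq, ADAPTER) == 50

    def test_adapter_free_read_untouched(self):
        seq = "C" * 60
        assert find_adapter_start(seq, ADAPTER) is None
        t, q = trim_read(seq, "I" * 60, [ADAPTER])
        assert (t, q) == (seq, "I" * 60)

    def test_one_mismatch_in_long_overlap_tolerated(self):
        mutated = "T" + ADAPTER[1:]  # 1 mismatch over 33 bases (rate 3%)
        seq = "C" * 40 + mutated + "C" * 5
        assert find_adapter_start(seq, ADAPTER) == 40

    def test_short_pairs_dropped_together(self):
        long1 = ("f1", "C" * 60, "I" * 60)
        long2 = ("f1", "C" * 60, "I" * 60)
        short1 = ("f2", "C" * 10 + ADAPTER, "I" * 43)
        long_mate = ("f2", "C" * 60, "I" * 60)
        out1, out2, dropped = trim_adapters(
            [long1, short1], [long2, long_mate], [ADAPTER], min_length=30
        )
        assert dropped == 1
        assert [r[0] for r in out1] == ["f1"]
        assert [r[0] for r in out2] == ["f1"]

    def test_unpaired_inputs_rejected(self):
        r = ("f1", "C" * 60, "I" * 60)
        with pytest.raises(FormatError):
            trim_adapters([r, r], [r], [ADAPTER])
        with pytest.raises(FormatError):
            trim_adapters([("a", "C" * 60, "I" * 60)], [("b", "C" * 60, "I" * 60)], [ADAPTER])

    def test_fastq_round_trip(self, tmp_path):
        recs = [("f1", "ACGT" * 10, "I" * 40), ("f2", "TTTT" * 10, "#" * 40)]
        for name in ("r.fastq", "r.fastq.gz"):
            write_fastq(recs, tmp_path / name)
            assert read_fastq(tmp_path / name) == recs


@pytest.fixture(scope="module")
def small_ref():
    panel = simulate_panel(["mkA", "mkB", "mkC"], seed=5)
    return panel, build_bisulfite_reference(panel)


@pytest.fixture(scope="module")
def one_locus():
    panel = simulate_panel(["mk1"], seed=7)
    ref = build_bisulfite_reference(panel)
    loc = panel.loci[0]
    ot = ref.frames[(loc.amplicon_id, "OT")]
    meth_read = ot[: loc.cpg_offset] + "C" + ot[loc.cpg_offset + 1 :]
    unmeth_read = ot
    return panel, ref, loc, meth_read, unmeth_read


class TestAssignReads:
    def test_frame_substring_assigned_to_its_window(self, small_ref):
        panel, ref = small_ref
        reads = []
        expected = []
        for (amp, fr), seq in ref.frames.items():
            reads.append((f"{amp}_{fr}", 1, seq[7 : 7 + 80]))
            expected.append((amp, fr, 7))
        out = assign_reads(reads, ref)
        tab = out.table.set_index("name")
        for (amp, fr, off), name in zip(expected, [r[0] for r in reads]):
            row = tab.loc[name]
            assert row["status"] == "assigned"
            assert (row["amplicon_id"], row["frame"], row["offset"]) == (amp, fr, off)
            assert row["score"] == 1.0

    def test_random_reads_left_unassigned(self, small_ref):
        _, ref = small_ref
        rng = np.random.default_rng(6)
        reads = [
            (f"r{i}", 1, "".join("ACGT"[b] for b in rng.integers(0, 4, 100)))
            for i in range(20)
        ]
        out = assign_reads(reads, ref)
        assert (out.table["status"] != "assigned").all()

    def test_simulated_reads_recover_their_source_amplicon(self, small_ref):
        panel, ref = small_ref
        spec = ReadSimSpec(
            mean_coverage=80,
            coverage_range=(40, 160),
            error_rate=0.005,
            off_target_fraction=0.0,
            seed=11,
        )
        beta = pd.Series(0.5, index=panel.locus_ids)
        r1, r2, truth = simulate_reads(panel, beta, spec)
        out = assign_reads(paired_records(r1, r2), ref)
        tab = out.table
        assigned = tab[tab["status"] == "assigned"]
        assert len(assigned) / len(tab) >= 0.99
        src = truth.fragments["amplicon_id"]
        mismatched = (
            assigned["amplicon_id"].to_numpy()
            != src.loc[assigned["name"]].to_numpy()
        ).sum()
        assert mismatched == 0

    def test_off_target_reads_rejected(self, small_ref):
        panel, ref = small_ref
        spec = ReadSimSpec(
            mean_coverage=60,
            coverage_range=(30, 120),
            error_rate=0.0,
            off_target_fraction=0.2,
            seed=13,
        )
        beta = pd.Series(0.5, index=panel.locus_ids)
        r1, r2, truth = simulate_reads(panel, beta, spec)
        out = assign_reads(paired_records(r1, r2), ref)
        off_names = set(truth.fragments.index[truth.fragments["off_target"]])
        tab = out.table
        off_rows = tab[tab["name"].isin(off_names)]
        assert len(off_rows) > 0
        assert (off_rows["status"] != "assigned").all()


class TestExtraction:
    def _quantify(self, panel, ref, reads, **kw):
        return extract_methylation(assign_reads(reads, ref), panel, ref, **kw)

    def test_fully_methylated_reads_give_beta_one(self, one_locus):
        panel, ref, loc, meth_read, _ = one_locus
        reads = [(f"f{i}", 1, meth_read) for i in range(12)]
        calls = self._quantify(panel, ref, reads)
        row = calls.table.loc[loc.locus_id]
        assert (row["n_meth"], row["n_unmeth"]) == (12, 0)
        assert row["beta"] == 1.0
        # non-CpG cytosines in these reads are all converted
        assert calls.conversion_rate == 1.0

    def test_hand_counted_mixture_gives_exact_beta(self, one_locus):
        panel, ref, loc, meth_read, unmeth_read = one_locus
        reads = [(f"m{i}", 1, meth_read) for i in range(3)]
        reads += [(f"u{i}", 1, unmeth_read) for i in range(9)]
        calls = self._quantify(panel, ref, reads)
        row = calls.table.loc[loc.locus_id]
        assert (row["n_meth"], row["n_unmeth"]) == (3, 9)
        assert row["beta"] == pytest.approx(0.25)

    def test_coverage_floor_yields_missing_not_zero(self, one_locus):
        panel, ref, loc, meth_read, _ = one_locus
        reads = [(f"f{i}", 1, meth_read) for i in range(5)]
        calls = self._quantify(panel, ref, reads, min_coverage=10)
        row = calls.table.loc[loc.locus_id]
        assert row["coverage"] == 5
        assert np.isnan(row["beta"])

    def test_disagreeing_mates_counted_once_mate1_wins(self, one_locus):
        panel, ref, loc, meth_read, unmeth_read = one_locus
        reads = []
        for i in range(10):
            reads.append((f"f{i}", 1, meth_read))
            reads.append((f"f{i}", 2, unmeth_read))
        calls = self._quantify(panel, ref, reads)
        row = calls.table.loc[loc.locus_id]
        assert (row["n_meth"], row["n_unmeth"]) == (10, 0)
        assert row["beta"] == 1.0

    def test_fully_unconverted_read_is_strand_ambiguous(self, one_locus):
        panel, ref, loc, *_ = one_locus
        raw = panel.amplicons[loc.amplicon_id].sequence  # no bisulfite at all
        out = assign_reads([("f0", 1, raw)], ref)
        # both reduction routes match perfectly, so the strand is undecidable
        assert out.table["status"].iloc[0] == "ambiguous"

    def test_partial_conversion_rate_counted_exactly(self, one_locus):
        panel, ref, loc, *_ = one_locus
        raw = panel.amplicons[loc.amplicon_id].sequence
        sites = sorted(
            s.frame_offset for s in ref.conversion_sites[(loc.amplicon_id, "OT")]
        )
        n_convert = len(sites) // 2
        read = list(raw)
        for off in sites:  # convert every non-CpG C first ...
            read[off] = "T"
        for off in sites[n_convert:]:  # ... then restore the unconverted half
            read[off] = "C"
        read = "".join(read)
        reads = [(f"f{i}", 1, read) for i in range(10)]
        calls = self._quantify(panel, ref, reads)
        assert calls.conversion_rate == pytest.approx(n_convert / len(sites))

    def test_top_and_complementary_frames_count_identically(self):
        panel = simulate_panel(["mkA", "mkB"], seed=9)
        ref = build_bisulfite_reference(panel)
        beta = pd.Series([0.3, 0.8], index=panel.locus_ids)
        tables = []
        for frames in (("OT", "OB"), ("CTOT", "CTOB")):
            spec = ReadSimSpec(
                mean_coverage=120,
                coverage_range=(60, 240),
                error_rate=0.0,
                conversion_rate=1.0,
                off_target_fraction=0.0,
                frames=frames,
                seed=21,
            )
            r1, r2, _ = simulate_reads(panel, beta, spec)
            calls = extract_methylation(
                assign_reads(paired_records(r1, r2), ref), panel, ref
            )
            tables.append(calls.table)
        pd.testing.assert_frame_equal(tables[0], tables[1])

    def test_error_free_counts_match_generator_truth_exactly(self):
        panel = simulate_panel(["mkA", "mkB", "mkC"], seed=15)
        ref = build_bisulfite_reference(panel)
        beta = pd.Series([0.0, 0.4, 1.0], index=panel.locus_ids)
        spec = ReadSimSpec(
            mean_coverage=100,
            coverage_range=(50, 200),
            error_rate=0.0,
            conversion_rate=1.0,
            off_target_fraction=0.0,
            seed=17,
        )
        r1, r2, truth = simulate_reads(panel, beta, spec)
        # short amplicons read through into adapter: trim before assignment
        t1, t2, _ = trim_adapters(r1, r2, [spec.adapter])
        calls = extract_methylation(
            assign_reads(paired_records(t1, t2), ref), panel, ref
        )
        expected = truth.truth_counts()
        got = calls.table[["n_meth", "n_unmeth"]].loc[expected.index]
        pd.testing.assert_frame_equal(got, expected, check_dtype=False)
        assert calls.conversion_rate == 1.0


class TestCoverageStats:
    def test_on_target_fraction_and_fragment_counts(self):
        panel = simulate_panel(["mkA", "mkB"], seed=19)
        ref = build_bisulfite_reference(panel)
        beta = pd.Series(0.5, index=panel.locus_ids)
        spec = ReadSimSpec(
            mean_coverage=80,
            coverage_range=(40, 160),
            error_rate=0.0,
            off_target_fraction=0.1,
            seed=23,
        )
        r1, r2, truth = simulate_reads(panel, beta, spec)
        out = assign_reads(paired_records(r1, r2), ref)
        rep = coverage_stats(out, panel)
        assert rep.total_reads == 2 * len(r1)
        assert rep.aligned_reads == len(out.assigned)
        assert rep.on_target_fraction == rep.aligned_reads / rep.total_reads
        on_target = truth.fragments[~truth.fragments["off_target"]]
        expected = on_target.groupby("amplicon_id").size()
        for amp_id, n in expected.items():
            assert rep.per_amplicon.at[amp_id, "n_fragments"] == n
        assert rep.mean_depth is not None and rep.mean_depth > 0

    def test_single_full_length_fragment_depth(self):
        panel = simulate_panel(["mk1"], seed=25)
        ref = build_bisulfite_reference(panel)
        loc = panel.loci[0]
        ot = ref.frames[(loc.amplicon_id, "OT")]
        # both mates cover the entire amplicon: unioned depth is exactly 1
        reads = [("f0", 1, ot), ("f0", 2, revcomp(ot))]
        rep = coverage_stats(assign_reads(reads, ref), panel)
        assert rep.per_amplicon.at[loc.amplicon_id, "depth"] == pytest.approx(1.0)
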