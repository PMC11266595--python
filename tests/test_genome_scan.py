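import numpy as np
import pytest

from asorf.composition import STOP_CODONS
from asorf.frame_model import revcomp
from asorf.genome_scan import (
    Feature,
    ORFRecord,
    classify_frame,
    exon_gc_comparison,
    find_orfs,
    read_fasta,
    read_gff3,
    scan_antisense_transcripts,
    scan_intergenic,
    sub_orfs,
)
from asorf.synthetic_data import intergenic_features


class TestFindORFs:
    def test_minimal_orf(self):
        orfs = find_orfs("ATGAAATGA", min_len=9)
        assert len(orfs) == 1
        assert (orfs[0].start, orfs[0].end) == (0, 9)

    def test_longest_per_stop(self):
        orfs = find_orfs("ATGATGAAATGA", min_len=9)
        assert len(orfs) == 1
        assert (orfs[0].start, orfs[0].end) == (0, 12)

    def test_min_len_counts_terminal_stop(self):
        assert find_orfs("ATGAAATGA", min_len=10) == []

    def test_all_frames_scanned(self):
        seq = "C" + "ATGAAATGA" + "CC"
        orfs = find_orfs(seq, min_len=9)
        assert [(o.start, o.end) for o in orfs] == [(1, 10)]

    def test_ambiguous_codon_breaks_orf(self):
        assert find_orfs("ATGANATGA", min_len=9) == []

    def test_reverse_complement_mirrors_coordinates(self, rng):
        # an ORF at [s, e) of the reverse complement corresponds to the
        # mirrored interval [L-e, L-s) of the forward sequence, whose
        # reverse complement is the ORF sequence itself
        seq = "".join(rng.choice(list("ACGT"), size=900))
        L = len(seq)
        rev = find_orfs(revcomp(seq))
        assert rev, "fixture sequence should contain minus-strand ORFs"
        for orf in rev:
            assert revcomp(seq[L - orf.end:L - orf.start]) == orf.sequence

    def test_found_orfs_satisfy_invariants(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        for orf in find_orfs(seq):
            orf.validate()


class TestSubORFs:
    def test_internal_atg(self):
        parent = find_orfs("ATGATGAAAAAATGA", min_len=12)[0]
        subs = sub_orfs(parent, min_len=12)
        assert len(subs) == 1
        assert subs[0].is_sub_orf
        assert subs[0].sequence == "ATGAAAAAATGA"
        assert subs[0].stop_anchor == parent.stop_anchor

    def test_no_internal_atg(self):
        parent = find_orfs("ATGAAAAAATGA", min_len=12)[0]
        assert sub_orfs(parent, min_len=12) == []

    def test_count_matches_brute_force(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        for parent in find_orfs(seq, min_len=30):
            subs = sub_orfs(parent, min_len=30)
            # oracle: in-frame ATGs in the interior with >= 30 nt to the stop
            expected = sum(
                1 for j in range(3, parent.length_nt - 3, 3)
                if parent.sequence[j:j + 3] == "ATG" and parent.length_nt - j >= 30)
            assert len(subs) == expected
            for s in subs:
                s.validate()


class TestClassifyFrame:
    def _orf(self, start, end, strand="-"):
        return ORFRecord("c", start, end, strand, "ATG" + "A" * (end - start - 6) + "TGA")

    @pytest.mark.parametrize("a_end,frame", [(16, 0), (15, 1), (14, 2)])
    def test_plus_strand_sense(self, a_end, frame):
        cds = Feature("c", 10, 40, "+")
        ov = classify_frame(self._orf(a_end - 9, a_end), cds)
        assert ov.frame == frame

    def test_anchor_invariance(self):
        # any codon start of the sense CDS gives the same frame
        orf = self._orf(4, 16)
        for shift in (0, 3, 6):
            assert classify_frame(orf, Feature("c", 1 + shift, 40, "+")).frame == \
                classify_frame(orf, Feature("c", 1, 40, "+")).frame

    @pytest.mark.parametrize("a_start,frame", [(34, 0), (35, 1), (36, 2)])
    def test_minus_strand_sense(self, a_start, frame):
        cds = Feature("c", 10, 40, "-")
        ov = classify_frame(self._orf(a_start, a_start + 9, strand="+"), cds)
        assert ov.frame == frame

    def test_same_strand_error(self):
        with pytest.raises(ValueError):
            classify_frame(self._orf(10, 19, strand="+"), Feature("c", 10, 40, "+"))

    def test_no_overlap_error(self):
        with pytest.raises(ValueError):
            classify_frame(self._orf(100, 109), Feature("c", 10, 40, "+"))

    def test_overlap_fraction(self):
        ov = classify_frame(self._orf(4, 16), Feature("c", 10, 40, "+"))
        assert ov.overlap_fraction == pytest.approx(6 / 12)


class TestScan:
    def test_planted_asorfs_recovered_exactly(self, planted_bundle):
        b = planted_bundle
        res = scan_antisense_transcripts(b.genome, b.cds, b.transcripts)
        found = {(o.orf.start, o.orf.end, o.orf.strand): o.frame for o in res.asorfs}
        assert len(b.ground_truth) == 9
        for _, row in b.ground_truth.iterrows():
            key = (row.start, row.end, row.strand)
            assert key in found, f"planted asORF not recovered: {dict(row)}"
            assert found[key] == row.frame

    def test_planted_asorfs_fully_contained(self, planted_bundle):
        b = planted_bundle
        res = scan_antisense_transcripts(b.genome, b.cds, b.transcripts)
        truth_keys = set(map(tuple, b.ground_truth[["start", "end"]].values))
        for ov in res.asorfs:
            if (ov.orf.start, ov.orf.end) in truth_keys:
                assert ov.overlap_fraction == 1.0

    def test_empty_transcripts(self, planted_bundle):
        b = planted_bundle
        res = scan_antisense_transcripts(b.genome, b.cds, [])
        assert res.asorfs == [] and res.multi_cds == []

    def test_missing_contig_error(self, planted_bundle):
        b = planted_bundle
        bad = [Feature("nope", 0, 100, "-", "tx")]
        with pytest.raises(ValueError, match="missing"):
            scan_antisense_transcripts(b.genome, b.cds, bad)

    def test_summary_shape(self, planted_bundle):
        b = planted_bundle
        res = scan_antisense_transcripts(b.genome, b.cds, b.transcripts,
                                         include_sub_orfs=True)
        table = res.summary()
        assert list(table.columns) == ["frame0", "frame1", "frame2"]
        assert (table.loc["n_orfs_with_sub_orfs"] >= table.loc["n_orfs"]).all()

    def test_intergenic_scan_both_strands(self, planted_bundle):
        b = planted_bundle
        ig = intergenic_features(b)
        one = scan_intergenic(b.genome, ig, strands="+")
        both = scan_intergenic(b.genome, ig, strands="both")
        assert len(both) >= len(one)
        for orf in both:
            orf.validate()


class TestExonGC:
    def test_identical_sets(self):
        exons = ["ATGCATGCAA", "GGGCCCATAT"]
        res = exon_gc_comparison(exons, exons, alternative="less")
        assert res["median_overlap"] == res["median_all"]
        assert res["p_value"] > 0.4

    def test_gc_shift_detected(self, rng):
        def draw(g, n):
            p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
            return ["".join(rng.choice(list("ACGT"), size=300, p=p)) for _ in range(n)]

        res = exon_gc_comparison(draw(0.36, 60), draw(0.44, 60), alternative="less")
        assert res["median_overlap"] < res["median_all"]
        assert res["p_value"] < 1e-6

    def test_empty_set_error(self):
        with pytest.raises(ValueError):
            exon_gc_comparison([], ["ACGT"])


class TestFileIO:
    def test_fasta_gff_round_trip(self, planted_bundle, tmp_path):
        planted_bundle.write(tmp_path)
        genome = read_fasta(tmp_path / "genome.fa")
        assert genome == planted_bundle.genome
        cds = read_gff3(tmp_path / "cds.gff3")
        assert [(f.seq_id, f.start, f.end, f.strand) for f in cds] == \
            [(f.seq_id, f.start, f.end, f.strand) for f in planted_bundle.cds]
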