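import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dualcassette.counting import (
    AlignedRead,
    JunctionCountVector,
    SamParseError,
    UniquenessPolicy,
    count_junction_reads,
    count_sam,
    junctions_of_read,
    parse_alignments,
    pool_counts,
    read_grouping_table,
    read_junction_table,
    read_sj_tab,
    write_junction_table,
)
from dualcassette.events import JUNCTION_ORDER, enumerate_junctions
from dualcassette.simulate import DEFAULT_TOY_EVENT, SimulationConfig, simulate_alignments


def sam_line(read_id="r1", flag=0, chrom="chr1", pos=191, mapq=50, cigar="10M100N15M",
             tags=("NH:i:1",)):
    cols = [read_id, str(flag), chrom, str(pos), str(mapq), cigar, "*", "0", "0", "*", "*"]
    return "\t".join(cols + list(tags))


class TestParseAlignments:
    def test_basic_record(self):
        reads = list(parse_alignments([sam_line()]))
        assert len(reads) == 1
        r = reads[0]
        assert (r.read_id, r.chrom, r.pos, r.mapq, r.nh_tag) == ("r1", "chr1", 191, 50, 1)
        assert r.cigar == (("M", 10), ("N", 100), ("M", 15))

    @pytest.mark.parametrize("flag", [4, 0x100, 0x800])
    def test_unmapped_secondary_supplementary_skipped(self, flag):
        assert list(parse_alignments([sam_line(flag=flag)])) == []

    def test_header_lines_skipped_and_optional(self):
        lines = ["@HD\tVN:1.6", "@SQ\tSN:chr1\tLN:1000", sam_line()]
        assert len(list(parse_alignments(lines))) == 1
        assert len(list(parse_alignments([sam_line()]))) == 1

    def test_invalid_cigar_reports_line_number(self):
        lines = [sam_line(), sam_line(read_id="r2", cigar="10M5Q")]
        with pytest.raises(SamParseError, match="line 2"):
            list(parse_alignments(lines))

    def test_missing_columns_reports_line_number(self):
        with pytest.raises(SamParseError, match="line 1"):
            list(parse_alignments(["r1\t0\tchr1\t191"]))

    def test_no_nh_tag_is_none(self):
        (r,) = parse_alignments([sam_line(tags=())])
        assert r.nh_tag is None


class TestJunctionsOfRead:
    def _read(self, pos, cigar):
        (r,) = parse_alignments([sam_line(pos=pos, cigar=cigar)])
        return r

    def test_single_gap_hand_trace(self):
        # pos 191, 10M -> bases 191..200, 100N -> intron, 15M -> 301..315
        (obs,) = junctions_of_read(self._read(191, "10M100N15M"))
        assert (obs.donor, obs.acceptor, obs.left_anchor, obs.right_anchor) == (200, 301, 10, 15)

    def test_two_gaps_hand_trace(self):
        obs = junctions_of_read(self._read(191, "10M100N5M160N20M"))
        assert [(o.donor, o.acceptor) for o in obs] == [(200, 301), (305, 466)]
        assert [(o.left_anchor, o.right_anchor) for o in obs] == [(10, 5), (5, 20)]

    def test_no_gap(self):
        assert junctions_of_read(self._read(191, "25M")) == []

    def test_deletion_counts_as_anchor_insertion_does_not(self):
        # 3M2D5M: reference walk 191..200 (10 ref bases), anchor 3+2+5=10
        (obs,) = junctions_of_read(self._read(191, "3M2D5M100N15M"))
        assert (obs.donor, obs.acceptor, obs.left_anchor) == (200, 301, 10)
        # 5M3I2M consumes 7 reference bases -> donor 197, anchor 7
        (obs,) = junctions_of_read(self._read(191, "5M3I2M100N15M"))
        assert (obs.donor, obs.acceptor, obs.left_anchor) == (197, 298, 7)

    def test_soft_clip_contributes_no_anchor(self):
        (obs,) = junctions_of_read(self._read(191, "4S10M100N15M6S"))
        assert (obs.left_anchor, obs.right_anchor) == (10, 15)


class TestCountJunctionReads:
    def _count(self, lines, event, **kw):
        return count_junction_reads(
            parse_alignments(lines), enumerate_junctions(event), chrom=event.chrom, **kw
        )

    def test_single_match(self, event):
        vec = self._count([sam_line()], event, min_overhang=5)
        assert vec.counts == (1, 0, 0, 0, 0, 0)
        assert vec.n_reads_counted == 1

    def test_anchor_filter(self, event):
        vec = self._count([sam_line(pos=198, cigar="3M100N15M")], event, min_overhang=5)
        assert vec.counts == (0, 0, 0, 0, 0, 0)
        assert vec.n_discarded_anchor == 1

    def test_uniqueness_filter_nh(self, event):
        vec = self._count([sam_line(tags=("NH:i:3",))], event, min_overhang=5)
        assert vec.counts == (0, 0, 0, 0, 0, 0)
        assert vec.n_discarded_nonunique == 1

    def test_mapq_fallback_when_nh_absent(self, event):
        lines = [sam_line(mapq=3, tags=())]
        assert self._count(lines, event).counts == (0, 0, 0, 0, 0, 0)
        assert self._count([sam_line(mapq=30, tags=())], event).counts == (1, 0, 0, 0, 0, 0)
        relaxed = UniquenessPolicy(min_mapq=0)
        assert self._count(lines, event, uniqueness=relaxed).counts == (1, 0, 0, 0, 0, 0)

    def test_chrom_mismatch_warns_all_zero(self, event):
        vec = self._count([sam_line(chrom="chr9")], event)
        assert vec.counts == (0, 0, 0, 0, 0, 0)
        assert vec.n_off_event == 1 and vec.warnings

    def test_dual_junction_read_counts_both_by_default(self, event):
        # spans C1A1 (200,301) and A1A2 (360,461): 10M into C1, all of A1, 20M into A2
        line = sam_line(pos=191, cigar="10M100N60M100N20M")
        vec = self._count([line], event, min_overhang=5)
        assert vec.counts == (1, 0, 0, 1, 0, 0)
        once = self._count([line], event, min_overhang=5, count_once=True)
        assert once.counts == (1, 0, 0, 0, 0, 0)

    def test_near_miss_tallied_never_counted(self, event):
        vec = self._count([sam_line(pos=192, cigar="10M99N15M")], event)  # donor 201, acceptor 301
        assert vec.counts == (0, 0, 0, 0, 0, 0)
        assert vec.n_near_miss == 1

    def test_read_accounting_is_complete(self, event):
        lines = [
            sam_line(),                                   # counted
            sam_line(read_id="r2", cigar="25M"),          # non-junction
            sam_line(read_id="r3", tags=("NH:i:2",)),     # non-unique
            sam_line(read_id="r4", pos=198, cigar="3M100N15M"),  # anchor fail
            sam_line(read_id="r5", chrom="chrX"),         # off-event
        ]
        vec = self._count(lines, event, min_overhang=5)
        assert vec.n_reads_seen == 5
        assert (vec.n_reads_counted + vec.n_discarded_nonunique + vec.n_discarded_anchor
                + vec.n_non_junction + vec.n_off_event) == vec.n_reads_seen

    def test_min_overhang_monotonicity(self, event):
        cfg = SimulationConfig(fractions=(0.25, 0.5, 0.0, 0.25), seed=3)
        sam, _ = simulate_alignments(DEFAULT_TOY_EVENT, cfg, 2000)
        prev = None
        for oh in (1, 5, 10, 20):
            vec = count_sam(sam.splitlines(), DEFAULT_TOY_EVENT, min_overhang=oh)
            if prev is not None:
                assert all(a <= b for a, b in zip(vec.counts, prev))
            prev = vec.counts

    def test_order_invariance(self, event):
        lines = [sam_line(read_id=f"r{i}") for i in range(5)] + [
            sam_line(read_id="s", pos=191, cigar="10M420N30M")  # C1C2
        ]
        fwd = self._count(lines, event)
        rev = self._count(list(reversed(lines)), event)
        assert fwd.counts == rev.counts


class TestTables:
    def test_round_trip(self, tmp_path):
        vecs = [
            JunctionCountVector("s1", (15, 0, 5, 5, 10, 5)),
            JunctionCountVector("s2", (0, 0, 7, 0, 0, 0)),
        ]
        path = tmp_path / "counts.tsv"
        write_junction_table(vecs, path)
        assert read_junction_table(path) == vecs

    @given(counts=st.lists(st.integers(0, 1000), min_size=6, max_size=6))
    def test_round_trip_property(self, tmp_path_factory, counts):
        path = tmp_path_factory.mktemp("t") / "c.tsv"
        vec = JunctionCountVector("s", tuple(counts))
        write_junction_table([vec], path)
        assert read_junction_table(path) == [vec]

    def test_missing_rows_default_zero(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("sample_id\tjunction_label\tcount\ns1\tC1C2\t7\n")
        assert read_junction_table(path) == [JunctionCountVector("s1", (0, 0, 7, 0, 0, 0))]

    def test_unknown_label_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("sample_id\tjunction_label\tcount\ns1\tC1A3\t2\n")
        with pytest.raises(ValueError, match="unknown junction label"):
            read_junction_table(path)

    def test_bad_count_reports_row(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("sample_id\tjunction_label\tcount\ns1\tC1C2\t-3\n")
        with pytest.raises(ValueError, match="row 2"):
            read_junction_table(path)

    def test_sj_tab_intron_coordinates(self, event, tmp_path):
        # C1A1 junction (donor 200, acceptor 301) <-> intron 201..300
        path = tmp_path / "sj.tab"
        path.write_text(
            "chr1\t201\t300\t1\t1\t1\t12\t3\t30\n"
            "chr1\t201\t620\t1\t1\t1\t4\t0\t30\n"   # C1C2 intron
            "chr1\t999\t1500\t1\t1\t1\t9\t0\t30\n"  # unrelated junction
            "chr9\t201\t300\t1\t1\t1\t5\t0\t30\n"   # wrong chromosome
        )
        vec = read_sj_tab(path, enumerate_junctions(event), chrom="chr1")
        assert vec.counts == (12, 0, 4, 0, 0, 0)


class TestPooling:
    def test_elementwise_sum(self):
        vecs = [
            JunctionCountVector("c1", (1, 0, 0, 0, 1, 0)),
            JunctionCountVector("c2", (1, 0, 1, 0, 0, 0)),
        ]
        (pooled,) = pool_counts(vecs, {"c1": "G", "c2": "G"})
        assert pooled.counts == (2, 0, 1, 0, 1, 0)
        assert pooled.n_members == 2

    def test_empty_group_retained(self):
        pooled = pool_counts([JunctionCountVector("c1", (1, 0, 0, 0, 0, 0))],
                             {"c1": "G1", "ghost": "G2"})
        by_id = {p.sample_id: p for p in pooled}
        assert by_id["G2"].counts == (0, 0, 0, 0, 0, 0)
        assert by_id["G2"].n_members == 0

    def test_unassigned_sample_strict_vs_permissive(self):
        vecs = [JunctionCountVector("orphan", (1, 0, 0, 0, 0, 0))]
        with pytest.raises(ValueError, match="orphan"):
            pool_counts(vecs, {"other": "G"})
        pooled = pool_counts(vecs, {"other": "G"}, strict=False)
        assert pooled[0].counts == (0, 0, 0, 0, 0, 0)

    @given(
        st.lists(
            st.tuples(st.integers(0, 3), st.lists(st.integers(0, 50), min_size=6, max_size=6)),
            min_size=1, max_size=30,
        )
    )
    def test_conservation_and_order_invariance(self, assignments):
        vecs = [JunctionCountVector(f"s{i}", tuple(c)) for i, (_, c) in enumerate(assignments)]
        grouping = {f"s{i}": f"g{g}" for i, (g, _) in enumerate(assignments)}
        pooled = pool_counts(vecs, grouping)
        total_pooled = np.sum([p.counts for p in pooled], axis=0)
        total_samples = np.sum([v.counts for v in vecs], axis=0)
        np.testing.assert_array_equal(total_pooled, total_samples)
        shuffled = pool_counts(list(reversed(vecs)), grouping)
        assert {p.sample_id: p.counts for p in shuffled} == {p.sample_id: p.counts for p in pooled}

    def test_grouping_table_io(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("sample_id\tgroup_id\nc1\tG1\nc2\tG1\nc3\tG2\n")
        assert read_grouping_table(path) == {"c1": "G1", "c2": "G1", "c3": "G2"}
        path.write_text("sample_id\tgroup_id\nc1\tG1\nc1\tG2\n")
        with pytest.raises(ValueError, match="two groups"):
            read_grouping_table(path)


class TestPysamCrossCheck:
    def test_simulated_sam_matches_pysam_intron_counts(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        cfg = SimulationConfig(fractions=(0.25, 0.5, 0.0, 0.25), seed=11)
        sam, _ = simulate_alignments(DEFAULT_TOY_EVENT, cfg, 3000)
        path = tmp_path / "sim.sam"
        path.write_text(sam)
        with pysam.AlignmentFile(str(path), "r") as af:
            introns = af.find_introns(read for read in af)
        junctions = enumerate_junctions(DEFAULT_TOY_EVENT)
        # pysam keys are 0-based (intron start, one-past-end):
        # donor = start, acceptor = stop + 1 in 1-based exon coordinates
        pysam_counts = [introns.get((j.donor, j.acceptor - 1), 0) for j in junctions]
        vec = count_sam(str(path), DEFAULT_TOY_EVENT, min_overhang=1)
        assert list(vec.counts) == pysam_counts
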