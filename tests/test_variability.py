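"""variability: n_i, v_j, region calling and locus categorization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import brute_force_column_states

from itxscan.fixtures import gen_alignment
from itxscan.variability import (
    Alignment,
    HomologySegment,
    VariabilityParams,
    categorize_locus,
    column_states,
    detect_variable_regions,
    read_aligned_fasta,
    read_blast_tab,
    segments_from_table,
    variability_profile,
    variable_length_at,
)


class TestColumnStates:
    def test_identical_rows_are_monomorphic(self):
        aln = Alignment(ids=("a", "b", "c", "d"), rows=("ACGT-",) * 4)
        assert column_states(aln).tolist() == [1, 1, 1, 1, 1]

    def test_all_five_states(self):
        aln = Alignment(ids=tuple("abcde"), rows=("A", "C", "G", "T", "-"))
        assert column_states(aln).tolist() == [5]

    def test_n_is_not_a_state(self):
        aln = Alignment(ids=("a", "b", "c"), rows=("AN", "AN", "CN"))
        assert column_states(aln).tolist() == [2, 1]

    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_set_recount(self, seed):
        rng = np.random.default_rng(seed)
        rows = tuple(
            "".join(rng.choice(list("ACGTN-"), size=80)) for _ in range(6)
        )
        aln = Alignment(ids=tuple(f"s{i}" for i in range(6)), rows=rows)
        assert column_states(aln).tolist() == brute_force_column_states(rows)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            Alignment(ids=("a", "b"), rows=("ACGT", "ACG"))

    def test_adding_identical_row_changes_nothing(self):
        aln = gen_alignment(5, 120, blocks=[(30, 60, 3)], seed=7)
        n1 = column_states(aln)
        bigger = Alignment(ids=aln.ids + ("copy",), rows=aln.rows + (aln.rows[0],))
        n2 = column_states(bigger)
        # the duplicated row realizes no new symbol anywhere
        assert (n2 >= n1).all() and (n2 <= 5).all()
        regions1 = detect_variable_regions(variability_profile(n1).v)
        regions2 = detect_variable_regions(variability_profile(n2).v)
        if (n1 == n2).all():
            assert regions1 == regions2


class TestProfile:
    def test_conserved_alignment_is_zero(self):
        v = variability_profile(np.ones(40, dtype=int)).v
        defined = v[~np.isnan(v)]
        assert (defined == 0).all()
        assert np.isnan(v[:5]).all() and np.isnan(v[-5:]).all()

    def test_single_polymorphic_column(self):
        n = np.ones(40, dtype=int)
        n[20] = 5
        v = variability_profile(n).v
        covering = [j for j in range(15, 26)]
        for j in covering:
            assert v[j] == pytest.approx(4 / 11)
        defined = ~np.isnan(v)
        others = [j for j in range(40) if defined[j] and j not in covering]
        assert all(v[j] == 0 for j in others)

    def test_upper_bound(self):
        v = variability_profile(np.full(30, 5)).v
        assert np.nanmax(v) == pytest.approx(4.0)
        assert np.nanmin(v) == pytest.approx(4.0)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            VariabilityParams(window=10)
        with pytest.raises(ValueError, match="longer"):
            variability_profile(np.ones(5), VariabilityParams(window=11))


class TestRegions:
    def test_all_zero(self):
        assert detect_variable_regions(np.zeros(100)) == []

    def test_step_profile(self):
        v = np.concatenate([np.full(30, 1.0), np.zeros(30)])
        regions = detect_variable_regions(v)
        assert [(r.start, r.end) for r in regions] == [(0, 29)]
        assert regions[0].length == 30

    def test_alternating_never_opens(self):
        v = np.tile([1.0, 0.0], 50)
        assert detect_variable_regions(v) == []

    def test_region_extends_to_last_defined_column(self):
        v = np.concatenate([np.zeros(20), np.full(25, 2.0)])
        v[:3] = np.nan
        regions = detect_variable_regions(v)
        assert [(r.start, r.end) for r in regions] == [(20, 44)]

    def test_intermediate_values_stay_inside_region(self):
        # dip to 0.7 (between thresholds) must not close the region
        v = np.concatenate([np.full(15, 1.5), np.full(12, 0.7), np.full(15, 1.5),
                            np.zeros(15)])
        regions = detect_variable_regions(v)
        assert [(r.start, r.end) for r in regions] == [(0, 41)]

    def test_two_separated_regions(self):
        v = np.concatenate([np.full(15, 2.0), np.zeros(20), np.full(15, 2.0),
                            np.zeros(12)])
        regions = detect_variable_regions(v)
        assert [(r.start, r.end) for r in regions] == [(0, 14), (35, 49)]

    def test_translation_equivariance(self):
        base = np.concatenate([np.zeros(14), np.full(20, 1.2), np.zeros(25)])
        shifted = np.concatenate([np.zeros(7), base])
        r0 = detect_variable_regions(base)
        r1 = detect_variable_regions(shifted)
        assert [(r.start + 7, r.end + 7) for r in r0] == [(r.start, r.end) for r in r1]

    def test_variable_length_at(self):
        v = np.concatenate([np.full(15, 2.0), np.zeros(20)])
        regions = detect_variable_regions(v)
        assert variable_length_at(regions, 5) == 15
        assert variable_length_at(regions, 30) == 0


class TestSyntheticAlignment:
    def test_block_produces_one_region_over_motif(self):
        aln = gen_alignment(8, 400, blocks=[(100, 160, 3)], seed=3)
        profile = variability_profile(column_states(aln))
        regions = detect_variable_regions(profile.v)
        assert len(regions) == 1
        r = regions[0]
        assert r.start < 160 and r.end >= 100  # overlaps the block
        assert variable_length_at(regions, 130) > 0
        assert variable_length_at(regions, 300) == 0

    def test_round_trip_through_aligned_fasta(self, tmp_path):
        aln = gen_alignment(5, 150, blocks=[(40, 80, 4)], seed=11)
        path = tmp_path / "aln.fa"
        with open(path, "w") as fh:
            for rid, row in zip(aln.ids, aln.rows):
                fh.write(f">{rid}\n{row}\n")
        back = read_aligned_fasta(path)
        assert back.rows == aln.rows
        assert column_states(back).tolist() == column_states(aln).tolist()


def seg(qstart, qend, pident, sseqid="s1"):
    return HomologySegment(qstart=qstart, qend=qend, pident=pident, sseqid=sseqid)


class TestCategorize:
    QLEN = 1036  # motif of 36 nt with 500-nt flanks
    TM = (500, 536)
    INTERGENIC = (420, 640)

    def test_full_coverage_is_no_change(self):
        lc = categorize_locus(self.QLEN, self.TM, self.INTERGENIC,
                              [seg(0, self.QLEN, 100.0)])
        assert (lc.category, lc.subcategory) == ("no_change", "none")

    def test_no_segments_is_no_homology(self):
        lc = categorize_locus(self.QLEN, self.TM, self.INTERGENIC, [])
        assert (lc.category, lc.subcategory) == ("no_homology", "none")

    def test_large_central_gap_is_region_missing_tm_missing(self):
        segments = [seg(0, 300, 100.0), seg(700, self.QLEN, 100.0)]
        lc = categorize_locus(self.QLEN, self.TM, self.INTERGENIC, segments)
        assert (lc.category, lc.subcategory) == ("region_missing", "tm_missing")

    def test_intergenic_gap_spanning_tm(self):
        segments = [seg(0, 480, 100.0), seg(600, self.QLEN, 100.0)]
        lc = categorize_locus(self.QLEN, self.TM, self.INTERGENIC, segments)
        assert (lc.category, lc.subcategory) == ("intergenic_change", "tm_missing")

    def test_intergenic_mutated_tm(self):
        segments = [seg(0, 450, 100.0), seg(450, 620, 95.0), seg(620, self.QLEN, 100.0)]
        lc = categorize_locus(self.QLEN, self.TM, self.INTERGENIC, segments)
        assert (lc.category, lc.subcategory) == ("intergenic_change", "tm_mutated")

    def test_palindrome_effect_flag(self):
        segments = [seg(0, 480, 100.0), seg(600, self.QLEN, 100.0)]
        lc = categorize_locus(self.QLEN, self.TM, self.INTERGENIC, segments,
                              hairpin_check=True)
        assert lc.subcategory == "palindrome_effect"

    def test_without_bed_falls_back_with_warning(self):
        segments = [seg(0, 480, 100.0), seg(600, self.QLEN, 100.0)]
        with pytest.warns(UserWarning, match="intergenic"):
            lc = categorize_locus(self.QLEN, self.TM, None, segments)
        assert lc.category == "no_change"

    def test_segments_outside_query_rejected(self):
        with pytest.raises(ValueError):
            categorize_locus(100, (40, 60), None, [seg(0, 200, 100.0)])

    def test_monotone_under_segment_removal(self):
        rank = {"no_change": 0, "intergenic_change": 1,
                "region_missing": 2, "no_homology": 3}
        segments = [seg(0, 460, 100.0), seg(460, 630, 97.0),
                    seg(630, self.QLEN, 100.0)]
        full = categorize_locus(self.QLEN, self.TM, self.INTERGENIC, segments)
        for drop in range(len(segments)):
            reduced = segments[:drop] + segments[drop + 1:]
            lc = categorize_locus(self.QLEN, self.TM, self.INTERGENIC, reduced)
            assert rank[lc.category] >= rank[full.category]
        assert rank[categorize_locus(self.QLEN, self.TM, self.INTERGENIC, []).category] == 3


class TestBlastTabular:
    def test_round_trip_segments(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\tsubjA\t99.5\t400\t2\t0\t1\t400\t100\t499\t1e-50\t700\n"
            "q1\tsubjB\t88.0\t200\t24\t1\t601\t800\t900\t1099\t1e-10\t150\n"
        )
        df = read_blast_tab(path)
        assert list(df.columns)[:3] == ["qseqid", "sseqid", "pident"]
        segs = segments_from_table(df, subject_id="subjA")
        assert len(segs) == 1
        assert (segs[0].qstart, segs[0].qend) == (0, 400)  # 1-based -> half-open
        assert segs[0].pident == pytest.approx(99.5)
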