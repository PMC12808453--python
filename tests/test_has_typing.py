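"""Cysteine-pair detection, the type classifier, motifs, trimming, fusions."""

import numpy as np
import pytest

from hastools.has_typing import (
    assign_type,
    detect_cys_pairs,
    detect_fusion,
    locate_motifs,
    motif_frequency_table,
    position_percent,
    trim_msa,
)
from hastools.records import ProteinRecord
from hastools.synthetic_data import gen_hos_domain, gen_sequence
from hastools.topology import Loop, Topology, extract_loops


def _out_loop(seq, start=1):
    return [Loop(ordinal=1, side="out", ecl_index=1, start=start,
                 end=start + len(seq) - 1)]


class TestDetectCysPairs:
    def test_simple_pair_spacing_four(self):
        seq = "ACDEFGCK"  # Cys at 2 and 7, spacing 4
        pairs = detect_cys_pairs(_out_loop(seq), seq)
        assert len(pairs) == 1
        assert (pairs[0].i, pairs[0].j, pairs[0].spacing) == (2, 7, 4)

    def test_subtilis_like_spacing_six(self):
        # Cys35/Cys42-style spacing (j - i - 1 = 6) falls inside [2, 12]
        seq = "A" * 30 + "DDDDC" + "NQDEST" + "C" + "DD"
        loops = [Loop(1, "out", 1, 31, len(seq))]
        pairs = detect_cys_pairs(loops, seq)
        assert len(pairs) == 1 and pairs[0].spacing == 6

    def test_single_cys_no_pair(self):
        seq = "ACDEFGHK"
        assert detect_cys_pairs(_out_loop(seq), seq) == []

    def test_most_n_terminal_pair_wins(self):
        seq = "ACDDDCKKCDDDCK"  # two candidate pairs; first reported
        pairs = detect_cys_pairs(_out_loop(seq), seq)
        assert len(pairs) == 1 and pairs[0].i == 2

    def test_cytoplasmic_loops_ignored(self):
        seq = "ACDDDCK"
        loops = [Loop(1, "in", None, 1, len(seq))]
        assert detect_cys_pairs(loops, seq) == []

    def test_generated_pairs_recovered_exactly(self, profiles):
        gs = gen_sequence(profiles["1B"], 31)
        loops = extract_loops(gs.topology, len(gs.record.seq))
        pairs = detect_cys_pairs(loops, gs.record.seq)
        got = {(p.ecl_index, p.i, p.j) for p in pairs}
        want = {(1 if n == "ECL1" else 3, i, j) for n, i, j in gs.cys_pairs}
        assert got == want


class TestAssignType:
    def _assign(self, profiles, panels, t, seed, **kw):
        gs = gen_sequence(profiles[t], seed)
        loops = extract_loops(gs.topology, len(gs.record.seq))
        pairs = detect_cys_pairs(loops, gs.record.seq)
        return assign_type(gs.record, gs.topology, pairs, panels, **kw)

    def test_double_pair_eight_tm_is_1b(self, profiles, panels):
        a = self._assign(profiles, panels, "1B", 8)
        assert a.type == "1B" and a.cys_ecl1 and a.cys_ecl3

    def test_four_tm_ecl1_is_1a(self, profiles, panels):
        a = self._assign(profiles, panels, "1A", 8)
        assert a.type == "1A" and 3 <= a.tm_count <= 5

    def test_partial_sequence_unassigned(self, panels):
        rec = ProteinRecord("p", "MKVLWHEAGA" * 9)  # 90 residues
        topo = Topology(((5, 25), (40, 60)), "in")
        a = assign_type(rec, topo, [], panels)
        assert a.type == "unassigned" and "partial" in a.flags

    def test_cysfree_trio_resolved_by_panels(self, profiles, panels):
        for t in ("0", "1D", "2"):
            a = self._assign(profiles, panels, t, 21)
            assert a.type == t
            assert not a.cys_ecl1 and not a.cys_ecl3

    def test_1a_star_vs_1c_by_panel_identity(self, profiles, panels):
        for t in ("1A*", "1C"):
            a = self._assign(profiles, panels, t, 33)
            assert a.type == t

    def test_atypical_tm_count_flagged(self, profiles, panels):
        gs = gen_sequence(profiles["2"], 3)
        topo = Topology(gs.topology.segments[:6], "in")  # pretend 6 TM
        a = assign_type(gs.record, topo, [], panels)
        assert "tm_atypical" in a.flags

    def test_empty_panels_rejected(self, profiles):
        gs = gen_sequence(profiles["2"], 5)
        with pytest.raises(ValueError, match="panel"):
            assign_type(gs.record, gs.topology, [], {})

    def test_deterministic(self, profiles, panels):
        a1 = self._assign(profiles, panels, "1C", 55)
        a2 = self._assign(profiles, panels, "1C", 55)
        assert a1 == a2


class TestLocateMotifs:
    def test_reference_alignment_reads_planted_residues(self, profiles,
                                                        motif_refs):
        gs = gen_sequence(profiles["1A*"], 70)
        res = locate_motifs(gs.record, gs.topology, motif_refs["1A*"])
        assert res.found and res.method == "reference_alignment"
        for slot in ("E57", "X1", "X2", "H1", "R"):
            assert res.primary[slot] == gs.motif[slot][1]
        for slot in ("mX1", "mX2", "mX3", "H3", "mX4"):
            assert res.mirror[slot] == gs.motif[slot][1]

    def test_asparagine_accepted_at_h1(self, profiles, motif_refs):
        # type 1C replaces H1 by Asn in a third of sequences
        for seed in range(40):
            gs = gen_sequence(profiles["1C"], 600 + seed)
            if gs.motif["H1"][1] == "N":
                res = locate_motifs(gs.record, gs.topology, motif_refs["1C"])
                assert res.found and res.primary["H1"] == "N"
                return
        pytest.fail("no Asn draw in 40 seeds")

    def test_regex_fallback_without_reference(self, profiles):
        gs = gen_sequence(profiles["1B"], 12)
        res = locate_motifs(gs.record, gs.topology, reference=None)
        assert res.found and res.method == "regex"
        assert res.primary["E57"] == "E" and res.primary["R"] == "R"
        assert res.e57_pos == gs.motif["E57"][0]

    def test_scrambled_sequence_not_found(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("LIVDEST"), 200))
        rec = ProteinRecord("x", seq)
        topo = Topology(tuple((25 * i + 1, 25 * i + 20) for i in range(8)),
                        "in")
        res = locate_motifs(rec, topo, reference=None)
        assert not res.found and res.method is None

    def test_four_tm_has_no_mirror(self, profiles, motif_refs):
        gs = gen_sequence(profiles["1A"], 9)
        res = locate_motifs(gs.record, gs.topology, motif_refs["1A"])
        assert res.found and res.mirror is None


class TestFrequencyTable:
    def _results(self, profiles, motif_refs, t, n, seed0):
        out = []
        for s in range(n):
            gs = gen_sequence(profiles[t], seed0 + s)
            out.append(locate_motifs(gs.record, gs.topology, motif_refs[t]))
        return out

    def test_single_record_is_100_percent(self, profiles, motif_refs):
        res = self._results(profiles, motif_refs, "1D", 1, 5)
        table = motif_frequency_table({"1D": res})
        sub = table[table.type == "1D"]
        assert (sub.percent == 100).all()
        assert sub.low_support.all()  # n=1 < default support floor

    def test_rows_sum_to_100_per_position(self, profiles, motif_refs):
        res = self._results(profiles, motif_refs, "1C", 30, 50)
        table = motif_frequency_table({"1C": res})
        for pos, grp in table.groupby("position"):
            assert abs(grp.percent.sum() - 100) <= len(grp)  # rounding slack

    def test_two_types_independent(self, profiles, motif_refs):
        r1 = self._results(profiles, motif_refs, "1D", 5, 2)
        r2 = self._results(profiles, motif_refs, "2", 5, 2)
        t_both = motif_frequency_table({"1D": r1, "2": r2})
        t_single = motif_frequency_table({"1D": r1})
        sub = t_both[t_both.type == "1D"].reset_index(drop=True)
        assert sub.equals(t_single.reset_index(drop=True))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            motif_frequency_table({})

    def test_position_percent_lookup(self, profiles, motif_refs):
        res = self._results(profiles, motif_refs, "1D", 10, 8)
        table = motif_frequency_table({"1D": res})
        assert position_percent(table, "1D", "E57", "E") == 100
        assert position_percent(table, "1D", "E57", "W") == 0


class TestTrimMsa:
    def test_all_gap_column_dropped(self):
        msa = ["A-C", "A-C", "A-C"]
        trimmed, cols = trim_msa(msa)
        assert trimmed == ["AC", "AC", "AC"] and cols == [0, 2]

    def test_gap_free_unchanged(self):
        msa = ["ACDE", "AGDE"]
        trimmed, cols = trim_msa(msa)
        assert trimmed == msa and cols == [0, 1, 2, 3]

    def test_toy_low_occupancy_columns(self):
        # 25 rows, 10 columns; 3 columns occupied by a single row (4%)
        nrow, sparse_cols = 25, {2, 5, 7}
        msa = []
        for r in range(nrow):
            row = "".join(
                ("A" if r == 0 else "-") if c in sparse_cols else "K"
                for c in range(10))
            msa.append(row)
        trimmed, cols = trim_msa(msa, 0.05, 0.60)
        assert len(cols) == 7 and not set(cols) & sparse_cols

    def test_conservation_floor_adds_columns_back(self):
        # 6 of 10 columns below the gap threshold; the 60% floor restores the
        # best-occupied dropped columns
        nrow = 100
        occup = [1.0, 1.0, 1.0, 1.0, 0.04, 0.03, 0.03, 0.02, 0.02, 0.01]
        msa = []
        for r in range(nrow):
            msa.append("".join("A" if r < int(o * nrow) else "-"
                               for o in occup))
        trimmed, cols = trim_msa(msa, 0.05, 0.60)
        assert len(cols) == 6  # ceil(0.6 * 10)
        assert cols == [0, 1, 2, 3, 4, 5]  # col 4 has top dropped occupancy

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            trim_msa(["AC", "A"])


@pytest.fixture(scope="module")
def fusion_panels(panels):
    has_panel = [panels[t][0] for t in ("1A", "1B", "2")]
    hos_panel = [gen_hos_domain(s) for s in range(3)]
    return {"HAS": has_panel, "HOS": hos_panel}


class TestDetectFusion:
    def test_concatenated_record_is_fusion(self, profiles, fusion_panels):
        gs = gen_sequence(profiles["1A"], 40)
        rec = ProteinRecord("f", gs.record.seq + gen_hos_domain(17))
        assert detect_fusion(rec, fusion_panels) == "fusion"

    def test_plain_1b_is_single(self, profiles, fusion_panels):
        rec = gen_sequence(profiles["1B"], 41).record
        assert detect_fusion(rec, fusion_panels) == "single"

    def test_random_sequence_is_neither(self, fusion_panels):
        rng = np.random.default_rng(2)
        rec = ProteinRecord("r", "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300)))
        assert detect_fusion(rec, fusion_panels) == "neither"

    def test_needs_two_panels(self, panels):
        with pytest.raises(ValueError):
            detect_fusion(ProteinRecord("x", "MKVL" * 50),
                          {"HAS": panels["1B"]})
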