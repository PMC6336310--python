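"""V/(D)/J resolution rules, pairing tables, rankings, filters, Circos export."""

import numpy as np
import pytest

from vdjrep.model import Repertoire
from vdjrep.pairing import (
    VDJCombination,
    export_circos_links,
    filter_low_frequency_pairs,
    pairing_table,
    rank_top_combinations,
    read_circos_links,
    resolve_vdj,
)
from vdjrep.synthetic import SimConfig, default_design, simulate_repertoires

from conftest import make_record, random_record


class TestResolveVdj:
    def test_fully_determined_combination(self):
        r = make_record(d_alignment_length=7)
        assert resolve_vdj(r) == VDJCombination("IGHV1-26", "IGHD1-1", "IGHJ1", "IGH")

    def test_short_d_alignment_is_undetermined(self):
        r = make_record(d_alignment_length=5)
        assert resolve_vdj(r).d == "U"

    def test_missing_and_multi_d(self):
        assert resolve_vdj(make_record(d_call=())).d == "U"
        assert resolve_vdj(make_record(d_call=("IGHD1-1", "IGHD2-3"))).d == "U"

    def test_multi_j_is_undetermined(self):
        assert resolve_vdj(make_record(j_call=("IGHJ1", "IGHJ2"))).j == "U"

    def test_two_v_calls_ineligible(self):
        assert resolve_vdj(make_record(v_call=("IGHV1-63", "IGHV1-76"))) is None

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"in_frame": None},
            {"has_stop": True},
            {"in_frame": False},
            {"junction_aa": "CARDYF", "c_call": "IgM"},  # bad anchor, unswitched
        ],
    )
    def test_nonproductive_or_invalid_never_resolves(self, kwargs):
        assert resolve_vdj(make_record(**kwargs)) is None

    def test_switched_record_with_bad_anchor_resolves(self):
        r = make_record(junction_aa="CARDYF", c_call="IgG1", d_alignment_length=7)
        assert resolve_vdj(r) is not None

    def test_kappa_has_no_d_component(self):
        r = make_record(locus="IGK", v_call=("IGKV4-55",), j_call=("IGKJ1",))
        combo = resolve_vdj(r)
        assert combo.d is None and combo.label() == "IGKV4-55/IGKJ1"

    def test_random_records_never_resolve_when_not_productive(self, rng):
        from vdjrep.model import classify_functionality

        for _ in range(300):
            r = random_record(rng)
            if classify_functionality(r) != "productive":
                assert resolve_vdj(r) is None


def _rep(design, records):
    return Repertoire(design.rows[0], records)


class TestPairingTable:
    def test_single_combination_is_100_percent(self, design2):
        recs = [make_record(sequence_id=f"s{i}", d_alignment_length=9) for i in range(2)]
        table = pairing_table([_rep(design2, recs)])
        assert table.percent.iloc[0, 0] == 100.0

    def test_vj_mode_marginalizes_d(self, design2):
        recs = [
            make_record(sequence_id="a", d_alignment_length=9),
            make_record(sequence_id="b", d_call=()),
        ]
        table = pairing_table([_rep(design2, recs)], mode="VJ")
        assert len(table.percent) == 1
        assert table.percent.iloc[0, 0] == 100.0

    def test_marginal_consistency_vj_equals_vdj_summed(self, germline, design2):
        cfg = SimConfig(reads_per_animal=800, seed=6)
        reps = simulate_repertoires(cfg, germline, [], design2)[:4]
        vdj = pairing_table(reps, mode="VDJ")
        vj = pairing_table(reps, mode="VJ")
        summed = vdj.counts.groupby(level=["v", "j"]).sum()
        flat_vj = vj.counts.droplevel("d")
        np.testing.assert_allclose(
            summed.sort_index().values, flat_vj.sort_index().values
        )

    def test_animal_without_resolvable_records_excluded(self, design2):
        good = _rep(design2, [make_record(d_alignment_length=9)])
        bad = Repertoire(design2.rows[1], [make_record(in_frame=None)])
        with pytest.warns(UserWarning, match="no resolvable"):
            table = pairing_table([good, bad])
        assert list(table.percent.columns) == [design2.rows[0].animal_id]

    def test_oracle_per_record_tally(self, germline, design2):
        cfg = SimConfig(reads_per_animal=500, seed=8)
        rep = simulate_repertoires(cfg, germline, [], design2)[0]
        table = pairing_table([rep])
        tally = {}
        for r in rep.records:
            c = resolve_vdj(r)
            if c is not None:
                key = (c.v, c.d, c.j)
                tally[key] = tally.get(key, 0) + 1
        col = table.counts[rep.animal.animal_id]
        assert {k: int(v) for k, v in col.items()} == tally


class TestRanking:
    def _table_from_simulation(self, germline, design):
        cfg = SimConfig(reads_per_animal=600, seed=10)
        reps = simulate_repertoires(cfg, germline, [], design)
        return pairing_table(reps, mode="VDJ")

    def test_shared_top5_union_is_five(self, germline, design2):
        # the same generator weights drive every group: top-5 should coincide
        table = self._table_from_simulation(germline, design2)
        ranks = rank_top_combinations(table, design2, ["---", "-++", "+++"], k=5)
        assert 5 <= len(ranks) <= 15
        ranks_one = rank_top_combinations(table, design2, ["---"], k=5)
        assert len(ranks_one) == 5

    def test_k_larger_than_table_returns_all(self, design2):
        recs = [make_record(d_alignment_length=9)]
        reps = [Repertoire(row, list(recs)) for row in design2.rows]
        table = pairing_table(reps)
        ranks = rank_top_combinations(table, design2, ["---"], k=99)
        assert len(ranks) == len(table.percent)

    def test_rank_matrix_is_deterministic(self, germline, design2):
        table = self._table_from_simulation(germline, design2)
        a = rank_top_combinations(table, design2, ["---", "+++"], k=5)
        b = rank_top_combinations(table, design2, ["---", "+++"], k=5)
        assert a.equals(b)


class TestLowFrequencyFilter:
    def _table(self, design, percents_by_combo):
        import pandas as pd

        animals = design.animal_ids
        index = pd.MultiIndex.from_tuples(percents_by_combo, names=["v", "d", "j"])
        rows = []
        for _, minus_pct, plus_pct in [
            (c, *percents_by_combo[c]) for c in percents_by_combo
        ]:
            rows.append(
                [plus_pct if design[a].aos else minus_pct for a in animals]
            )
        from vdjrep.pairing import PairingTable

        pct = pd.DataFrame(rows, index=index, columns=animals)
        return PairingTable(mode="VJ", locus="IGH", counts=pct.copy(), percent=pct)

    def test_both_below_dropped_one_above_kept(self, design2):
        table = self._table(
            design2,
            {
                ("V1", "", "J1"): (0.05, 0.05),  # both below: dropped
                ("V2", "", "J2"): (0.5, 0.01),  # one above: kept
                ("V3", "", "J3"): (99.45, 99.94),
            },
        )
        kept = filter_low_frequency_pairs(table, design2, "AOS", threshold=0.1)
        assert ("V1", "", "J1") not in kept.percent.index
        assert ("V2", "", "J2") in kept.percent.index

    def test_never_drops_pair_at_or_above_threshold(self, design2):
        table = self._table(
            design2, {("V1", "", "J1"): (0.1, 0.0), ("V2", "", "J2"): (99.9, 100.0)}
        )
        kept = filter_low_frequency_pairs(table, design2, "AOS", threshold=0.1)
        assert ("V1", "", "J1") in kept.percent.index

    def test_empty_table_passes_through(self, germline, design2):
        reps = [Repertoire(row, []) for row in design2.rows]
        with pytest.warns(UserWarning):
            table = pairing_table(reps, mode="VJ")
        kept = filter_low_frequency_pairs(table, design2, "AOS")
        assert kept.percent.empty


class TestCircos:
    def test_round_trip(self, tmp_path, germline, design2):
        cfg = SimConfig(reads_per_animal=500, seed=12)
        reps = simulate_repertoires(cfg, germline, [], design2)
        table = pairing_table(reps, mode="VJ")
        path = tmp_path / "links.txt"
        export_circos_links(table, design2, "---", path)
        links = read_circos_links(path)
        animals = [a for a in table.counts.columns if design2[a].cell == "---"]
        assert sum(links.values()) == int(table.counts[animals].values.sum())

    def test_u_emitted_as_segment(self, tmp_path, design2):
        recs = [make_record(d_call=()), make_record(sequence_id="s2", j_call=())]
        reps = [Repertoire(design2.rows[0], recs)] + [
            Repertoire(r, [make_record()]) for r in design2.rows[1:]
        ]
        table = pairing_table(reps, mode="VJ")
        path = tmp_path / "links.txt"
        export_circos_links(table, design2, "---", path)
        segments = {s for pair in read_circos_links(path) for s in pair}
        assert "U" in segments

    def test_vdj_table_rejected(self, design2):
        reps = [Repertoire(row, [make_record(d_alignment_length=9)]) for row in design2.rows]
        table = pairing_table(reps, mode="VDJ")
        with pytest.raises(ValueError, match="VJ"):
            export_circos_links(table, design2, "---", "/dev/null")
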