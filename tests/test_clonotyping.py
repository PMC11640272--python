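"""Chain pairing, clonotype counting, filtering and dominant selection."""

import random
from collections import Counter

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrscout.clonotyping import (
    ClonotypeRecord,
    ClonotypeTable,
    FullLengthKey,
    Resolution,
    count_clonotypes,
    filter_singletons,
    attach_scores,
    compare_resolutions,
    pair_chains,
    percent,
    select_dominant,
    strip_allele,
)
from tcrscout.io_airr import Locus, TcrContig
from tcrscout.synthetic import (
    RepertoireSpec,
    simulate_planted_repertoire,
    simulate_repertoire,
)


def _contig(cell, locus, v="V1", j="J1", cdr3="CAF", productive=True, umi=1):
    return TcrContig(cell, locus, v, j, cdr3, productive, umi)


class TestPairChains:
    def test_one_alpha_one_beta_gives_complete_receptor(self):
        cells = pair_chains(
            [_contig("c1", Locus.TRA), _contig("c1", Locus.TRB, cdr3="CASSF")]
        )
        assert len(cells) == 1 and cells[0].complete
        assert cells[0].alpha.junction_aa == "CAF"
        assert cells[0].beta.junction_aa == "CASSF"

    def test_beta_only_cell_is_incomplete(self):
        cells = pair_chains([_contig("c1", Locus.TRB)])
        assert len(cells) == 1 and not cells[0].complete and cells[0].alpha is None

    def test_highest_umi_chain_wins(self):
        cells = pair_chains(
            [
                _contig("c1", Locus.TRA, cdr3="CAAF", umi=5),
                _contig("c1", Locus.TRA, cdr3="CABF", umi=2),
            ]
        )
        assert cells[0].alpha.junction_aa == "CAAF"

    def test_umi_tie_breaks_lexicographically(self):
        cells = pair_chains(
            [
                _contig("c1", Locus.TRA, cdr3="CZZF", umi=3),
                _contig("c1", Locus.TRA, cdr3="CAAF", umi=3),
            ]
        )
        assert cells[0].alpha.junction_aa == "CAAF"

    def test_nonproductive_contigs_ignored(self):
        cells = pair_chains(
            [
                _contig("c1", Locus.TRA, cdr3="CXXF", productive=False, umi=99),
                _contig("c1", Locus.TRA, cdr3="CAAF", umi=1),
            ]
        )
        assert cells[0].alpha.junction_aa == "CAAF"

    @given(st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force_max_over_contigs(self, data):
        n = data.draw(st.integers(1, 12))
        contigs = [
            _contig(
                "c1",
                data.draw(st.sampled_from([Locus.TRA, Locus.TRB])),
                cdr3=data.draw(st.text(alphabet="ACDF", min_size=1, max_size=4)),
                productive=data.draw(st.booleans()),
                umi=data.draw(st.integers(0, 9)),
            )
            for _ in range(n)
        ]
        cells = pair_chains(contigs)
        for locus, get in ((Locus.TRA, "alpha"), (Locus.TRB, "beta")):
            prod = [c for c in contigs if c.productive and c.locus == locus]
            expected = (
                min(prod, key=lambda c: (-c.umi_count, c.junction_aa)).junction_aa
                if prod
                else None
            )
            if not cells:
                assert expected is None
                continue
            chain = getattr(cells[0], get)
            assert (chain.junction_aa if chain else None) == expected


def _receptors_from(contigs):
    return pair_chains(contigs)


class TestCountClonotypes:
    def test_empty_input_gives_empty_table(self):
        assert len(count_clonotypes([], Resolution.FULL_LENGTH)) == 0

    def test_incomplete_cells_not_counted(self):
        cells = pair_chains([_contig("c1", Locus.TRB)])
        assert len(count_clonotypes(cells, Resolution.FULL_LENGTH)) == 0

    def test_allele_suffixes_merge_into_one_clonotype(self):
        contigs = []
        for cell, suffix in (("c1", "*01"), ("c2", "*02"), ("c3", "")):
            contigs += [
                _contig(cell, Locus.TRA, v=f"TRAV1-2{suffix}", j="TRAJ3"),
                _contig(cell, Locus.TRB, v="TRBV9", j="TRBJ2-7", cdr3="CASSF"),
            ]
        table = count_clonotypes(pair_chains(contigs), Resolution.FULL_LENGTH)
        assert len(table) == 1
        (key,) = table.entries
        assert key.v_alpha == "TRAV1-2"

    @pytest.mark.parametrize("seed", range(20))
    def test_partition_and_refinement(self, seed):
        """Full-length clonotypes partition cells and refine CDR3 pairs."""
        contigs, _ = simulate_repertoire(
            RepertoireSpec(n_cells=120, n_clones=40, seed=seed)
        )
        cells = pair_chains(contigs)
        complete = {c.cell_id for c in cells if c.complete}
        full = count_clonotypes(cells, Resolution.FULL_LENGTH)
        pairs = count_clonotypes(cells, Resolution.CDR3_PAIR)
        for table in (full, pairs):
            seen = [cid for rec in table.entries.values() for cid in rec.cell_ids]
            assert len(seen) == len(set(seen))  # disjoint
            assert set(seen) == complete  # cover
        # refinement: pair count = sum of full-length counts sharing the pair
        by_pair = Counter()
        for key, rec in full.entries.items():
            by_pair[key.cdr3_pair] += rec.cell_count
        assert dict(by_pair) == {k: r.cell_count for k, r in pairs.entries.items()}


class TestFilterSingletons:
    def _table(self, counts):
        t = ClonotypeTable(Resolution.FULL_LENGTH)
        for i, (name, n) in enumerate(counts.items()):
            key = FullLengthKey("V", "J", f"CA{name}F", "V", "J", f"CAS{name}F")
            t.entries[key] = ClonotypeRecord({f"{name}{j}" for j in range(n)})
        return t

    def test_singletons_removed_and_report_correct(self):
        retained, rep = filter_singletons(self._table({"A": 7, "B": 2, "C": 1}))
        assert {r.cell_count for r in retained.entries.values()} == {7, 2}
        assert rep == (3, 2, 66.7)

    def test_idempotent(self):
        once, _ = filter_singletons(self._table({"A": 7, "B": 2, "C": 1}))
        twice, rep = filter_singletons(once)
        assert twice.entries.keys() == once.entries.keys()
        assert rep.retained_pct == 100.0

    def test_empty_table_flagged(self):
        _, rep = filter_singletons(ClonotypeTable(Resolution.FULL_LENGTH))
        assert rep.n_before == 0 and rep.retained_pct is None

    def test_matches_brute_force_on_simulation(self):
        contigs, _ = simulate_repertoire(RepertoireSpec(n_cells=200, n_clones=80, seed=1))
        table = count_clonotypes(pair_chains(contigs), Resolution.FULL_LENGTH)
        retained, _ = filter_singletons(table)
        expected = {k for k, r in table.entries.items() if r.cell_count >= 2}
        assert set(retained.entries) == expected


class TestPercent:
    @pytest.mark.parametrize(
        "part,whole,expected",
        [(4989, 18000, 27.7), (110, 1429, 7.7), (2, 3, 66.7), (5, 10000, 0.1), (1, 1, 100.0)],
    )
    def test_half_up_to_one_decimal(self, part, whole, expected):
        assert percent(part, whole) == expected


def _scored_table(counts_scores):
    t = ClonotypeTable(Resolution.FULL_LENGTH)
    for i, (n, s) in enumerate(counts_scores):
        key = FullLengthKey("V", "J", f"CA{i:03d}F", "V", "J", f"CAS{i:03d}F")
        t.entries[key] = ClonotypeRecord({f"cell{i}-{j}" for j in range(n)}, s)
    return t


class TestSelectDominant:
    def test_score_breaks_count_tie(self):
        t = _scored_table([(7, 0.31), (7, 0.52), (7, 0.47)])
        dom = select_dominant(t)
        assert dom.binding_score == 0.52 and dom.cell_count == 7
        assert len(dom.candidates) == 3

    def test_single_clonotype_is_dominant(self):
        t = _scored_table([(3, 0.1)])
        assert select_dominant(t).cell_count == 3

    def test_unscored_max_count_clonotype_raises(self):
        t = _scored_table([(7, None), (2, 0.9)])
        with pytest.raises(ValueError, match="lack binding scores"):
            select_dominant(t)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            select_dominant(ClonotypeTable(Resolution.FULL_LENGTH))

    @pytest.mark.parametrize("seed", range(0, 200, 10))
    def test_matches_brute_force_argmax(self, seed):
        rng = random.Random(seed)
        t = _scored_table(
            [(rng.randint(1, 9), round(rng.random(), 6)) for _ in range(rng.randint(1, 30))]
        )
        dom = select_dominant(t)
        # brute force: max (count, score), then lexicographically smallest key
        best = max((r.cell_count, r.binding_score) for r in t.entries.values())
        expected = min(
            k for k, r in t.entries.items() if (r.cell_count, r.binding_score) == best
        )
        assert dom.key == expected

    def test_row_order_invariance(self):
        rng = random.Random(7)
        pairs = [(rng.randint(1, 5), round(rng.random(), 6)) for _ in range(20)]
        t1 = _scored_table(pairs)
        t2 = ClonotypeTable(Resolution.FULL_LENGTH)
        for key in reversed(list(t1.entries)):
            t2.entries[key] = t1.entries[key]
        assert select_dominant(t1).key == select_dominant(t2).key


class TestAttachScores:
    def test_all_matching_rows_scored(self, worked_example):
        cells = pair_chains(worked_example.contigs)
        table = count_clonotypes(cells, Resolution.FULL_LENGTH)
        scored = attach_scores(table, worked_example.binding_scores)
        assert all(r.binding_score is not None for r in scored.entries.values())

    def test_unmatched_clonotype_gets_absent_score(self, worked_example, caplog):
        t = _scored_table([(2, None)])
        with caplog.at_level("WARNING"):
            scored = attach_scores(t, worked_example.binding_scores)
        assert next(iter(scored.entries.values())).binding_score is None
        assert any("without a matching score" in r.message for r in caplog.records)

    def test_ambiguous_double_match_raises(self, worked_example):
        scores = worked_example.binding_scores.copy()
        dup = scores.iloc[[0]].copy()
        dup["score"] = scores.iloc[0]["score"] / 2 + 0.01
        scores = pd.concat([scores, dup], ignore_index=True)
        cells = pair_chains(worked_example.contigs)
        table = count_clonotypes(cells, Resolution.FULL_LENGTH)
        with pytest.raises(ValueError, match="ambiguous"):
            attach_scores(table, scores)

    def test_matches_nested_loop_join(self):
        contigs, truth, scores = simulate_planted_repertoire(
            n_cells=150, n_clones=50, seed=3
        )
        table = count_clonotypes(pair_chains(contigs), Resolution.FULL_LENGTH)
        scored = attach_scores(table, scores)
        for key, rec in scored.entries.items():
            expected = None
            for row in scores.itertuples(index=False):
                row_key = FullLengthKey(
                    strip_allele(row.v_alpha), strip_allele(row.j_alpha), row.cdr3_alpha,
                    strip_allele(row.v_beta), strip_allele(row.j_beta), row.cdr3_beta,
                )
                if row_key == key:
                    expected = float(row.score)
            assert rec.binding_score == expected


class TestCompareResolutions:
    def test_worked_example_dominant_pair(self, worked_example):
        cells = pair_chains(worked_example.contigs)
        df = compare_resolutions(cells)
        top = df.iloc[0]
        assert top["pair_cell_count"] == 21
        assert top["n_full_length_clonotypes"] == 8
        assert top["max_full_length_count"] == 7

    def test_unique_pairs_collapse_to_identity(self):
        contigs = []
        for i in range(5):
            contigs += [
                _contig(f"c{i}", Locus.TRA, cdr3=f"CA{i}F"),
                _contig(f"c{i}", Locus.TRB, cdr3=f"CAS{i}F"),
            ]
        df = compare_resolutions(pair_chains(contigs))
        assert (df["pair_cell_count"] == df["max_full_length_count"]).all()
        assert (df["n_full_length_clonotypes"] == 1).all()

    def test_cell_conservation(self):
        contigs, _ = simulate_repertoire(RepertoireSpec(n_cells=180, n_clones=60, seed=4))
        cells = pair_chains(contigs)
        df = compare_resolutions(cells)
        n_complete = sum(1 for c in cells if c.complete)
        assert df["pair_cell_count"].sum() == n_complete
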