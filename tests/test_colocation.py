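import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casnet.colocation import (
    contig_cooccurrence,
    filter_hits,
    format_p,
    gene_gap,
    hhsuite_filter,
    min_distance_to_cas,
    orf_reassignment_test,
    random_location_null,
    read_tblout,
    tm_flag,
)
from casnet.synth import SyntheticGenomeConfig, simulate_genomes
from conftest import make_gene_table


class TestFilterHits:
    def hits(self, evalues):
        return pd.DataFrame(
            {
                "genome_id": "g1",
                "contig_id": "c1",
                "start": range(1, len(evalues) + 1),
                "end": range(10, 10 * len(evalues) + 1, 10),
                "family_id": [f"f{i}" for i in range(len(evalues))],
                "evalue": evalues,
            }
        )

    def test_bonferroni_style_cutoff(self):
        out = filter_hits(self.hits([0.004]), n_targets=10)
        assert len(out) == 0  # 0.004 >= 0.01/10

    def test_far_below_threshold_retained(self):
        out = filter_hits(self.hits([1e-6]), n_targets=10_000)
        assert len(out) == 1

    def test_best_hit_per_gene_wins(self):
        hits = pd.DataFrame(
            {
                "genome_id": ["g1", "g1"],
                "contig_id": ["c1", "c1"],
                "start": [5, 5],
                "end": [50, 50],
                "family_id": ["better", "worse"],
                "evalue": [1e-9, 1e-6],
            }
        )
        out = filter_hits(hits, n_targets=1)
        assert len(out) == 1
        assert out["family_id"].iloc[0] == "better"

    def test_missing_evalue_column(self):
        with pytest.raises(ValueError, match="E-value"):
            filter_hits(pd.DataFrame({"x": [1]}), n_targets=1)

    def test_hhsuite_probability_filter(self):
        hits = pd.DataFrame({"probability": [89.9, 90.0, 99.0]})
        out = hhsuite_filter(hits)
        assert list(out["probability"]) == [90.0, 99.0]


class TestReadTblout:
    def test_parses_sample(self, tmp_path):
        txt = (
            "#                                                               --- full sequence ---\n"
            "# target name        accession  query name           accession    E-value  score  bias "
            "  E-value  score  bias   exp reg clu  ov env dom rep inc description of target\n"
            "#------------------- ---------- -------------------- ---------- --------- ------ -----\n"
            "NOG1                 -          gene_0001            -            1.3e-20   70.5   0.1"
            "   1.5e-20   70.3   0.1   1.0   1   0   0   1   1   1   1 hypothetical protein\n"
            "NOG2                 -          gene_0002            -             0.0042   12.1   0.0"
            "    0.0051   11.8   0.0   1.2   1   0   0   1   1   1   1 -\n"
        )
        path = tmp_path / "hits.tblout"
        path.write_text(txt)
        df = read_tblout(path)
        assert len(df) == 2
        assert df["target_name"].tolist() == ["NOG1", "NOG2"]
        assert df["full_evalue"].tolist() == [1.3e-20, 0.0042]
        assert df["description"].iloc[0] == "hypothetical protein"


class TestTmFlag:
    @pytest.mark.parametrize("count,expected", [(18, True), (17, False), (0, False)])
    def test_threshold(self, count, expected):
        assert tm_flag(count) is expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tm_flag(-1)


class TestContigCooccurrence:
    def test_single_genome_on_cas_contig(self):
        t = make_gene_table("g1", [
            ("c1", 1, 100, "+", "cas1", True),
            ("c1", 200, 300, "+", "fam", False),
        ])
        assert contig_cooccurrence([t], "fam") == 1.0

    def test_mean_over_genomes(self):
        t1 = make_gene_table("g1", [
            ("c1", 1, 100, "+", "cas1", True),
            ("c1", 200, 300, "+", "fam", False),
        ])
        t2 = make_gene_table("g2", [
            ("c1", 1, 100, "+", "cas1", True),
            ("c2", 200, 300, "+", "fam", False),
        ])
        assert contig_cooccurrence([t1, t2], "fam") == 0.5

    def test_absent_family_errors(self):
        t = make_gene_table("g1", [("c1", 1, 100, "+", "cas1", True)])
        with pytest.raises(ValueError, match="absent"):
            contig_cooccurrence([t], "zz")

    def test_matches_independent_scan(self, rng):
        cfg = SyntheticGenomeConfig(n_genomes=8, colocated_families=("fam",),
                                    pi_coloc=0.5, seed=6)
        tables = simulate_genomes(cfg)
        obs = contig_cooccurrence(tables, "fam")
        # independent recount over raw rows
        vals = []
        for t in tables:
            rows = list(t.genes.itertuples())
            cas_contigs = {r.contig_id for r in rows if r.is_cas}
            mine = [r for r in rows if r.family_id == "fam"]
            if mine:
                vals.append(1.0 if any(r.contig_id in cas_contigs for r in mine) else 0.0)
        assert obs == pytest.approx(np.mean(vals))


class TestOrfReassignmentTest:
    def test_planted_family_small_p(self):
        # family always adjacent to cas; cas occupies one contig in many, so a
        # random ORF rarely lands on the cas contig
        cfg = SyntheticGenomeConfig(n_genomes=15, contigs_per_genome=10,
                                    genes_per_contig=10,
                                    colocated_families=("fam",), pi_coloc=1.0,
                                    seed=1)
        tables = simulate_genomes(cfg)
        res = orf_reassignment_test(tables, "fam", n_perm=2000, seed=0)
        assert res.observed == 1.0
        assert res.p_value < 0.01

    def test_analytic_null_probability(self):
        # 1 genome, 100 equal contigs of 2 genes, cas on one contig: relocated
        # family lands on the cas contig w.p. ~2/199 per draw
        rows = []
        for c in range(100):
            rows.append((f"c{c}", 1, 100, "+", "cas1" if c == 0 else f"x{c}", c == 0))
            rows.append((f"c{c}", 200, 300, "+", "fam" if c == 0 else f"y{c}", False))
        t = make_gene_table("g1", rows)
        res = orf_reassignment_test([t], "fam", n_perm=5000, seed=0)
        assert res.observed == 1.0
        # expected null rate: the 199 other ORFs include 1 on the cas contig
        assert res.null_draws.mean() == pytest.approx(1 / 199, rel=0.5)
        assert res.p_value < 0.02

    def test_cas_genes_never_move(self):
        cfg = SyntheticGenomeConfig(n_genomes=4, colocated_families=("fam",),
                                    pi_coloc=0.3, seed=3)
        tables = simulate_genomes(cfg)
        before = [t.genes[t.genes["is_cas"]].copy() for t in tables]
        orf_reassignment_test(tables, "fam", n_perm=50, seed=0)
        for t, b in zip(tables, before):
            assert t.genes[t.genes["is_cas"]].equals(b)

    def test_deterministic(self):
        cfg = SyntheticGenomeConfig(n_genomes=5, colocated_families=("fam",),
                                    pi_coloc=0.5, seed=4)
        tables = simulate_genomes(cfg)
        a = orf_reassignment_test(tables, "fam", n_perm=500, seed=7)
        b = orf_reassignment_test(tables, "fam", n_perm=500, seed=7)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_draws, b.null_draws)

    def test_single_orf_genome_excluded(self, caplog):
        t_ok = make_gene_table("g1", [
            ("c1", 1, 100, "+", "cas1", True),
            ("c1", 200, 300, "+", "fam", False),
            ("c2", 1, 100, "+", "x", False),
        ])
        t_single = make_gene_table("g2", [("c1", 1, 100, "+", "fam", False)])
        res = orf_reassignment_test([t_ok, t_single], "fam", n_perm=100, seed=0)
        assert res.n_perm == 100  # ran despite the excluded genome

    def test_p_in_unit_interval(self):
        cfg = SyntheticGenomeConfig(n_genomes=5, colocated_families=("fam",),
                                    pi_coloc=0.0, seed=5)
        tables = simulate_genomes(cfg)
        res = orf_reassignment_test(tables, "fam", n_perm=200, seed=0)
        assert 0 < res.p_value <= 1


class TestMinDistance:
    def test_gap_example(self):
        assert gene_gap(100, 400, 501, 900) == 101

    def test_overlap_zero(self):
        assert gene_gap(100, 400, 300, 500) == 0
        assert gene_gap(100, 400, 150, 200) == 0

    @given(st.tuples(st.integers(1, 1000), st.integers(1, 1000),
                     st.integers(1, 1000), st.integers(1, 1000)))
    @settings(max_examples=100, deadline=None)
    def test_gap_symmetric(self, coords):
        s1, l1, s2, l2 = coords
        assert gene_gap(s1, s1 + l1, s2, s2 + l2) == gene_gap(s2, s2 + l2, s1, s1 + l1)

    def test_per_genome_and_overall(self):
        t1 = make_gene_table("g1", [
            ("c1", 100, 400, "+", "fam", False),
            ("c1", 501, 900, "-", "cas1", True),
        ])
        t2 = make_gene_table("g2", [
            ("c1", 100, 400, "+", "fam", False),
            ("c2", 501, 900, "+", "cas1", True),
        ])
        per_genome, overall = min_distance_to_cas([t1, t2], "fam")
        assert per_genome == {"g1": 101, "g2": math.inf}
        assert overall == 101

    def test_strand_invariant(self):
        rows = [("c1", 100, 400, "+", "fam", False), ("c1", 600, 700, "+", "cas1", True)]
        flipped = [(c, s, e, "-", f, ic) for c, s, e, _, f, ic in rows]
        _, a = min_distance_to_cas([make_gene_table("g", rows)], "fam")
        _, b = min_distance_to_cas([make_gene_table("g", flipped)], "fam")
        assert a == b == 200

    def test_matches_all_pairs_oracle(self, rng):
        cfg = SyntheticGenomeConfig(n_genomes=6, colocated_families=("fam",),
                                    pi_coloc=0.5, seed=8)
        tables = simulate_genomes(cfg)
        per_genome, overall = min_distance_to_cas(tables, "fam")
        for t in tables:
            rows = list(t.genes.itertuples())
            best = math.inf
            for a in rows:
                if a.family_id != "fam":
                    continue
                for b in rows:
                    if b.is_cas and b.contig_id == a.contig_id:
                        best = min(best, gene_gap(a.start, a.end, b.start, b.end))
            assert per_genome[t.genome_id] == best
        assert overall == min(per_genome.values())


class TestRandomLocationNull:
    def test_full_coverage_all_zero(self):
        t = make_gene_table("g1", [("c1", 1, 1000, "+", "cas1", True)])
        null = random_location_null([t], n_reps=20, seed=0)
        assert np.all(null == 0)

    def test_matches_exhaustive_position_enumeration(self):
        # one contig of span 1000 with a central cas gene: the exact mean
        # distance over all positions is computable by enumeration
        t = make_gene_table("g1", [
            ("c1", 450, 550, "+", "cas1", True),
            ("c1", 900, 1000, "+", "x", False),
        ])
        exact = np.mean([
            0 if 450 <= pos <= 550 else min(abs(450 - pos), abs(pos - 550))
            for pos in range(1, 1001)
        ])
        null = random_location_null([t], n_reps=4000, seed=1)
        assert null.mean() == pytest.approx(exact, rel=0.05)

    def test_deterministic(self):
        cfg = SyntheticGenomeConfig(n_genomes=3, seed=2)
        tables = simulate_genomes(cfg)
        a = random_location_null(tables, n_reps=100, seed=5)
        b = random_location_null(tables, n_reps=100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_shape(self):
        cfg = SyntheticGenomeConfig(n_genomes=4, seed=3)
        tables = simulate_genomes(cfg)
        null = random_location_null(tables, n_reps=7, seed=0)
        assert null.shape == (7, 4)


class TestFormatP:
    def test_below_floor_reported_as_inequality(self):
        assert format_p(1 / 10_001, 10_000) == "< 0.0001"

    def test_ordinary_p(self):
        assert format_p(0.2, 100) == "0.2"
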