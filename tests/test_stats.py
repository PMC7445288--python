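"""Exact tests, FDR, diversity, hotspots, gene significance and the
randomization test."""

import math
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from gbcpipe.model import Cohort, GeneModel, SomaticMutation
from gbcpipe.stats import (
    bh_fdr,
    cooccurrence,
    detect_hotspots,
    fisher_exact_2x2,
    gene_significance,
    mann_whitney_u,
    match_meta_hotspots,
    protein_position,
    randomization_test_truncating,
    shannon_entropy,
)

from conftest import make_cds


def brute_force_fisher(a, b, c, d):
    """Independent oracle: enumerate the hypergeometric support."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = hypergeom.pmf(x, n, r1, c1)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


class TestFisher:
    def test_regional_frameshift_table(self):
        # 4/60 low-rate vs 30/100 high-rate populations
        r = fisher_exact_2x2(4, 56, 30, 70)
        assert r.p_two_sided == pytest.approx(3e-4, abs=0.5e-4)

    def test_pathway_activation_table(self):
        assert fisher_exact_2x2(6, 8, 2, 85).p_two_sided < 6e-5

    def test_symmetric_table(self):
        r = fisher_exact_2x2(1, 1, 1, 1)
        assert r.p_two_sided == 1.0 and r.odds_ratio == 1.0

    def test_zero_cell_haldane_flag(self):
        r = fisher_exact_2x2(5, 0, 2, 7)
        assert r.haldane and r.odds_ratio == (5.5 * 7.5) / (0.5 * 2.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_matches_enumeration_oracle_small_margins(self):
        # spot-check here; the exhaustive margin sweep runs in the acceptance suite
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 9, size=4)
            if a + b + c + d == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d).p_two_sided == pytest.approx(
                brute_force_fisher(a, b, c, d), rel=1e-9)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04]) == [0.04]

    def test_step_up_by_hand(self):
        # q_i = min over j>=i of p_(j) * m / j, all equal to 0.04 here
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_empty(self):
        assert bh_fdr([]) == []

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_q_at_least_p(self, ps):
        qs = bh_fdr(ps)
        assert all(q >= p - 1e-12 for p, q in zip(ps, qs))
        order = np.argsort(ps)
        assert all(np.diff(np.array(qs)[order]) >= -1e-12)


class TestMannWhitney:
    def test_identical_groups(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0, abs=0.05)

    def test_full_enumeration_two_vs_two(self):
        # all 6 rank assignments; both extremes -> two-sided p = 2/6
        assert mann_whitney_u([1, 2], [10, 11]) == pytest.approx(2 / 6)

    def test_u_statistic_depends_on_ranks_not_gaps(self):
        p1 = mann_whitney_u([1, 2], [10, 11])
        p2 = mann_whitney_u([1, 2], [1000, 1100])
        assert p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestShannon:
    def test_uniform_four_clones(self):
        assert shannon_entropy([10, 10, 10, 10]) == pytest.approx(math.log(4))

    def test_single_clone(self):
        assert shannon_entropy([100]) == 0.0

    def test_three_one_split(self):
        assert shannon_entropy([3, 1]) == pytest.approx(0.5623, abs=1e-4)

    def test_zero_counts_ignored(self):
        assert shannon_entropy([3, 0, 1, 0]) == pytest.approx(shannon_entropy([3, 1]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=10**6), min_size=1, max_size=50)
           .filter(lambda c: sum(c) > 0))
    def test_entropy_bounds(self, counts):
        h = shannon_entropy(counts)
        nonzero = sum(1 for c in counts if c > 0)
        assert -1e-9 <= h <= math.log(nonzero) + 1e-9


class TestHotspots:
    def _cohort(self, positions_by_sample, gene=None):
        gene = gene or GeneModel("G", make_cds(50, seed=1))
        muts = []
        i = 0
        for sid, positions in positions_by_sample.items():
            for pos in positions:
                ref = gene.cds_sequence[pos - 1]
                alt = "T" if ref != "T" else "A"
                # force non-synonymous by deleting 1 nt instead when SNV would be silent
                muts.append(SomaticMutation(f"m{i}", sid, "G", pos, "DEL", "p", del_length=1))
                i += 1
        samples = [(s, "p") for s in positions_by_sample]
        return Cohort(samples=samples, mutations=muts, gene_models={"G": gene})

    def test_five_distinct_samples(self):
        cohort = self._cohort({f"S{i}": [31] for i in range(5)})
        calls = detect_hotspots(cohort, min_samples=2)
        assert len(calls) == 1
        assert calls[0].protein_pos == 11 and calls[0].n_samples == 5

    def test_same_sample_twice_not_hotspot(self):
        cohort = self._cohort({"S1": [31, 32]})
        assert detect_hotspots(cohort, min_samples=2) == []

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(5)
        gene = GeneModel("G", make_cds(40, seed=2))
        positions = {f"S{i}": list(rng.integers(4, 100, size=4)) for i in range(12)}
        cohort = self._cohort(positions, gene)
        calls = detect_hotspots(cohort, min_samples=2)
        # oracle: direct dict grouping over (codon -> samples)
        grouping = {}
        for m in cohort.mutations:
            grouping.setdefault(protein_position(m), set()).add(m.sample_id)
        expected = {(c, len(s)) for c, s in grouping.items() if len(s) >= 2}
        assert {(h.protein_pos, h.n_samples) for h in calls} == expected

    def test_insertion_first_affected_codon(self):
        m = SomaticMutation("m", "S", "G", 3, "INS", "p", inserted_seq="A")
        assert protein_position(m) == 2  # alters sequence from base 4 on


class TestMetaHotspots:
    def test_exact_codon_match_only(self):
        import pandas as pd
        gene = GeneModel("KRAS", make_cds(60, seed=3))
        muts = [SomaticMutation("m1", "S1", "KRAS", 35, "DEL", "p", del_length=1),
                SomaticMutation("m2", "S2", "KRAS", 34, "DEL", "p", del_length=1)]
        cohort = Cohort(samples=[("S1", "p"), ("S2", "p")], mutations=muts,
                        gene_models={"KRAS": gene})
        catalog = pd.DataFrame({"gene": ["KRAS", "TP53"], "codon": [12, 175],
                                "label": ["G12", "R175"]})
        out = match_meta_hotspots(cohort, catalog)
        assert list(out["codon"]) == [12] and out.iloc[0]["n_samples"] == 2
        # off-by-one codon and absent gene do not match
        catalog2 = pd.DataFrame({"gene": ["KRAS", "EGFR"], "codon": [13, 12],
                                 "label": ["G13", "x"]})
        assert match_meta_hotspots(cohort, catalog2).empty


class TestGeneSignificance:
    def test_qscore_boundary(self):
        from gbcpipe.stats import GeneSignificance
        r = GeneSignificance("G", 5, 1.0, 0.05, 0.1)
        assert r.q_score == pytest.approx(1.0)
        assert r.is_smg(qscore_min=1.0)

    def test_empty_cohort(self):
        cohort = Cohort(samples=[], mutations=[], gene_models={})
        assert gene_significance(cohort) == []

    def test_no_mutations_all_p_one(self):
        cohort = Cohort(samples=[("S1", "p")], mutations=[],
                        gene_models={"G": GeneModel("G", make_cds(20, seed=1))})
        res = gene_significance(cohort)
        assert [r.p for r in res] == [1.0]

    def test_planted_driver_flagged(self, small_cohort_and_truth):
        cohort, truth = small_cohort_and_truth
        res = gene_significance(cohort)
        flagged = {r.gene_symbol for r in res if r.is_smg()}
        assert "TP53" in flagged


class TestCooccurrence:
    def _pair_cohort(self, pattern):
        gene_a = GeneModel("A", make_cds(30, seed=1))
        gene_b = GeneModel("B", make_cds(30, seed=2))
        muts, samples = [], []
        for i, (has_a, has_b) in enumerate(pattern):
            sid = f"S{i}"
            samples.append((sid, "p"))
            if has_a:
                muts.append(SomaticMutation(f"a{i}", sid, "A", 10, "DEL", "p", del_length=1))
            if has_b:
                muts.append(SomaticMutation(f"b{i}", sid, "B", 10, "DEL", "p", del_length=1))
        return Cohort(samples=samples, mutations=muts,
                      gene_models={"A": gene_a, "B": gene_b})

    def test_perfect_cooccurrence(self):
        pattern = [(True, True)] * 20 + [(False, False)] * 20
        r = cooccurrence(self._pair_cohort(pattern), "A", "B")
        assert r.p_two_sided < 0.001

    def test_manual_cross_tabulation(self):
        pattern = [(True, True), (True, False), (False, True),
                   (False, False), (True, True), (False, False)]
        r = cooccurrence(self._pair_cohort(pattern), "A", "B")
        assert r.table == ((2, 1), (1, 2))

    def test_null_calibration_type_one_error(self):
        # independent genes: rejection rate at 0.05 stays within the
        # binomial envelope over 1000 simulated cohorts
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            pattern = [(rng.random() < 0.4, rng.random() < 0.4) for _ in range(60)]
            r = cooccurrence(self._pair_cohort(pattern), "A", "B")
            rejections += r.p_two_sided < 0.05
        # Fisher is conservative: reject at most at nominal rate (+3 sigma)
        assert rejections / n_rep <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_rep)

    def test_unknown_gene(self, toy_cohort):
        with pytest.raises(KeyError):
            cooccurrence(toy_cohort, "TOY", "NOPE")


class TestRandomization:
    def test_observed_statistic_is_truncating_fraction(self, small_cohort):
        res = randomization_test_truncating("ELF3", small_cohort, n_iter=50, seed=1)
        from gbcpipe.consequence import is_truncating
        g = small_cohort.gene_models["ELF3"]
        muts = small_cohort.mutations_of_gene("ELF3")
        expected = sum(is_truncating(m, g) for m in muts) / len(muts)
        assert res.observed_statistic == pytest.approx(expected)
        assert 0 < res.empirical_p <= 1.0

    def test_same_seed_identical_draws(self, small_cohort):
        r1 = randomization_test_truncating("ELF3", small_cohort, n_iter=30, seed=9)
        r2 = randomization_test_truncating("ELF3", small_cohort, n_iter=30, seed=9)
        assert np.array_equal(r1.null_draws, r2.null_draws)

    def test_observed_zero_gives_p_one(self):
        # all-synonymous-capable set: a single synonymous SNV can still
        # truncate under random placement, so p stays in (0, 1]
        gene = GeneModel("G", make_cds(30, seed=4))
        m = SomaticMutation("m", "S1", "G", 6, "SNV", "p",
                            ref_base=gene.cds_sequence[5],
                            alt_base={"A": "G", "G": "A", "C": "T", "T": "C"}[
                                gene.cds_sequence[5]])
        cohort = Cohort(samples=[("S1", "p")], mutations=[m], gene_models={"G": gene})
        res = randomization_test_truncating("G", cohort, n_iter=40, seed=2)
        if res.observed_statistic == 0.0:
            assert res.empirical_p >= 1 / 41

    def test_n_iter_must_be_positive(self, small_cohort):
        with pytest.raises(ValueError):
            randomization_test_truncating("ELF3", small_cohort, n_iter=0, seed=1)
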