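"""Peptide enumeration, binder calling, allele pools and the
immune-editing Monte Carlo."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from gbcpipe.consequence import MutantProtein, build_mutant_protein, translate_cds
from gbcpipe.model import AnalysisConfig, Cohort, GeneModel, SomaticMutation
from gbcpipe.neoantigen import (
    AMINO_ACIDS,
    AllelePool,
    SurrogatePredictor,
    TablePredictor,
    best_affinity,
    build_allele_pool,
    call_binders,
    enumerate_mutant_peptides,
    immune_editing_mc,
    odds_ratio_from_props,
    summarize_neoantigens,
)

from conftest import make_cds

DATA = Path(__file__).parent / "data"


def _mp(seq, span):
    return MutantProtein(seq, span, truncated=False, no_stop_reached=False)


def _random_protein(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


class TestEnumeration:
    def test_interior_missense_window_count(self):
        # novel residue at position 15 of a 30-mer: k windows containing
        # it number k each for k=8..11 -> 38 candidates before filtering
        wt = _random_protein(30, seed=1)
        mut = wt[:14] + ("A" if wt[14] != "A" else "C") + wt[15:]
        peps = enumerate_mutant_peptides(_mp(mut, (15, 15)), wt, 8, 11)
        assert len(peps) == 8 + 9 + 10 + 11
        assert all(p.sequence not in wt for p in peps)
        assert all(len(p.novel_positions) >= 1 for p in peps)

    def test_novel_residue_at_position_one(self):
        wt = _random_protein(15, seed=2)
        mut = ("A" if wt[0] != "A" else "C") + wt[1:]
        peps = enumerate_mutant_peptides(_mp(mut, (1, 1)), wt, 8, 11)
        assert len(peps) == 4  # one start per k

    def test_synonymous_yields_nothing(self):
        wt = _random_protein(20, seed=3)
        assert enumerate_mutant_peptides(_mp(wt, None), wt, 8, 11) == []

    def test_frameshift_tail_all_windows_novel(self):
        wt = _random_protein(40, seed=4)
        tail = _random_protein(12, seed=5)
        mut = wt[:20] + tail
        peps = enumerate_mutant_peptides(_mp(mut, (21, 32)), wt, 8, 11)
        lengths = {len(p.sequence) for p in peps}
        assert lengths == {8, 9, 10, 11}
        for p in peps:
            assert any(21 <= i <= 32 for i in
                       range(mut.index(p.sequence) + 1,
                             mut.index(p.sequence) + len(p.sequence) + 1))

    def test_wild_type_substring_discarded(self):
        # mutant repeats a wild-type block so some windows are wt substrings
        wt = _random_protein(30, seed=6)
        mut = wt[:10] + wt[:12]  # duplicated prefix: windows inside it match wt
        peps = enumerate_mutant_peptides(_mp(mut, (11, 22)), wt, 8, 11)
        assert all(p.sequence not in wt for p in peps)

    def test_window_count_formula(self):
        # closed form: max(0, min(p, L-k+1) - max(1, p-k+1) + 1)
        for L in (8, 12, 25):
            wt = _random_protein(L, seed=L)
            for p in range(1, L + 1):
                mut = wt[: p - 1] + ("A" if wt[p - 1] != "A" else "C") + wt[p:]
                for k in range(8, 12):
                    expected = max(0, min(p, L - k + 1) - max(1, p - k + 1) + 1)
                    peps = enumerate_mutant_peptides(_mp(mut, (p, p)), wt, k, k)
                    assert len(peps) == expected, (L, p, k)


class TestBinderCalls:
    def _pep(self, seq="ACDEFGHIK"):
        from gbcpipe.neoantigen import PeptideCandidate
        return PeptideCandidate(seq, "m", "G", "S", (0,))

    def test_threshold_is_inclusive(self):
        calls = call_binders([(self._pep(), "A*01", 500.0), (self._pep(), "A*01", 500.1)])
        assert calls[0].binder and not calls[1].binder

    def test_empty_input(self):
        assert call_binders([]) == []

    def test_non_positive_ic50_rejected(self):
        with pytest.raises(ValueError):
            call_binders([(self._pep(), "A*01", 0.0)])

    def test_best_affinity_min_and_tiebreak(self):
        from gbcpipe.neoantigen import AffinityCall, PeptideCandidate
        a = AffinityCall(PeptideCandidate("CCCCCCCCC", "m", "G", "S", (0,)), "A*01", 400.0, True)
        b = AffinityCall(PeptideCandidate("AAAAAAAAA", "m", "G", "S", (0,)), "A*01", 400.0, True)
        c = AffinityCall(PeptideCandidate("DDDDDDDDD", "m", "G", "S", (0,)), "A*01", 300.0, True)
        assert best_affinity([a, b]) is b        # lexicographic peptide tie-break
        assert best_affinity([a, b, c]) is c     # plain minimum
        assert best_affinity([a]) is a
        with pytest.raises(ValueError):
            best_affinity([])


class TestSurrogate:
    def test_deterministic(self):
        p1 = SurrogatePredictor(seed=1)
        p2 = SurrogatePredictor(seed=1)
        assert p1.ic50("ACDEFGHIK", "A*01") == p2.ic50("ACDEFGHIK", "A*01")

    def test_golden_file_across_restarts(self):
        golden = pd.read_csv(DATA / "surrogate_golden.tsv", sep="\t")
        pred = SurrogatePredictor(seed=123)
        for r in golden.itertuples():
            assert pred.ic50(r.peptide, r.allele) == pytest.approx(r.ic50, rel=1e-9)

    def test_binder_fraction_of_random_9mers(self):
        # z ~ N(0,1) so P(IC50 <= 500) = P(z >= 2) ~ 0.023
        rng = np.random.default_rng(7)
        pred = SurrogatePredictor(seed=5)
        hits = sum(
            pred.ic50("".join(rng.choice(list(AMINO_ACIDS), size=9)), "B*07") <= 500
            for _ in range(10_000))
        assert 0.005 < hits / 10_000 < 0.10

    def test_alleles_get_distinct_matrices(self):
        pred = SurrogatePredictor(seed=2)
        m1 = pred._matrix("A*01", 9)
        m2 = pred._matrix("A*02", 9)
        assert (m1 != m2).any()

    def test_length_out_of_range(self):
        with pytest.raises(ValueError):
            SurrogatePredictor().ic50("SHORT", "A*01")

    def test_table_predictor_lookup(self):
        t = TablePredictor(pd.DataFrame(
            {"peptide": ["ACDEFGHIK"], "allele": ["A*01"], "ic50": [42.0]}))
        assert t.ic50("ACDEFGHIK", "A*01") == 42.0
        with pytest.raises(KeyError):
            t.ic50("ACDEFGHIK", "A*02")


class TestAllelePool:
    def _cohort(self):
        hla = {"S1": ["X", "X"], "S2": ["X", "X"], "S3": ["Y"]}
        return Cohort(samples=[("S1", "pA"), ("S2", "pA"), ("S3", "pB")],
                      mutations=[], gene_models={}, hla=hla)

    def test_multiplicity_preserved(self):
        pool = build_allele_pool(self._cohort(), "pA")
        assert sorted(pool.alleles) == ["X", "X", "X", "X"]

    def test_size_is_total_copies(self):
        cohort = self._cohort()
        pool = build_allele_pool(cohort, "pA")
        assert len(pool.alleles) == sum(len(cohort.hla[s]) for s in ("S1", "S2"))

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            build_allele_pool(self._cohort(), "pC")


def _mini_cohort(seed=0):
    gene = GeneModel("G", make_cds(60, seed=seed))
    muts = []
    rng = np.random.default_rng(seed)
    for i in range(6):
        pos = int(rng.integers(10, 150))
        muts.append(SomaticMutation(
            f"m{i}", f"S{i % 3}", "G", pos, "DEL", "pop",
            del_length=1, expressed_read_count=int(i != 0)))
    samples = [(f"S{i}", "pop") for i in range(3)]
    hla = {f"S{i}": [f"A*{j:02d}" for j in range(1, 5)] for i in range(3)}
    return Cohort(samples=samples, mutations=muts, gene_models={"G": gene}, hla=hla)


class TestSummarize:
    def test_expression_filter_and_oracle(self):
        cohort = _mini_cohort(seed=3)
        pred = SurrogatePredictor(seed=9)
        cfg = AnalysisConfig()
        summary = summarize_neoantigens(cohort, pred, cfg)
        # independent brute-force pass over (mutation, peptide, allele)
        wt = translate_cds(cohort.gene_models["G"].cds_sequence)
        for sid in cohort.sample_ids:
            n = 0
            for m in cohort.mutations:
                if m.sample_id != sid or m.expressed_read_count < 1:
                    continue
                mp = build_mutant_protein(m, cohort.gene_models["G"])
                peps = enumerate_mutant_peptides(mp, wt, 8, 11)
                if any(pred.ic50(p.sequence, a) <= 500.0
                       for p in peps for a in set(cohort.hla[sid])):
                    n += 1
            assert summary.per_sample[sid] == n

    def test_unexpressed_mutation_never_counts(self):
        cohort = _mini_cohort(seed=4)
        # zero out all expression support: nothing can count
        muts = [SomaticMutation(m.mutation_id, m.sample_id, m.gene_symbol, m.cds_pos,
                                m.mutation_type, m.population, del_length=m.del_length,
                                expressed_read_count=0)
                for m in cohort.mutations]
        cohort2 = Cohort(cohort.samples, muts, cohort.gene_models, hla=cohort.hla)
        summary = summarize_neoantigens(cohort2, SurrogatePredictor(seed=9))
        assert all(v == 0 for v in summary.per_sample.values())

    def test_sample_without_hla_skipped_with_warning(self):
        cohort = _mini_cohort(seed=5)
        del cohort.hla["S2"]
        with pytest.warns(UserWarning, match="S2"):
            summary = summarize_neoantigens(cohort, SurrogatePredictor(seed=9))
        assert "S2" in summary.skipped_samples


class TestImmuneEditing:
    def test_counts_sum_to_n_sim_and_determinism(self):
        cohort = _mini_cohort(seed=6)
        gene = cohort.gene_models["G"]
        pool = AllelePool("pop", tuple(f"A*{j:02d}" for j in range(1, 9)))
        pred = SurrogatePredictor(seed=3)
        r1 = immune_editing_mc(cohort.mutations, gene, pool, pool, pred,
                               n_sim=200, seed=11)
        r2 = immune_editing_mc(cohort.mutations, gene, pool, pool, pred,
                               n_sim=200, seed=11)
        assert r1.binders_a + r1.nonbinders_a == 200
        assert (r1.binders_a, r1.binders_b) == (r2.binders_a, r2.binders_b)

    def test_planted_binding_allele_shifts_odds_ratio(self):
        # engineer an allele that binds the frameshift tail by searching
        # the surrogate's deterministic allele space
        gene = GeneModel("G", make_cds(80, seed=7))
        pred = SurrogatePredictor(seed=21)
        wt = translate_cds(gene.cds_sequence)
        # pick a frameshift whose novel tail is long enough to window
        for pos in range(60, 200, 7):
            m = SomaticMutation("fs", "S0", "G", pos, "DEL", "pop", del_length=1,
                                expressed_read_count=5)
            mp = build_mutant_protein(m, gene)
            peps = enumerate_mutant_peptides(mp, wt, 8, 11, "fs", "G", "S0")
            if len(peps) > 10:
                break
        assert len(peps) > 10
        def best(allele):
            return min(pred.ic50(p.sequence, allele) for p in peps)
        candidates = [f"Z*{i:03d}" for i in range(60)]
        strong = min(candidates, key=best)
        weak = max(candidates, key=best)
        assert best(strong) <= 500.0  # best-of-many peptides binds
        pool_strong = AllelePool("strong", (strong,) * 4)
        pool_weak = AllelePool("weak", (weak,) * 4)
        res = immune_editing_mc([m], gene, pool_strong, pool_weak, pred,
                                n_sim=5000, seed=1)
        assert res.binders_a > res.binders_b
        assert res.contingency.p_two_sided < 0.05
        assert res.contingency.odds_ratio > 1

    def test_wrong_gene_mutations_rejected(self):
        cohort = _mini_cohort(seed=8)
        other = GeneModel("H", make_cds(30, seed=9))
        pool = AllelePool("pop", ("A*01",))
        with pytest.raises(ValueError):
            immune_editing_mc(cohort.mutations, other, pool, pool,
                              SurrogatePredictor(), n_sim=10, seed=0)


class TestOddsRatio:
    def test_printed_binder_rates(self):
        assert odds_ratio_from_props(0.43, 0.41) == pytest.approx(1.1, abs=0.05)

    def test_symmetry_and_reciprocal(self):
        assert odds_ratio_from_props(0.5, 0.5) == 1.0
        assert odds_ratio_from_props(0.3, 0.7) == pytest.approx(
            1 / odds_ratio_from_props(0.7, 0.3))

    @pytest.mark.parametrize("p1,p2", [(0.0, 0.5), (0.5, 1.0), (1.2, 0.5)])
    def test_boundary_rejected(self, p1, p2):
        with pytest.raises(ValueError):
            odds_ratio_from_props(p1, p2)
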