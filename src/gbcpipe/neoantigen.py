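"""Mutant-peptide enumeration, MHC-I binder calling and the
immune-editing Monte Carlo.

Binding prediction goes through a pluggable predictor contract: any
object with a deterministic ``ic50(peptide, allele) -> nM`` method.
A deterministic surrogate predictor is bundled so the pipeline runs
without an external MHC tool; real predictions can be wired in from a
scored-peptide TSV. The binder rule is inclusive: IC50 <= 500 nM.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .consequence import MutantProtein, build_mutant_protein, translate_with_flags
from .model import AnalysisConfig, Cohort, GeneModel, SomaticMutation
from .stats import ContingencyResult, fisher_exact_2x2

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class PeptideCandidate:
    sequence: str
    mutation_id: str
    gene_symbol: str
    sample_id: str
    novel_positions: tuple[int, ...]  # 0-based indices within the peptide


@dataclass(frozen=True)
class AffinityCall:
    peptide: PeptideCandidate
    allele: str
    ic50_nM: float
    binder: bool


class PredictorContract(Protocol):
    """Deterministic (peptide, allele) -> IC50 nM in [0.1, 50000]."""

    def ic50(self, peptide: str, allele: str) -> float: ...


class SurrogatePredictor:
    """Deterministic stand-in affinity model.

    For each (allele, peptide length k) a k x 20 position weight
    matrix is derived from a seeded pseudo-random stream; the summed
    per-position weights, scaled by 1/sqrt(k), give a standard-normal
    score z for random peptides, and IC50 = 50000 x 10^(-a z) clipped
    to [0.1, 50000]. With sharpness a = 1 roughly 2% of random 9-mers
    fall at or below 500 nM, a plausible binder rate.
    """

    def __init__(self, seed: int = 0, sharpness: float = 1.0,
                 kmin: int = 8, kmax: int = 11):
        self.seed = seed
        self.sharpness = sharpness
        self.kmin, self.kmax = kmin, kmax
        self._matrices: dict[tuple[str, int], np.ndarray] = {}
        self._cache: dict[tuple[str, str], float] = {}

    def _matrix(self, allele: str, k: int) -> np.ndarray:
        key = (allele, k)
        if key not in self._matrices:
            digest = hashlib.sha256(f"{allele}|{k}|{self.seed}".encode()).digest()
            rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
            self._matrices[key] = rng.standard_normal((k, 20))
        return self._matrices[key]

    def ic50(self, peptide: str, allele: str) -> float:
        k = len(peptide)
        if not (self.kmin <= k <= self.kmax):
            raise ValueError(f"peptide length {k} outside {self.kmin}..{self.kmax}")
        key = (peptide, allele)
        if key not in self._cache:
            W = self._matrix(allele, k)
            z = sum(W[i, _AA_INDEX[a]] for i, a in enumerate(peptide)) / np.sqrt(k)
            self._cache[key] = float(np.clip(50000.0 * 10.0 ** (-self.sharpness * z),
                                             0.1, 50000.0))
        return self._cache[key]


class TablePredictor:
    """Predictions read from a scored-peptide TSV (peptide, allele, ic50),
    the adapter point for an external MHC-I tool."""

    def __init__(self, table: pd.DataFrame):
        self._scores = {(r.peptide, r.allele): float(r.ic50) for r in table.itertuples()}

    @classmethod
    def from_tsv(cls, path) -> "TablePredictor":
        return cls(pd.read_csv(path, sep="\t"))

    def ic50(self, peptide: str, allele: str) -> float:
        try:
            return self._scores[(peptide, allele)]
        except KeyError:
            raise KeyError(f"no prediction for ({peptide}, {allele})") from None


def enumerate_mutant_peptides(
    mp: MutantProtein, wt: str, kmin: int = 8, kmax: int = 11,
    mutation_id: str = "", gene_symbol: str = "", sample_id: str = "",
) -> list[PeptideCandidate]:
    """All kmin..kmax windows of the mutant protein overlapping at
    least one novel residue, deduplicated, with wild-type substrings
    discarded (those are not neoantigens by definition)."""
    if not mp.sequence or mp.novel_span is None:
        return []
    a, b = mp.novel_span
    L = len(mp.sequence)
    out: list[PeptideCandidate] = []
    seen: set[str] = set()
    for k in range(kmin, kmax + 1):
        for start in range(max(1, a - k + 1), min(b, L - k + 1) + 1):
            pep = mp.sequence[start - 1 : start - 1 + k]
            if pep in seen or pep in wt:
                continue
            seen.add(pep)
            novel = tuple(
                i for i in range(k)
                if a <= start + i <= b
            )
            out.append(PeptideCandidate(pep, mutation_id, gene_symbol, sample_id, novel))
    return out


def call_binders(calls: Sequence[tuple[PeptideCandidate, str, float]],
                 threshold_nM: float = 500.0) -> list[AffinityCall]:
    """Set the binder flag by inclusive comparison with the threshold."""
    out = []
    for pep, allele, ic50 in calls:
        if ic50 <= 0:
            raise ValueError(f"non-positive IC50 {ic50} for {pep.sequence}/{allele}")
        out.append(AffinityCall(pep, allele, float(ic50), ic50 <= threshold_nM))
    return out


def best_affinity(calls: Sequence[AffinityCall]) -> AffinityCall:
    """Representative call: minimum IC50, ties to the lexicographically
    smallest peptide then allele."""
    if not calls:
        raise ValueError("no affinity calls")
    return min(calls, key=lambda c: (c.ic50_nM, c.peptide.sequence, c.allele))


@dataclass(frozen=True)
class AllelePool:
    """All observed HLA allele copies of one population, multiplicities
    preserved exactly as observed."""

    population: str
    alleles: tuple[str, ...]


def build_allele_pool(cohort: Cohort, population: str) -> AllelePool:
    if not cohort.hla:
        raise ValueError("cohort has no HLA typings")
    alleles: list[str] = []
    for sid in cohort.samples_of(population):
        alleles.extend(cohort.hla.get(sid, []))
    if not alleles:
        raise ValueError(f"no HLA alleles observed for population {population!r}")
    return AllelePool(population, tuple(alleles))


@dataclass
class NeoantigenSummary:
    """Per-sample neoantigen burden: expressed mutations with at least
    one binder peptide against any of the sample's alleles."""

    per_sample: dict[str, int]
    per_gene: dict[str, int]
    skipped_samples: list[str]  # samples without HLA typings

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_sample.values()))) if self.per_sample else 0.0

    @property
    def range(self) -> tuple[int, int]:
        v = list(self.per_sample.values())
        return (min(v), max(v)) if v else (0, 0)


class _PeptideCache:
    """Per-mutation peptide lists and per-(mutation, allele) best IC50."""

    def __init__(self, gene_models: dict[str, GeneModel], predictor: PredictorContract,
                 kmin: int, kmax: int):
        self.gene_models = gene_models
        self.predictor = predictor
        self.kmin, self.kmax = kmin, kmax
        self._wt: dict[str, str] = {}
        self._peps: dict[str, list[PeptideCandidate]] = {}
        self._best: dict[tuple[str, str], Optional[AffinityCall]] = {}

    def wild_type(self, gene_symbol: str) -> str:
        if gene_symbol not in self._wt:
            self._wt[gene_symbol] = translate_with_flags(
                self.gene_models[gene_symbol].cds_sequence)[0]
        return self._wt[gene_symbol]

    def peptides(self, m: SomaticMutation) -> list[PeptideCandidate]:
        if m.mutation_id not in self._peps:
            g = self.gene_models[m.gene_symbol]
            mp = build_mutant_protein(m, g)
            self._peps[m.mutation_id] = enumerate_mutant_peptides(
                mp, self.wild_type(m.gene_symbol), self.kmin, self.kmax,
                m.mutation_id, m.gene_symbol, m.sample_id)
        return self._peps[m.mutation_id]

    def best_call(self, m: SomaticMutation, allele: str) -> Optional[AffinityCall]:
        key = (m.mutation_id, allele)
        if key not in self._best:
            peps = self.peptides(m)
            if not peps:
                self._best[key] = None
            else:
                calls = call_binders(
                    [(p, allele, self.predictor.ic50(p.sequence, allele)) for p in peps])
                self._best[key] = best_affinity(calls)
        return self._best[key]


def summarize_neoantigens(cohort: Cohort, predictor: PredictorContract,
                          config: Optional[AnalysisConfig] = None) -> NeoantigenSummary:
    """Count, per sample, expressed mutations carrying >= 1 binder
    peptide against any of the sample's HLA alleles."""
    config = config or AnalysisConfig()
    if not cohort.hla:
        raise ValueError("cohort has no HLA typings")
    cache = _PeptideCache(cohort.gene_models, predictor,
                          config.peptide_kmin, config.peptide_kmax)
    per_sample: dict[str, int] = {}
    per_gene: dict[str, int] = {}
    skipped: list[str] = []
    for sid in cohort.sample_ids:
        alleles = cohort.hla.get(sid)
        if not alleles:
            skipped.append(sid)
            warnings.warn(f"sample {sid} has no HLA typing; excluded from neoantigen summary")
            continue
        n = 0
        for m in cohort.mutations:
            if m.sample_id != sid or m.expressed_read_count < config.expression_min_reads:
                continue
            hit = False
            for allele in set(alleles):
                call = cache.best_call(m, allele)
                if call is not None and call.ic50_nM <= config.binder_threshold_nM:
                    hit = True
                    break
            if hit:
                n += 1
                per_gene[m.gene_symbol] = per_gene.get(m.gene_symbol, 0) + 1
        per_sample[sid] = n
    return NeoantigenSummary(per_sample, per_gene, skipped)


def odds_ratio_from_props(p1: float, p2: float) -> float:
    """(p1/(1-p1)) / (p2/(1-p2)); boundary proportions are an error."""
    for p in (p1, p2):
        if not 0 < p < 1:
            raise ValueError(f"proportion {p} outside the open interval (0, 1)")
    return (p1 / (1 - p1)) / (p2 / (1 - p2))


@dataclass
class ImmunoeditingResult:
    """Monte Carlo comparison of binder rates between two HLA pools."""

    n_sim: int
    binders_a: int
    binders_b: int
    contingency: ContingencyResult
    or_from_proportions: Optional[float]
    pool_a: str = "A"
    pool_b: str = "B"

    @property
    def nonbinders_a(self) -> int:
        return self.n_sim - self.binders_a

    @property
    def nonbinders_b(self) -> int:
        return self.n_sim - self.binders_b


def immune_editing_mc(
    mutations: Sequence[SomaticMutation],
    gene: GeneModel,
    pool_a: AllelePool,
    pool_b: AllelePool,
    predictor: PredictorContract,
    n_sim: int = 5000,
    seed: int = 0,
    threshold_nM: float = 500.0,
    kmin: int = 8,
    kmax: int = 11,
    cache: Optional[_PeptideCache] = None,
) -> ImmunoeditingResult:
    """Per iteration and per pool, draw one mutation and one allele
    copy uniformly, take the best-affinity peptide of that mutation
    against that allele, and record a binder by the inclusive 500 nM
    rule; then compare binder counts with a two-sided Fisher test.
    """
    if not mutations:
        raise ValueError("no mutations supplied")
    if not pool_a.alleles or not pool_b.alleles:
        raise ValueError("both allele pools must be non-empty")
    muts = [m for m in mutations if m.gene_symbol == gene.gene_symbol]
    if len(muts) != len(mutations):
        raise ValueError("mutation list must be restricted to the target gene")
    cache = cache or _PeptideCache({gene.gene_symbol: gene}, predictor, kmin, kmax)
    rng = np.random.default_rng(seed)
    binders = {}
    for label, pool in (("a", pool_a), ("b", pool_b)):
        mut_idx = rng.integers(0, len(muts), size=n_sim)
        all_idx = rng.integers(0, len(pool.alleles), size=n_sim)
        count = 0
        for mi, ai in zip(mut_idx, all_idx):
            call = cache.best_call(muts[mi], pool.alleles[ai])
            if call is not None and call.ic50_nM <= threshold_nM:
                count += 1
        binders[label] = count
    ct = fisher_exact_2x2(binders["a"], n_sim - binders["a"],
                          binders["b"], n_sim - binders["b"])
    fa, fb = binders["a"] / n_sim, binders["b"] / n_sim
    orp = odds_ratio_from_props(fa, fb) if 0 < fa < 1 and 0 < fb < 1 else None
    return ImmunoeditingResult(n_sim, binders["a"], binders["b"], ct, orp,
                               pool_a.population, pool_b.population)


__all__ = [
    "PeptideCandidate", "AffinityCall", "AllelePool", "PredictorContract",
    "SurrogatePredictor", "TablePredictor", "NeoantigenSummary",
    "ImmunoeditingResult", "enumerate_mutant_peptides", "call_binders",
    "best_affinity", "build_allele_pool", "summarize_neoantigens",
    "immune_editing_mc", "odds_ratio_from_props", "AMINO_ACIDS",
]
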