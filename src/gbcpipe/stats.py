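"""Exact 2x2 statistics, FDR, diversity indices, hotspot detection,
gene significance and the truncating-fraction randomization test.

The gene-significance test is a deliberately simple Poisson background
model (cohort-wide per-base per-sample rate, upper-tail test per gene,
BH correction) — comparable in spirit, not numerically, to
convolution-based exome tools. q-score = -log10(q), with q-score >= 1
selecting significantly mutated genes (SMGs).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .consequence import (
    Consequence,
    SUBSTITUTION_TYPES,
    classify_consequence,
    is_truncating,
    trinucleotide_context,
)
from .model import Cohort, GeneModel, SomaticMutation


@dataclass(frozen=True)
class ContingencyResult:
    """Two-sided Fisher exact result for a 2x2 table.

    With any zero cell the odds ratio uses the Haldane-Anscombe
    correction (0.5 added to every cell) and ``haldane`` is flagged.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float
    haldane: bool = False


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-sided Fisher exact test: the p-value sums hypergeometric
    point probabilities not exceeding the observed one (with the usual
    1e-7 relative tolerance)."""
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError("cells must be non-negative integers")
    if sum(cells) == 0:
        raise ValueError("all-zero table")
    a, b, c, d = (int(x) for x in cells)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        return ContingencyResult(((a, b), (c, d)), orr, float(p), haldane=True)
    return ContingencyResult(((a, b), (c, d)), (a * d) / (b * c), float(p))


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = list(pvalues)
    if not p:
        return []
    if any(x < 0 or x > 1 or x != x for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p: exact distribution for combined n <= 20
    without ties, tie-corrected normal approximation otherwise."""
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    no_ties = len(set(x + y)) == len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and no_ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def shannon_entropy(counts: Iterable[float]) -> float:
    """Shannon index H = -sum p ln p over clonotype frequencies (nats);
    zero-count clones are ignored."""
    all_counts = np.asarray(list(counts), dtype=float)
    if np.any(all_counts < 0):
        raise ValueError("negative clonotype count")
    arr = all_counts[all_counts > 0]
    if arr.size == 0:
        raise ValueError("no clonotypes with positive count")
    return float(sps.entropy(arr))


@dataclass(frozen=True)
class HotspotCall:
    gene_symbol: str
    protein_pos: int
    n_samples: int  # distinct samples, not mutation rows
    consequences: tuple[str, ...] = ()


def protein_position(m: SomaticMutation) -> int:
    """First affected codon: ceil(pos/3) for SNV/DEL; insertions alter
    sequence only after their anchor, so the next base's codon."""
    pos = m.cds_pos + 1 if m.mutation_type == "INS" else m.cds_pos
    return -(-pos // 3)


def _protein_altering(m: SomaticMutation, g: GeneModel) -> bool:
    if m.consequence_override:
        return True
    return classify_consequence(m, g) is not Consequence.synonymous


def detect_hotspots(cohort: Cohort, min_samples: int = 2,
                    require_expression: bool = False,
                    expression_min_reads: int = 1) -> list[HotspotCall]:
    """Codons carrying protein-altering mutations in >= min_samples
    distinct samples, sorted by sample count (desc) then gene/codon.

    ``require_expression`` keeps only mutations with RNA support, the
    optional confirmation filter applied upstream of hotspot reporting.
    """
    groups: dict[tuple[str, int], dict[str, list[str]]] = {}
    for m in cohort.mutations:
        g = cohort.gene_models[m.gene_symbol]
        if not _protein_altering(m, g):
            continue
        if require_expression and m.expressed_read_count < expression_min_reads:
            continue
        key = (m.gene_symbol, protein_position(m))
        groups.setdefault(key, {}).setdefault(m.sample_id, []).append(
            classify_consequence(m, g).value)
    calls = [
        HotspotCall(gene, codon, len(by_sample),
                    tuple(sorted(c for v in by_sample.values() for c in v)))
        for (gene, codon), by_sample in groups.items()
        if len(by_sample) >= min_samples
    ]
    calls.sort(key=lambda h: (-h.n_samples, h.gene_symbol, h.protein_pos))
    return calls


def read_hotspot_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "codon": int, "label": str})
    return df


def match_meta_hotspots(cohort: Cohort, catalog: pd.DataFrame) -> pd.DataFrame:
    """Cohort mutations whose (gene, codon) matches a catalog entry
    exactly; returns one row per matched site with sample counts."""
    sites = {(r.gene, int(r.codon)): getattr(r, "label", "") for r in catalog.itertuples()}
    hits: dict[tuple[str, int], set[str]] = {}
    n_mut: Counter = Counter()
    for m in cohort.mutations:
        g = cohort.gene_models[m.gene_symbol]
        if not _protein_altering(m, g):
            continue
        key = (m.gene_symbol, protein_position(m))
        if key in sites:
            hits.setdefault(key, set()).add(m.sample_id)
            n_mut[key] += 1
    rows = [
        {"gene": gene, "codon": codon, "label": sites[(gene, codon)],
         "n_samples": len(samples), "n_mutations": n_mut[(gene, codon)]}
        for (gene, codon), samples in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "codon", "label", "n_samples", "n_mutations"])


@dataclass(frozen=True)
class GeneSignificance:
    gene_symbol: str
    observed: int
    expected: float
    p: float
    q: float

    @property
    def q_score(self) -> float:
        return -math.log10(self.q) if self.q > 0 else math.inf

    def is_smg(self, qscore_min: float = 1.0) -> bool:
        return self.q_score >= qscore_min


def gene_significance(cohort: Cohort, exclude_msi: bool = True,
                      msi_threshold: float = 0.35,
                      qscore_min: float = 1.0,
                      exclude_from_background: Iterable[str] = (),
                      ) -> list[GeneSignificance]:
    """Poisson-background gene significance.

    Background rate = protein-altering mutations per CDS base per
    sample (hypermutated MSI samples excluded when flagged, given
    their outlier burden); per-gene expectation = rate x CDS length x
    n samples; upper-tail Poisson p, BH q.

    ``exclude_from_background`` lets known drivers be left out of the
    rate estimate — on a small gene panel a strong driver otherwise
    inflates the background appreciably (a panel-scale artifact that
    is negligible exome-wide). Excluded genes are still tested.
    """
    included = set(cohort.sample_ids)
    if exclude_msi and cohort.msi_scores:
        included -= {s for s, v in cohort.msi_scores.items() if v > msi_threshold}
    n_samples = len(included)
    genes = sorted(cohort.gene_models)
    excluded_bg = set(exclude_from_background)
    obs = Counter()
    for m in cohort.mutations:
        if m.sample_id in included and _protein_altering(
                m, cohort.gene_models[m.gene_symbol]):
            obs[m.gene_symbol] += 1
    bg_genes = [g for g in genes if g not in excluded_bg] or genes
    bg_bases = sum(len(cohort.gene_models[g].cds_sequence) for g in bg_genes)
    bg_total = sum(obs[g] for g in bg_genes)
    if bg_total == 0 or n_samples == 0:
        pvals = [1.0] * len(genes)
    else:
        rate = bg_total / (bg_bases * n_samples)
        pvals = [
            float(sps.poisson.sf(obs[g] - 1,
                                 rate * len(cohort.gene_models[g].cds_sequence) * n_samples))
            if obs[g] > 0 else 1.0
            for g in genes
        ]
    qvals = bh_fdr(pvals) if genes else []
    per_base = bg_total / bg_bases if bg_total else 0.0
    out = [
        GeneSignificance(
            g, obs[g], per_base * len(cohort.gene_models[g].cds_sequence), p, q,
        )
        for g, p, q in zip(genes, pvals, qvals)
    ]
    out.sort(key=lambda r: (r.p, r.gene_symbol))
    return out


def cooccurrence(cohort: Cohort, gene_a: str, gene_b: str) -> ContingencyResult:
    """Fisher test of co-mutation across samples for two genes."""
    for g in (gene_a, gene_b):
        if g not in cohort.gene_models:
            raise KeyError(f"gene {g!r} not in cohort")
    mut_a, mut_b = set(), set()
    for m in cohort.mutations:
        if _protein_altering(m, cohort.gene_models[m.gene_symbol]):
            if m.gene_symbol == gene_a:
                mut_a.add(m.sample_id)
            elif m.gene_symbol == gene_b:
                mut_b.add(m.sample_id)
    both = a_only = b_only = neither = 0
    for s in cohort.sample_ids:
        ina, inb = s in mut_a, s in mut_b
        both += ina and inb
        a_only += ina and not inb
        b_only += inb and not ina
        neither += not ina and not inb
    return fisher_exact_2x2(both, a_only, b_only, neither)


@dataclass
class RandomizationResult:
    """Monte Carlo comparison of an observed truncating fraction
    against random re-placement of the same mutation set."""

    observed_statistic: float
    null_draws: np.ndarray
    n_iter: int

    @property
    def empirical_p(self) -> float:
        return (1 + int(np.sum(self.null_draws >= self.observed_statistic))) / (1 + self.n_iter)


def _cohort_substitution_freqs(cohort: Cohort) -> np.ndarray:
    counts = Counter()
    for m in cohort.mutations:
        if m.mutation_type == "SNV":
            label = trinucleotide_context(m, cohort.gene_models[m.gene_symbol])
            if label is not None:
                counts[label[2:5]] += 1
    freqs = np.array([counts[s] for s in SUBSTITUTION_TYPES], dtype=float)
    if freqs.sum() == 0:
        freqs = np.ones(6)
    return freqs / freqs.sum()


_PYR_ALTS = {"C": ["A", "G", "T"], "T": ["A", "C", "G"]}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _random_snv_alt(ref: str, sub_freqs: np.ndarray, rng: np.random.Generator) -> str:
    """Draw an alt base consistent with the cohort's six-type frequencies,
    conditioned on the reference base at the drawn site."""
    pyr = ref if ref in "CT" else _COMP[ref]
    idx = [i for i, s in enumerate(SUBSTITUTION_TYPES) if s[0] == pyr]
    w = sub_freqs[idx]
    w = w / w.sum() if w.sum() > 0 else np.full(3, 1 / 3)
    alt_pyr = _PYR_ALTS[pyr][int(rng.choice(3, p=w))]
    return alt_pyr if ref in "CT" else _COMP[alt_pyr]


def randomization_test_truncating(gene_symbol: str, cohort: Cohort,
                                  n_iter: int = 5000, seed: int = 0) -> RandomizationResult:
    """Is the gene's truncating fraction higher than random placement
    would produce?

    Each null draw re-places the gene's mutation set at uniform CDS
    positions (indel types and lengths preserved; SNV substitution
    types redrawn from the cohort's six-type frequencies),
    re-classifies consequences and recomputes the truncating fraction.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    g = cohort.gene_models[gene_symbol]
    muts = cohort.mutations_of_gene(gene_symbol)
    if not muts:
        raise ValueError(f"gene {gene_symbol!r} has no mutations")
    observed = sum(is_truncating(m, g) for m in muts) / len(muts)
    sub_freqs = _cohort_substitution_freqs(cohort)
    L = len(g.cds_sequence)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_iter)
    from .model import replace as _replace

    for it in range(n_iter):
        trunc = 0
        for m in muts:
            if m.mutation_type == "SNV":
                pos = int(rng.integers(1, L + 1))
                ref = g.cds_sequence[pos - 1]
                alt = _random_snv_alt(ref, sub_freqs, rng)
                mm = _replace(m, cds_pos=pos, ref_base=ref, alt_base=alt,
                              consequence_override=None)
            elif m.mutation_type == "INS":
                pos = int(rng.integers(1, L + 1))
                mm = _replace(m, cds_pos=pos, consequence_override=None)
            else:
                pos = int(rng.integers(1, L - m.del_length + 2))
                mm = _replace(m, cds_pos=pos, consequence_override=None)
            trunc += is_truncating(mm, g)
        draws[it] = trunc / len(muts)
    return RandomizationResult(observed, draws, n_iter)
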