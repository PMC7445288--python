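"""Expression-program scoring and threshold classifiers.

Covers: the NRF2 (KEAP1/NFE2L2) pathway activation score — the sum of
per-gene expression z-scores over a 27-gene target signature, with
NRF2+ called at score > 15 — its mutation-enrichment scan, the
splice-variant filter, MSI classification, and the TCR-diversity
group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import AnalysisConfig, Cohort
from .stats import (
    bh_fdr,
    fisher_exact_2x2,
    mann_whitney_u,
    shannon_entropy,
)


@dataclass
class Nrf2Result:
    """Pathway-activation scores and classes for one expression matrix."""

    scores: pd.Series  # per sample, sum of z-scores over present signature genes
    classes: pd.Series  # bool, NRF2+ iff score > threshold (strict)
    threshold: float
    present_genes: list[str]
    missing_genes: list[str]
    zero_variance_genes: list[str]


def nrf2_score(expression: pd.DataFrame, signature_genes: Sequence[str],
               threshold: float = 15.0) -> Nrf2Result:
    """Per-gene z-score across samples, summed over the signature.

    Zero-variance genes contribute 0 and are flagged; classification
    is strict (score exactly at the threshold is NRF2-). The score is
    invariant to affine rescaling of any gene's expression row.
    """
    if expression.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    present = [g for g in signature_genes if g in expression.index]
    missing = [g for g in signature_genes if g not in expression.index]
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    sub = expression.loc[present].astype(float)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    zero_var = sd[sd == 0].index.tolist()
    z = sub.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    scores = z.sum(axis=0)
    scores.name = "nrf2_score"
    return Nrf2Result(
        scores=scores,
        classes=scores > threshold,
        threshold=threshold,
        present_genes=present,
        missing_genes=missing,
        zero_variance_genes=zero_var,
    )


def nrf2_enrichment(classes: pd.Series, cohort: Cohort,
                    candidate_genes: Sequence[str]) -> pd.DataFrame:
    """Per-gene 2x2 Fisher test of mutation status against NRF2 class.

    Rows: a = mutated & NRF2+, b = mutated & NRF2-, c = unmutated &
    NRF2+, d = unmutated & NRF2-. q by BH over the candidate list;
    sorted by p. Genes never mutated keep a p = 1 row.
    """
    from .stats import _protein_altering  # shared protein-altering rule

    n_pos = int(classes.sum())
    if n_pos < 2 or (len(classes) - n_pos) < 2:
        raise ValueError("need >= 2 samples in each NRF2 class")
    classified = set(classes.index)
    mutated: dict[str, set[str]] = {g: set() for g in candidate_genes}
    for m in cohort.mutations:
        if m.gene_symbol in mutated and m.sample_id in classified:
            gm = cohort.gene_models.get(m.gene_symbol)
            if gm is None or _protein_altering(m, gm):
                mutated[m.gene_symbol].add(m.sample_id)
    rows = []
    for g in candidate_genes:
        a = sum(1 for s in mutated[g] if classes[s])
        b = len(mutated[g]) - a
        c = n_pos - a
        d = (len(classes) - n_pos) - b
        res = fisher_exact_2x2(a, b, c, d)
        rows.append({"gene": g, "mut_pos": a, "mut_neg": b, "wt_pos": c, "wt_neg": d,
                     "odds_ratio": res.odds_ratio, "p": res.p_two_sided})
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].tolist())
    return df.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)


@dataclass
class SpliceVariantRecord:
    """One candidate splice variant with per-tumor-sample support and
    a normal-panel zero fraction."""

    variant_id: str
    gene: str
    fpkm: dict[str, float]
    psi: dict[str, Optional[float]]
    psi_denominator: dict[str, int]
    panel_zero_fraction: float
    event_flags: frozenset[str] = frozenset()  # subset of {alt_start, alt_end, retained_intron}


def _effective_psi(rec: SpliceVariantRecord, sample: str, min_denominator: int
                   ) -> Optional[float]:
    # PSI estimates from too few informative reads are set to missing first
    if rec.psi_denominator.get(sample, 0) < min_denominator:
        return None
    return rec.psi.get(sample)


def filter_splice_variants(records: Sequence[SpliceVariantRecord],
                           config: Optional[AnalysisConfig] = None
                           ) -> list[SpliceVariantRecord]:
    """Tumor-specific splice-variant filter.

    Keep a record iff some tumor sample has FPKM > 2 and non-missing
    PSI > 0.1, the normal panel is FPKM-zero in > 99.8% of samples,
    and the event is none of alternative start / alternative end /
    retained intron. Idempotent and order-independent.
    """
    cfg = config or AnalysisConfig()
    kept = []
    for rec in records:
        if rec.event_flags:
            continue
        if not rec.panel_zero_fraction > cfg.panel_zero_fraction:
            continue
        for sample, fpkm in rec.fpkm.items():
            psi = _effective_psi(rec, sample, cfg.psi_min_denominator)
            if fpkm > cfg.fpkm_min and psi is not None and psi > cfg.psi_min:
                kept.append(rec)
                break
    return kept


def read_splice_tsv(path) -> list[SpliceVariantRecord]:
    """Splice records TSV: one row per (variant, sample) with columns
    variant_id, gene, sample_id, fpkm, psi, psi_denominator,
    panel_zero_fraction, event_flags (comma-separated, may be empty)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"variant_id": str, "gene": str, "sample_id": str})
    out: dict[str, SpliceVariantRecord] = {}
    for r in df.itertuples():
        vid = r.variant_id
        if vid not in out:
            flags = frozenset(f for f in str(r.event_flags).split(",") if f)
            out[vid] = SpliceVariantRecord(vid, r.gene, {}, {}, {},
                                           float(r.panel_zero_fraction), flags)
        rec = out[vid]
        rec.fpkm[r.sample_id] = float(r.fpkm)
        rec.psi[r.sample_id] = float(r.psi) if str(r.psi) != "" else None
        rec.psi_denominator[r.sample_id] = int(r.psi_denominator)
    return list(out.values())


@dataclass(frozen=True)
class MsiRecord:
    sample_id: str
    mantis_score: float
    msi: bool  # score strictly above the threshold


def classify_msi(scores: Mapping[str, float], threshold: float = 0.35) -> list[MsiRecord]:
    """Flag microsatellite instability at score > threshold (strict)."""
    out = []
    for sid in sorted(scores):
        v = float(scores[sid])
        if v < 0:
            raise ValueError(f"negative MSI score {v} for sample {sid}")
        out.append(MsiRecord(sid, v, v > threshold))
    return out


def compare_entropy_groups(
    clonotypes: Mapping[str, Mapping[str, int]],
    group_assignment: Mapping[str, str],
) -> tuple[pd.Series, float]:
    """Shannon index per sample, then a two-sided Mann-Whitney test
    between the two groups; each group needs >= 2 samples."""
    groups: dict[str, list[float]] = {}
    entropies = {}
    for sid, counts in clonotypes.items():
        if sid not in group_assignment:
            continue
        h = shannon_entropy(list(counts.values()))
        entropies[sid] = h
        groups.setdefault(group_assignment[sid], []).append(h)
    if len(groups) != 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need two groups with >= 2 samples each")
    ga, gb = sorted(groups)
    p = mann_whitney_u(groups[ga], groups[gb])
    return pd.Series(entropies, name="shannon_nats"), p
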