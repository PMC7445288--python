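"""Domain types and validation for the cohort analysis pipeline.

Coordinates are CDS-based, 1-based and closed: codon ``i`` spans CDS
positions ``3i-2 .. 3i`` on the coding strand. Insertions are anchored
AFTER ``cds_pos`` (VCF-style left anchoring); deletions are inclusive
ranges ``cds_pos .. cds_pos + del_length - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd
import yaml

NUCLEOTIDES = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

IMPACT_LABELS = frozenset({"deleterious", "benign", "missing"})
MUTATION_TYPES = frozenset({"SNV", "INS", "DEL"})


@dataclass(frozen=True)
class GeneModel:
    """A coding sequence on the coding strand, with optional edge flanks.

    The CDS must start with ATG, end with a stop codon, have length a
    multiple of 3 (>= 6) and contain no internal stop. ``flank5`` and
    ``flank3`` provide trinucleotide context for substitutions at the
    first/last CDS base.
    """

    gene_symbol: str
    cds_sequence: str
    flank5: str = ""
    flank3: str = ""

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3

    def codon(self, i: int) -> str:
        """1-based codon accessor."""
        return self.cds_sequence[3 * (i - 1) : 3 * i]


@dataclass(frozen=True)
class SomaticMutation:
    """One somatic event in CDS coordinates.

    ``impact_labels`` is the optional triple of functional-impact calls
    from three external predictors, each one of
    {deleterious, benign, missing}. ``consequence_override`` lets
    events that cannot be represented in a CDS-only model (essential
    splice sites) enter truncating statistics.
    """

    mutation_id: str
    sample_id: str
    gene_symbol: str
    cds_pos: int
    mutation_type: str  # SNV | INS | DEL
    population: str
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    inserted_seq: Optional[str] = None
    del_length: Optional[int] = None
    expressed_read_count: int = 0
    impact_labels: Optional[tuple[str, str, str]] = None
    consequence_override: Optional[str] = None


@dataclass
class Cohort:
    """A validated multi-population cohort.

    ``samples`` fixes sample order for all downstream matrices.
    Optional slots carry expression (genes x samples DataFrame), HLA
    genotypes (one entry per allele copy), clonotype count tables and
    MSI scores.
    """

    samples: list[tuple[str, str]]
    mutations: list[SomaticMutation]
    gene_models: dict[str, GeneModel]
    expression: Optional[pd.DataFrame] = None
    hla: Optional[dict[str, list[str]]] = None
    clonotypes: Optional[dict[str, dict[str, int]]] = None
    msi_scores: Optional[dict[str, float]] = None

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    @property
    def populations(self) -> dict[str, str]:
        return dict(self.samples)

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.samples if p == population]

    def mutations_of_gene(self, gene_symbol: str) -> list[SomaticMutation]:
        return [m for m in self.mutations if m.gene_symbol == gene_symbol]


@dataclass(frozen=True)
class AnalysisConfig:
    """All numeric cut-offs used downstream, with their comparison sense.

    binder_threshold_nM is inclusive (<=); nrf2_threshold, msi_threshold,
    fpkm_min, psi_min and panel_zero_fraction are strict (>).
    """

    binder_threshold_nM: float = 500.0
    nrf2_threshold: float = 15.0
    msi_threshold: float = 0.35
    hotspot_min_samples: int = 2
    fpkm_min: float = 2.0
    psi_min: float = 0.1
    panel_zero_fraction: float = 0.998
    psi_min_denominator: int = 10
    qscore_min: float = 1.0
    expression_min_reads: int = 1
    n_sim: int = 5000
    peptide_kmin: int = 8
    peptide_kmax: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "binder_threshold_nM", "nrf2_threshold", "msi_threshold",
            "hotspot_min_samples", "fpkm_min", "psi_min",
            "panel_zero_fraction", "psi_min_denominator", "qscore_min",
            "n_sim", "peptide_kmin", "peptide_kmax",
        ):
            v = getattr(self, name)
            if not (v > 0 and v == v and abs(v) != float("inf")):
                raise ValueError(f"AnalysisConfig.{name} must be finite and positive, got {v!r}")
        if self.peptide_kmin > self.peptide_kmax:
            raise ValueError("peptide_kmin must be <= peptide_kmax")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown AnalysisConfig keys: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("analysis", data))


@dataclass(frozen=True)
class Violation:
    """One invariant failure found by :func:`validate_cohort`."""

    entity: str
    invariant: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity}: {self.invariant}: {self.message}"


def validate_gene_model(g: GeneModel) -> list[Violation]:
    out: list[Violation] = []
    ent = f"gene:{g.gene_symbol}"
    bad = set(g.cds_sequence) - NUCLEOTIDES
    if bad:
        out.append(Violation(ent, "alphabet", f"non-ACGT characters {sorted(bad)}"))
        return out
    for name, fl in (("flank5", g.flank5), ("flank3", g.flank3)):
        if set(fl) - NUCLEOTIDES:
            out.append(Violation(ent, "alphabet", f"non-ACGT characters in {name}"))
    n = len(g.cds_sequence)
    if n < 6 or n % 3:
        out.append(Violation(ent, "cds_length", f"length {n} not a multiple of 3 >= 6"))
        return out
    if not g.cds_sequence.startswith("ATG"):
        out.append(Violation(ent, "start_codon", "CDS does not begin with ATG"))
    if g.cds_sequence[-3:] not in STOP_CODONS:
        out.append(Violation(ent, "stop_codon", "CDS does not end with a stop codon"))
    internal = [
        i for i in range(1, n // 3)  # codons 1..n-1 (0-based), excluding terminal
        if g.cds_sequence[3 * (i - 1) : 3 * i] in STOP_CODONS
    ]
    if internal:
        out.append(Violation(ent, "internal_stop", f"stop codon at codon(s) {internal}"))
    return out


def validate_mutation(m: SomaticMutation, g: Optional[GeneModel]) -> list[Violation]:
    out: list[Violation] = []
    ent = f"mutation:{m.mutation_id}"
    if m.mutation_type not in MUTATION_TYPES:
        out.append(Violation(ent, "mutation_type", f"unknown type {m.mutation_type!r}"))
        return out
    if m.expressed_read_count < 0:
        out.append(Violation(ent, "expressed_read_count", "negative read count"))
    if m.impact_labels is not None:
        if len(m.impact_labels) != 3 or set(m.impact_labels) - IMPACT_LABELS:
            out.append(Violation(ent, "impact_labels", f"bad impact triple {m.impact_labels!r}"))
    if g is None:
        out.append(Violation(ent, "gene_registered", f"unknown gene {m.gene_symbol!r}"))
        return out
    L = len(g.cds_sequence)
    if not (1 <= m.cds_pos <= L):
        out.append(Violation(ent, "cds_pos_bounds", f"cds_pos {m.cds_pos} outside 1..{L}"))
        return out
    if m.mutation_type == "SNV":
        if m.ref_base not in NUCLEOTIDES or m.alt_base not in NUCLEOTIDES:
            out.append(Violation(ent, "snv_alleles", "ref/alt must be single ACGT bases"))
        elif len(m.ref_base) != 1 or len(m.alt_base) != 1:
            out.append(Violation(ent, "snv_alleles", "multi-nucleotide substitutions unsupported"))
        elif m.ref_base == m.alt_base:
            out.append(Violation(ent, "snv_alleles", "ref equals alt"))
        elif g.cds_sequence[m.cds_pos - 1] != m.ref_base:
            out.append(Violation(
                ent, "snv_ref_match",
                f"ref_base {m.ref_base} != CDS base {g.cds_sequence[m.cds_pos - 1]} "
                f"at position {m.cds_pos} of {m.gene_symbol}",
            ))
    elif m.mutation_type == "INS":
        if not m.inserted_seq or set(m.inserted_seq) - NUCLEOTIDES:
            out.append(Violation(ent, "ins_seq", "inserted_seq must be non-empty ACGT"))
    elif m.mutation_type == "DEL":
        if not m.del_length or m.del_length < 1:
            out.append(Violation(ent, "del_length", "del_length must be a positive integer"))
        elif m.cds_pos + m.del_length - 1 > L:
            out.append(Violation(
                ent, "del_bounds",
                f"deletion {m.cds_pos}..{m.cds_pos + m.del_length - 1} runs past CDS end {L}",
            ))
    return out


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every structural invariant; violations are data, not exceptions."""
    out: list[Violation] = []
    seen: set[str] = set()
    for sid, _pop in cohort.samples:
        if sid in seen:
            out.append(Violation(f"sample:{sid}", "unique_sample_ids", "duplicate sample id"))
        seen.add(sid)
    for g in cohort.gene_models.values():
        out.extend(validate_gene_model(g))
    pops = cohort.populations
    for m in cohort.mutations:
        out.extend(validate_mutation(m, cohort.gene_models.get(m.gene_symbol)))
        if m.sample_id not in seen:
            out.append(Violation(
                f"mutation:{m.mutation_id}", "sample_registered",
                f"unknown sample {m.sample_id!r}",
            ))
        elif pops.get(m.sample_id) != m.population:
            out.append(Violation(
                f"mutation:{m.mutation_id}", "population_consistent",
                f"population {m.population!r} != sample's {pops.get(m.sample_id)!r}",
            ))
    for name, mapping in (
        ("hla", cohort.hla), ("clonotypes", cohort.clonotypes), ("msi_scores", cohort.msi_scores),
    ):
        if mapping:
            for sid in mapping:
                if sid not in seen:
                    out.append(Violation(f"{name}:{sid}", "sample_registered", "unknown sample"))
    if cohort.expression is not None:
        if cohort.expression.isna().any().any():
            out.append(Violation("expression", "no_missing_values", "NaN in expression matrix"))
        if cohort.expression.index.duplicated().any():
            out.append(Violation("expression", "unique_gene_names", "duplicate gene rows"))
    return out


__all__ = [
    "GeneModel", "SomaticMutation", "Cohort", "AnalysisConfig", "Violation",
    "validate_gene_model", "validate_mutation", "validate_cohort",
    "NUCLEOTIDES", "STOP_CODONS", "replace", "field",
]
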