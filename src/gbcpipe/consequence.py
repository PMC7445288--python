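"""CDS translation, consequence classification, mutant proteins and
trinucleotide-context spectra.

A mutation's consequence is found by applying the edit to the CDS and
retranslating from the start codon. Frameshift translation continues in
the shifted frame until the first stop; it never reads past the CDS end
into invented sequence (``no_stop_reached`` is flagged instead).
Substitution contexts use the pyrimidine-strand convention: purine
references are reverse-complemented together with their flanks, giving
the standard 96 classes (6 substitution types x 16 flank pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .model import Cohort, GeneModel, SomaticMutation, STOP_CODONS

_CODON_TABLE = dict(standard_dna_table.forward_table)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTION_TYPES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
CONTEXT_CLASSES = [
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTION_TYPES
    for f5 in "ACGT"
    for f3 in "ACGT"
]


class Consequence(str, Enum):
    synonymous = "synonymous"
    missense = "missense"
    nonsense = "nonsense"
    stop_lost = "stop_lost"
    start_lost = "start_lost"
    frameshift = "frameshift"
    inframe_indel = "inframe_indel"


TRUNCATING_CONSEQUENCES = {Consequence.frameshift, Consequence.nonsense}
SPLICE_OVERRIDES = {"splice", "essential_splice", "essential_splice_site"}


@dataclass(frozen=True)
class MutantProtein:
    """A retranslated mutant protein.

    ``novel_span`` is the 1-based closed interval of residues differing
    from wild type (``None`` when the protein is unchanged). For
    frameshifts it runs from the first shifted residue to the new
    C-terminus. ``truncated`` means shorter than wild type;
    ``no_stop_reached`` means translation ran off the available
    sequence without meeting a stop codon.
    """

    sequence: str
    novel_span: Optional[tuple[int, int]]
    truncated: bool
    no_stop_reached: bool
    start_lost: bool = False


def translate_with_flags(cds: str) -> tuple[str, bool]:
    """Translate to the first stop codon; returns (protein, stop_reached)."""
    bad = set(cds) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in CDS: {sorted(bad)}")
    aa = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            return "".join(aa), True
        aa.append(_CODON_TABLE[codon])
    return "".join(aa), False


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    Stops at (and excludes) the first stop codon; with no stop, the
    last complete codon ends the protein.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    return translate_with_flags(cds)[0]


def apply_edit(m: SomaticMutation, g: GeneModel) -> str:
    """Return the mutant CDS string for any mutation type."""
    s = g.cds_sequence
    i = m.cds_pos - 1
    if m.mutation_type == "SNV":
        return s[:i] + m.alt_base + s[i + 1 :]
    if m.mutation_type == "INS":
        return s[: i + 1] + m.inserted_seq + s[i + 1 :]
    if m.mutation_type == "DEL":
        return s[:i] + s[i + m.del_length :]
    raise ValueError(f"unknown mutation type {m.mutation_type!r}")


def classify_consequence(m: SomaticMutation, g: GeneModel) -> Consequence:
    mutant = apply_edit(m, g)
    if mutant[:3] != "ATG":
        return Consequence.start_lost
    if m.mutation_type in ("INS", "DEL"):
        length = len(m.inserted_seq) if m.mutation_type == "INS" else m.del_length
        return Consequence.frameshift if length % 3 else Consequence.inframe_indel
    codon_idx = (m.cds_pos - 1) // 3
    wt_codon = g.cds_sequence[3 * codon_idx : 3 * codon_idx + 3]
    mut_codon = mutant[3 * codon_idx : 3 * codon_idx + 3]
    wt_stop, mut_stop = wt_codon in STOP_CODONS, mut_codon in STOP_CODONS
    if wt_stop and mut_stop:
        return Consequence.synonymous
    if wt_stop:
        return Consequence.stop_lost
    if mut_stop:
        return Consequence.nonsense
    if _CODON_TABLE[wt_codon] == _CODON_TABLE[mut_codon]:
        return Consequence.synonymous
    return Consequence.missense


def is_truncating(m: SomaticMutation, g: GeneModel) -> bool:
    """Frameshift, nonsense, or an essential-splice override."""
    if m.consequence_override and m.consequence_override.lower() in SPLICE_OVERRIDES:
        return True
    return classify_consequence(m, g) in TRUNCATING_CONSEQUENCES


def build_mutant_protein(m: SomaticMutation, g: GeneModel) -> MutantProtein:
    """Apply the edit, retranslate, and locate the novel residue span.

    Stop-lost proteins extend only through any provided 3' flank;
    start-loss yields an empty sequence with a flag rather than an
    exception.
    """
    wt, _ = translate_with_flags(g.cds_sequence)
    mutant_cds = apply_edit(m, g)
    if mutant_cds[:3] != "ATG":
        return MutantProtein("", None, True, False, start_lost=True)
    mut, stopped = translate_with_flags(mutant_cds)
    if not stopped and g.flank3:
        # read on through the provided flank, complete codons only
        mut, stopped = translate_with_flags(mutant_cds + g.flank3)
    consequence = classify_consequence(m, g)
    # first differing residue
    first = None
    for i in range(min(len(wt), len(mut))):
        if wt[i] != mut[i]:
            first = i + 1
            break
    if first is None and len(mut) != len(wt):
        first = min(len(wt), len(mut)) + 1
    if first is None or first > len(mut):
        # unchanged protein, or a pure truncation sharing its whole prefix
        span = None
    elif consequence in (Consequence.frameshift, Consequence.stop_lost):
        span = (first, len(mut))
    else:
        # trim the longest common suffix, keeping the span well-formed
        k = 0
        while (
            k < len(mut) - first + 1
            and k < len(wt) - first + 1
            and mut[len(mut) - 1 - k] == wt[len(wt) - 1 - k]
        ):
            k += 1
        last = len(mut) - k
        span = (first, last) if last >= first else None
    return MutantProtein(
        sequence=mut,
        novel_span=span,
        truncated=len(mut) < len(wt),
        no_stop_reached=not stopped,
    )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def trinucleotide_context(m: SomaticMutation, g: GeneModel) -> Optional[str]:
    """96-class context label for an SNV, or ``None`` when unresolvable.

    The 5'/3' bases come from the CDS or, at its edges, from the gene's
    flanks; with a purine reference the whole triplet is
    reverse-complemented to the pyrimidine strand.
    """
    if m.mutation_type != "SNV":
        raise ValueError("context is defined for SNVs only")
    s, pos = g.cds_sequence, m.cds_pos
    five = s[pos - 2] if pos >= 2 else (g.flank5[-1] if g.flank5 else None)
    three = s[pos] if pos < len(s) else (g.flank3[0] if g.flank3 else None)
    if five is None or three is None:
        return None
    ref, alt = m.ref_base, m.alt_base
    if ref in "AG":
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
        five, three = three.translate(_COMPLEMENT), five.translate(_COMPLEMENT)
    return f"{five}[{ref}>{alt}]{three}"


@dataclass
class SpectrumMatrix:
    """Samples x 96 context-class counts, plus the SNVs left out for
    lack of flanking context."""

    counts: pd.DataFrame  # index: sample_id, columns: CONTEXT_CLASSES
    excluded: list[str]  # mutation_ids with unresolvable context

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")


def build_spectrum(cohort: Cohort) -> SpectrumMatrix:
    sample_ids = cohort.sample_ids
    counts = pd.DataFrame(
        np.zeros((len(sample_ids), 96), dtype=int),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=CONTEXT_CLASSES,
    )
    excluded: list[str] = []
    for m in cohort.mutations:
        if m.mutation_type != "SNV":
            continue
        label = trinucleotide_context(m, cohort.gene_models[m.gene_symbol])
        if label is None:
            excluded.append(m.mutation_id)
        else:
            counts.loc[m.sample_id, label] += 1
    return SpectrumMatrix(counts=counts, excluded=excluded)


def deleterious_consensus(labels: Optional[tuple[str, str, str]]) -> bool:
    """2-of-3 consensus: deleterious iff at least two predictors say so.

    'missing' never counts toward either side; an absent triple is
    not deleterious.
    """
    if labels is None:
        return False
    return sum(1 for x in labels if x == "deleterious") >= 2


__all__ = [
    "Consequence", "MutantProtein", "SpectrumMatrix",
    "CONTEXT_CLASSES", "SUBSTITUTION_TYPES",
    "translate_cds", "translate_with_flags", "apply_edit",
    "classify_consequence", "is_truncating", "build_mutant_protein",
    "trinucleotide_context", "build_spectrum", "deleterious_consensus",
    "reverse_complement",
]
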