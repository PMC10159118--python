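"""Coding-region GC content, codon-GC amino-acid classes, proteome amino-acid frequencies.

The coding GC content of a genome G is the pooled fraction

    GC_G = sum_g GC(g) / sum_g |g|

over its protein-coding genes g, with GC(g) the G+C count of the CDS and
|g| its length; N bases are excluded from both numerator and denominator.

Amino acids are classified by the unweighted mean GC fraction of their
synonymous codons (stop codons belong to no amino acid): high if the
mean exceeds 1/2, neutral if it equals 1/2 exactly, low otherwise.
Under the standard genetic code this yields the fixed 5/8/7 partition
high = {A,G,P,R,W}, neutral = {C,D,E,H,Q,S,T,V}, low = {F,I,K,L,M,N,Y}.

Proteome amino-acid frequencies pool residue counts across proteins:
aa_G = sum_p |p(aa)| / |P(G)|, with X residues excluded throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .io import STANDARD_AA, CodingGene, ProteinRecord

GCClass = Literal["high", "neutral", "low"]
Context = Literal["proteome", "helix", "sheet", "coil"]

#: Comparison tolerance for the neutral boundary; all standard-code means
#: are exact multiples of 1/12 or 1/18, so the boundary is crisp.
NEUTRAL_TOL = 1e-9


class EmptyInputError(ValueError):
    """No usable sequence content for a composition statistic."""


@dataclass(frozen=True)
class CodonClassTable:
    """Per-amino-acid mean synonymous-codon GC and high/neutral/low class."""

    mean_codon_gc: Mapping[str, float]
    gc_class: Mapping[str, GCClass]
    codons: Mapping[str, tuple[str, ...]]

    def members(self, cls: GCClass) -> frozenset[str]:
        return frozenset(a for a, c in self.gc_class.items() if c == cls)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "amino_acid": aa,
                "n_codons": len(self.codons[aa]),
                "mean_codon_gc": self.mean_codon_gc[aa],
                "gc_class": self.gc_class[aa],
                "codons": ",".join(self.codons[aa]),
            }
            for aa in sorted(self.mean_codon_gc)
        ]
        return pd.DataFrame(rows).set_index("amino_acid")


@dataclass(frozen=True)
class AAFrequencyTable:
    """Relative amino-acid frequencies with their residue counts."""

    frequency: Mapping[str, float]
    count: Mapping[str, int]
    context: Context
    total: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            {aa: self.frequency[aa] for aa in STANDARD_AA}, name=self.context
        )


def compute_coding_gc(genes: Sequence[CodingGene]) -> float:
    """Pooled G+C fraction over all coding genes, N bases excluded."""
    if not genes:
        raise EmptyInputError("no coding genes supplied")
    gc = 0
    total = 0
    for g in genes:
        counts = Counter(g.sequence)
        gc += counts["G"] + counts["C"]
        total += counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if total == 0:
        raise EmptyInputError("all-N input: no A/C/G/T bases to count")
    return gc / total


def classify_amino_acids(table_id: int = 11) -> CodonClassTable:
    """Classify the 20 standard amino acids by mean synonymous-codon GC.

    The mean is unweighted over the amino acid's codons in the given NCBI
    translation table (default 11, the bacterial/archaeal code, whose
    sense-codon assignments match the standard code); stop codons are
    excluded from every codon list.
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codons_by_aa: dict[str, list[str]] = {aa: [] for aa in STANDARD_AA}
    for codon, aa in table.forward_table.items():
        if aa in codons_by_aa:
            codons_by_aa[aa].append(codon)
    mean_gc: dict[str, float] = {}
    cls: dict[str, GCClass] = {}
    for aa, codons in codons_by_aa.items():
        if not codons:
            raise ValueError(f"translation table {table_id} encodes no codon for {aa}")
        # exact rational mean, then compared against 1/2 within NEUTRAL_TOL
        m = Fraction(
            sum(c.count("G") + c.count("C") for c in codons), 3 * len(codons)
        )
        mean_gc[aa] = float(m)
        if m > Fraction(1, 2) + Fraction(1, 10**9):
            cls[aa] = "high"
        elif m < Fraction(1, 2) - Fraction(1, 10**9):
            cls[aa] = "low"
        else:
            cls[aa] = "neutral"
    return CodonClassTable(
        mean_codon_gc=mean_gc,
        gc_class=cls,
        codons={aa: tuple(sorted(c)) for aa, c in codons_by_aa.items()},
    )


def aa_frequencies(
    proteins: Sequence[ProteinRecord], context: Context = "proteome"
) -> AAFrequencyTable:
    """Pooled relative frequency of each standard amino acid, X excluded."""
    if not proteins:
        raise EmptyInputError("empty proteome")
    counts: Counter[str] = Counter()
    for p in proteins:
        counts.update(p.sequence)
    counts.pop("X", None)
    total = sum(counts.values())
    if total == 0:
        raise EmptyInputError("no standard residues in proteome")
    return AAFrequencyTable(
        frequency={aa: counts.get(aa, 0) / total for aa in STANDARD_AA},
        count={aa: counts.get(aa, 0) for aa in STANDARD_AA},
        context=context,
        total=total,
    )


def composition_table(
    organisms: Mapping[str, tuple[Sequence[CodingGene], Sequence[ProteinRecord]]]
) -> pd.DataFrame:
    """Per-organism row of coding GC plus the 20 amino-acid frequencies."""
    rows = []
    for org_id, (genes, proteins) in organisms.items():
        row: dict[str, object] = {"organism_id": org_id}
        row["coding_gc"] = compute_coding_gc(genes)
        freqs = aa_frequencies(proteins)
        for aa in STANDARD_AA:
            row[aa] = freqs.frequency[aa]
        rows.append(row)
    return pd.DataFrame(rows).set_index("organism_id")
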