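"""File formats and the canonical in-memory sequence/annotation model.

Three FASTA dialects are read and written: nucleotide coding sequences
(one record per protein-coding gene), amino-acid protein sequences, and
per-residue three-state secondary-structure strings over the alphabet
{H, E, C} (helix, sheet, coil).  Secondary-structure annotations arrive
as a FASTA-like file with the same IDs and lengths as the protein FASTA;
any state letter other than H or E is remapped to C on import, following
the three-state convention, and the number of remapped characters is
logged.

COG (Cluster of Orthologous Genes) membership is consumed as a 5-column
TSV produced upstream (e.g. by HMM domain scanning); coordinates are
1-based inclusive residue indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
#: 20 standard one-letter amino-acid codes; X marks an unknown residue.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(STANDARD_AA + "X")
SS_STATES = "HEC"
SS_ALPHABET = frozenset(SS_STATES)

Alphabet = Literal["nucleotide", "protein", "ss"]


class FastaError(ValueError):
    """Malformed or invalid FASTA input."""


class CogTableError(ValueError):
    """Malformed or invalid COG membership table."""


@dataclass(frozen=True)
class CodingGene:
    """One protein-coding gene as pre-extracted CDS (sense strand, 5'->3')."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaError(f"gene {self.gene_id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an optional aligned H/E/C annotation."""

    protein_id: str
    sequence: str
    ss_string: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaError(f"protein {self.protein_id!r}: empty sequence")
        if self.ss_string is not None and len(self.ss_string) != len(self.sequence):
            raise FastaError(
                f"protein {self.protein_id!r}: secondary-structure string length "
                f"{len(self.ss_string)} != sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SSRecord:
    """A raw three-state secondary-structure string keyed by protein ID."""

    protein_id: str
    ss_string: str


@dataclass(frozen=True)
class COGMembership:
    """One protein's assignment to a COG with its domain span (1-based inclusive)."""

    protein_id: str
    cog_id: str
    domain_start: int
    domain_end: int
    organism_id: str

    def __post_init__(self) -> None:
        if not (1 <= self.domain_start <= self.domain_end):
            raise CogTableError(
                f"{self.protein_id}/{self.cog_id}: invalid domain span "
                f"[{self.domain_start}, {self.domain_end}]"
            )

    @property
    def domain_length(self) -> int:
        return self.domain_end - self.domain_start + 1


@dataclass
class GenomeRecord:
    """One organism: its coding genes, proteins and optional annotations.

    When a gene and a protein share an ID, the translated gene length
    (codons minus the stop) should equal the protein length; mismatches
    are recorded as warnings rather than errors, since real annotation
    pipelines disagree at a low rate.
    """

    organism_id: str
    genes: list[CodingGene] = field(default_factory=list)
    proteins: list[ProteinRecord] = field(default_factory=list)
    taxon_label: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for kind, ids in (
            ("gene", [g.gene_id for g in self.genes]),
            ("protein", [p.protein_id for p in self.proteins]),
        ):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FastaError(f"{self.organism_id}: duplicate {kind} ID {i!r}")
                seen.add(i)
        self._check_lengths()

    def _check_lengths(self) -> None:
        genes_by_id = {g.gene_id: g for g in self.genes}
        for p in self.proteins:
            g = genes_by_id.get(p.protein_id)
            if g is None:
                continue
            expected = g.length // 3 - 1  # codons minus stop
            if expected != len(p):
                msg = (
                    f"{self.organism_id}/{p.protein_id}: gene of {g.length} nt "
                    f"implies {expected} aa, protein has {len(p)}"
                )
                self.warnings.append(msg)
                logger.warning(msg)

    @property
    def annotated_proteins(self) -> list[ProteinRecord]:
        return [p for p in self.proteins if p.ss_string is not None]


def _validate(seq: str, allowed: frozenset[str], rec_id: str, kind: str) -> None:
    bad = set(seq) - allowed
    if bad:
        raise FastaError(
            f"record {rec_id!r}: illegal {kind} character(s) {sorted(bad)!r}"
        )


def read_fasta(
    path: str | Path, alphabet: Alphabet
) -> list[CodingGene] | list[ProteinRecord] | list[SSRecord]:
    """Read a FASTA file as genes, proteins or H/E/C annotations.

    Case is normalised to upper.  Characters outside the alphabet raise
    :class:`FastaError`, except that in the ``ss`` dialect any letter
    other than H or E is remapped to C (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FastaError(f"{path}: duplicate record ID(s) {dupes!r}")

    out: list = []
    remapped = 0
    for rec in records:
        seq = str(rec.seq).upper()
        if alphabet == "nucleotide":
            _validate(seq, NUCLEOTIDE_ALPHABET, rec.id, "nucleotide")
            out.append(CodingGene(gene_id=rec.id, sequence=seq))
        elif alphabet == "protein":
            _validate(seq, PROTEIN_ALPHABET, rec.id, "amino-acid")
            out.append(ProteinRecord(protein_id=rec.id, sequence=seq))
        elif alphabet == "ss":
            if not seq:
                raise FastaError(f"record {rec.id!r}: empty annotation")
            if not seq.isalpha():
                raise FastaError(f"record {rec.id!r}: non-letter in annotation")
            mapped = "".join(c if c in "HE" else "C" for c in seq)
            remapped += sum(1 for a, b in zip(seq, mapped) if a != b and a != "C")
            out.append(SSRecord(protein_id=rec.id, ss_string=mapped))
        else:
            raise ValueError(f"unknown alphabet {alphabet!r}")
    if remapped:
        logger.info("%s: remapped %d non-H/E state letters to C", path, remapped)
    return out


def write_fasta(
    records: Iterable[CodingGene | ProteinRecord | SSRecord],
    path: str | Path,
    *,
    what: Literal["sequence", "ss"] = "sequence",
    width: int = 60,
) -> None:
    """Write records back to FASTA; round-trips IDs and sequences exactly."""
    seqrecs = []
    for r in records:
        if what == "ss":
            if isinstance(r, SSRecord):
                seq = r.ss_string
            elif isinstance(r, ProteinRecord) and r.ss_string is not None:
                seq = r.ss_string
            else:
                raise ValueError(f"record {r!r} carries no secondary structure")
            rid = r.protein_id
        else:
            seq = r.sequence
            rid = r.gene_id if isinstance(r, CodingGene) else r.protein_id
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def attach_ss(
    proteins: Sequence[ProteinRecord], ss_records: Sequence[SSRecord]
) -> tuple[list[ProteinRecord], list[str]]:
    """Attach H/E/C annotations to proteins by ID.

    Returns ``(attached, unannotated_ids)``.  Proteins lacking an
    annotation are returned unchanged but flagged in the second element
    (downstream structure statistics exclude them).  A length mismatch
    or an annotation for an unknown protein ID is an error.  Idempotent:
    re-attaching an identical annotation changes nothing.
    """
    by_id = {p.protein_id: p for p in proteins}
    unknown = [s.protein_id for s in ss_records if s.protein_id not in by_id]
    if unknown:
        raise FastaError(f"annotations for unknown protein ID(s) {unknown!r}")
    ss_by_id = {s.protein_id: s for s in ss_records}
    out: list[ProteinRecord] = []
    missing: list[str] = []
    for p in proteins:
        s = ss_by_id.get(p.protein_id)
        if s is None:
            missing.append(p.protein_id)
            out.append(p)
            continue
        if len(s.ss_string) != len(p):
            raise FastaError(
                f"protein {p.protein_id!r}: annotation length {len(s.ss_string)} "
                f"!= sequence length {len(p)}"
            )
        out.append(replace(p, ss_string=s.ss_string))
    if missing:
        logger.info("%d protein(s) lack secondary-structure annotations", len(missing))
    return out, missing


COG_COLUMNS = ("protein_id", "cog_id", "domain_start", "domain_end", "organism_id")


def read_cog_table(
    path: str | Path,
    proteins: Sequence[ProteinRecord] | None = None,
) -> list[COGMembership]:
    """Read a COG membership TSV (header: protein_id, cog_id, domain_start,
    domain_end, organism_id).

    When ``proteins`` is given, domain coordinates are checked against
    protein lengths.  An empty table (header only) is allowed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lengths = {p.protein_id: len(p) for p in proteins} if proteins is not None else {}
    out: list[COGMembership] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != COG_COLUMNS:
            raise CogTableError(
                f"{path}: expected header {COG_COLUMNS!r}, found {tuple(header)!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise CogTableError(f"{path}:{lineno}: expected 5 columns, found {len(parts)}")
            pid, cog_id, start_s, end_s, org = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CogTableError(f"{path}:{lineno}: non-integer coordinate") from exc
            m = COGMembership(pid, cog_id, start, end, org)
            if pid in lengths and end > lengths[pid]:
                raise CogTableError(
                    f"{path}:{lineno}: domain_end {end} exceeds length "
                    f"{lengths[pid]} of protein {pid!r}"
                )
            out.append(m)
    return out


def write_cog_table(memberships: Iterable[COGMembership], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COG_COLUMNS) + "\n")
        for m in memberships:
            fh.write(
                f"{m.protein_id}\t{m.cog_id}\t{m.domain_start}\t{m.domain_end}\t{m.organism_id}\n"
            )
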