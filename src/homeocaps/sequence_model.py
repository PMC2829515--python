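"""Core sequence and individual data types shared by the whole pipeline.

A CAPS (cleaved amplified polymorphic sequence) study is built on pairs of
parental allele sequences per locus, a set of sampled individuals with known
roles (diploid maternal parent, diploid paternal parent, allopolyploid, or
synthetic F1 hybrid), and the IUPAC degenerate DNA alphabet used both for
amplicon sequences and for restriction-enzyme recognition sites.

Coordinates everywhere are 0-based, half-open; restriction cut positions are
between-base indices in ``[0, length]``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

__all__ = [
    "Role",
    "NucleotideSequence",
    "IndividualRecord",
    "LocusAlleles",
    "AlphabetError",
    "FastaParseError",
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "reverse_complement",
    "iupac_match",
    "read_fasta",
    "write_fasta",
    "read_individuals",
    "write_individuals",
]

# Degeneracy sets of the 15-letter IUPAC DNA alphabet (no U: DNA amplicons only).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

CONCRETE_BASES = frozenset("ACGT")


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside the IUPAC DNA alphabet."""


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class Role(str, enum.Enum):
    """Role of a sequence or sampled individual within the study design."""

    MATERNAL_PARENT = "maternal_parent"
    PATERNAL_PARENT = "paternal_parent"
    POLYPLOID = "polyploid"
    F1_HYBRID = "f1_hybrid"


def _validate_residues(residues: str, seq_id: str = "<anonymous>") -> str:
    """Uppercase ``residues`` and reject anything outside the IUPAC alphabet."""
    if not residues:
        raise AlphabetError(f"sequence {seq_id!r}: empty residues")
    up = residues.upper()
    for offset, ch in enumerate(up):
        if ch not in IUPAC_SETS:
            raise AlphabetError(
                f"sequence {seq_id!r}: illegal character {ch!r} at offset {offset}"
            )
    return up


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence with study-role metadata.

    Parameters
    ----------
    seq_id : str
        Identifier, unique within a dataset.
    residues : str
        Sequence over the 15-letter IUPAC DNA alphabet; canonicalized to
        uppercase on construction.
    role : Role
        Study role of the organism the sequence came from.
    species_label : str
        Free-text species name (e.g. ``"T. porrifolius"``).
    """

    seq_id: str
    residues: str
    role: Role = Role.POLYPLOID
    species_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _validate_residues(self.residues, self.seq_id))
        object.__setattr__(self, "role", Role(self.role))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_concrete(self) -> bool:
        """True when every residue is a concrete A/C/G/T base."""
        return all(ch in CONCRETE_BASES for ch in self.residues)


@dataclass(frozen=True)
class IndividualRecord:
    """A sampled plant: identifier, population of origin and study role."""

    individual_id: str
    population_id: str
    role: Role
    species_label: str = ""

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise ValueError("individual_id must be nonempty")
        if not self.population_id:
            raise ValueError(f"individual {self.individual_id!r}: population_id must be nonempty")
        object.__setattr__(self, "role", Role(self.role))


@dataclass(frozen=True)
class LocusAlleles:
    """The two parental reference sequences for one amplified locus."""

    locus_id: str
    maternal_allele: NucleotideSequence
    paternal_allele: NucleotideSequence

    def __post_init__(self) -> None:
        if self.maternal_allele.role is not Role.MATERNAL_PARENT:
            raise ValueError(f"locus {self.locus_id!r}: maternal allele must have role maternal_parent")
        if self.paternal_allele.role is not Role.PATERNAL_PARENT:
            raise ValueError(f"locus {self.locus_id!r}: paternal allele must have role paternal_parent")


def reverse_complement(s: str) -> str:
    """Reverse complement of an IUPAC DNA string.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    up = _validate_residues(s) if s else s
    if not s:
        raise AlphabetError("empty sequence")
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(up))


def iupac_match(pattern_char: str, base: str) -> bool:
    """True iff concrete ``base`` is in the degeneracy set of ``pattern_char``."""
    try:
        degeneracy = IUPAC_SETS[pattern_char.upper()]
    except KeyError:
        raise AlphabetError(f"illegal IUPAC pattern character {pattern_char!r}") from None
    b = base.upper()
    if b not in CONCRETE_BASES:
        raise AlphabetError(f"sequence base must be concrete A/C/G/T, got {base!r}")
    return b in degeneracy


def _parse_description_tokens(description: str) -> dict[str, str]:
    """Extract ``key=value`` tokens from a FASTA description; unknown tokens ignored."""
    tokens: dict[str, str] = {}
    for tok in description.split():
        if "=" in tok:
            key, _, value = tok.partition("=")
            tokens[key] = value
    return tokens


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA into :class:`NucleotideSequence` objects.

    Role and species metadata are carried in the description line as
    ``role=... species=...`` tokens; records without a ``role`` token default
    to ``polyploid``. Residues are uppercased; record order is preserved.

    Raises
    ------
    FastaParseError
        On malformed FASTA (including duplicate ids).
    AlphabetError
        On residues outside the IUPAC alphabet (names the record and offset).
    """
    path = Path(path)
    records: list[NucleotideSequence] = []
    seen: set[str] = set()
    with open(path) as handle:
        # Reject leading junk before the first header so errors carry a line number.
        for lineno, line in enumerate(handle, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}")
            break
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            tokens = _parse_description_tokens(rec.description)
            role = tokens.get("role", Role.POLYPLOID.value)
            try:
                role = Role(role)
            except ValueError:
                raise FastaParseError(f"{path}: record {rec.id!r}: unknown role {role!r}") from None
            if rec.id in seen:
                raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(
                NucleotideSequence(
                    seq_id=rec.id,
                    residues=str(rec.seq),
                    role=role,
                    species_label=tokens.get("species", "").replace("_", " "),
                )
            )
    return records


def write_fasta(sequences: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write sequences with ``role=... species=...`` description tokens."""
    records = []
    for s in sequences:
        desc = f"role={s.role.value}"
        if s.species_label:
            desc += f" species={s.species_label.replace(' ', '_')}"
        records.append(SeqRecord(Seq(s.residues), id=s.seq_id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_individuals(path: str | Path) -> list[IndividualRecord]:
    """Read the individuals table (TSV: individual_id, population_id, role, species_label)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"individual_id", "population_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: individuals table missing columns {sorted(missing)}")
    out = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.individual_id in seen:
            raise ValueError(f"{path}: duplicate individual_id {row.individual_id!r}")
        seen.add(row.individual_id)
        out.append(
            IndividualRecord(
                individual_id=row.individual_id,
                population_id=row.population_id,
                role=Role(row.role),
                species_label=getattr(row, "species_label", ""),
            )
        )
    return out


def write_individuals(individuals: Iterable[IndividualRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": i.individual_id,
                "population_id": i.population_id,
                "role": i.role.value,
                "species_label": i.species_label,
            }
            for i in individuals
        ]
    ).to_csv(path, sep="\t", index=False)
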