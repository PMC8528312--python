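"""Genetic-code primitives, CDS validation and synonymous-variant enumeration.

All coordinates are 0-based, half-open. Only the forward (coding) strand is
considered; GenBank minus-strand CDS features are reverse-complemented on
input so a :class:`CDSRecord` sequence is always the coding strand.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

STOP = "*"
VALID_BASES = frozenset("ACGT")

#: Codons that are markedly under-used in E. coli and can slow or
#: mistranslate expression; overridable per organism.
DEFAULT_RARE_CODONS = frozenset(
    {"AGG", "AGA", "CGA", "CGG", "CTA", "ATA", "CCC", "TCG"}
)


class SequenceError(ValueError):
    """Invalid nucleotide sequence (non-ACGT character, bad length...)."""


def _standard_code(table_id: int = 11) -> dict[str, str]:
    ncbi = unambiguous_dna_by_id[table_id]
    code = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        code[stop] = STOP
    return code


@dataclass(frozen=True)
class CodonTable:
    """Genetic code with synonym sets, rare codons and allowed start codons.

    The default is the bacterial/archaeal code (NCBI translation table 11),
    with ``start_codons`` restricted to ATG: created start codons default to
    the canonical start only, although the table is injectable.
    """

    code: dict[str, str] = field(default_factory=_standard_code)
    rare_codons: frozenset[str] = DEFAULT_RARE_CODONS
    start_codons: frozenset[str] = frozenset({"ATG"})

    @property
    def synonym_sets(self) -> dict[str, tuple[str, ...]]:
        """Amino acid -> lexicographically sorted tuple of its codons.

        Stop codons are excluded: the 61 sense codons are partitioned.
        """
        if not hasattr(self, "_synonym_sets"):
            sets: dict[str, list[str]] = {}
            for codon, aa in self.code.items():
                if aa != STOP:
                    sets.setdefault(aa, []).append(codon)
            object.__setattr__(
                self,
                "_synonym_sets",
                {aa: tuple(sorted(c)) for aa, c in sets.items()},
            )
        return self._synonym_sets

    @property
    def stop_codons(self) -> frozenset[str]:
        if not hasattr(self, "_stop_codons"):
            object.__setattr__(
                self,
                "_stop_codons",
                frozenset(c for c, aa in self.code.items() if aa == STOP),
            )
        return self._stop_codons

    @property
    def sense_codons(self) -> tuple[str, ...]:
        if not hasattr(self, "_sense_codons"):
            object.__setattr__(
                self,
                "_sense_codons",
                tuple(sorted(c for c, aa in self.code.items() if aa != STOP)),
            )
        return self._sense_codons

    def synonyms(self, codon: str) -> tuple[str, ...]:
        """All codons encoding the same amino acid, including ``codon``."""
        aa = self.code[codon]
        if aa == STOP:
            raise SequenceError(f"stop codon {codon} has no synonym set")
        return self.synonym_sets[aa]

    def is_stop(self, codon: str) -> bool:
        return self.code.get(codon) == STOP


STANDARD_TABLE = CodonTable()


def _check_bases(sequence: str) -> None:
    for i, base in enumerate(sequence):
        if base not in VALID_BASES:
            raise SequenceError(
                f"invalid base {base!r} at position {i}: only A/C/G/T accepted "
                "(ambiguity codes are rejected)"
            )


@dataclass(frozen=True)
class CDSRecord:
    """One protein-coding sequence (the gene to protect, or a payload gene).

    Invariants enforced at construction: length is a positive multiple of 3,
    only A/C/G/T, and the frame-0 translation has no internal stop codon.
    A missing start codon or terminal stop only warns: partial CDSs occur in
    real annotation and the designer does not need either.
    """

    id: str
    sequence: str
    description: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise SequenceError(
                f"CDS {self.id!r}: length {len(seq)} is not a positive multiple of 3"
            )
        _check_bases(seq)
        aa = translate(seq, 0)
        if STOP in aa[:-1]:
            pos = aa.index(STOP) * 3
            raise SequenceError(
                f"CDS {self.id!r}: internal stop codon at nt {pos}"
            )
        if seq[:3] not in ("ATG", "GTG", "TTG"):
            warnings.warn(f"CDS {self.id!r} does not begin with a start codon")
        if aa[-1] != STOP:
            warnings.warn(f"CDS {self.id!r} does not end with a stop codon")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    @property
    def has_terminal_stop(self) -> bool:
        return translate(self.sequence, 0)[-1] == STOP


def translate(sequence: str, offset: int = 0, table: CodonTable = STANDARD_TABLE) -> str:
    """Translate complete codons from ``offset``; a trailing partial codon is dropped.

    Stop codons are rendered ``*`` and do NOT halt translation — design
    operations need to see every stop in a frame.
    """
    if offset < 0 or offset >= len(sequence):
        raise SequenceError(
            f"offset {offset} outside sequence of length {len(sequence)}"
        )
    _check_bases(sequence)
    code = table.code
    out = []
    for i in range(offset, len(sequence) - 2, 3):
        out.append(code[sequence[i : i + 3]])
    return "".join(out)


def synonymous_variants(
    window: str, table: CodonTable = STANDARD_TABLE
) -> Iterator[str]:
    """Yield every synonymous recoding of a codon-aligned window.

    Each codon is independently replaced by any codon in its synonym set
    (the original is included). Order is deterministic: codon-position-major
    with codons in lexicographic order, so the total count is the product of
    synonym-set sizes.
    """
    if len(window) % 3 != 0:
        raise SequenceError(f"window length {len(window)} is not a multiple of 3")
    _check_bases(window)
    choices = []
    for i in range(0, len(window), 3):
        codon = window[i : i + 3]
        if table.is_stop(codon):
            raise SequenceError(f"stop codon {codon} at window offset {i}")
        choices.append(table.synonyms(codon))
    for combo in itertools.product(*choices):
        yield "".join(combo)


def count_synonymous_variants(window: str, table: CodonTable = STANDARD_TABLE) -> int:
    """Product of synonym-set sizes over the window's codons."""
    n = 1
    for i in range(0, len(window), 3):
        codon = window[i : i + 3]
        if table.is_stop(codon):
            raise SequenceError(f"stop codon {codon} at window offset {i}")
        n *= len(table.synonyms(codon))
    return n


def edit_distance_aa(
    original: str, variant: str, table: CodonTable = STANDARD_TABLE
) -> int:
    """Number of codon positions whose translations differ (stringency cost)."""
    if len(original) != len(variant):
        raise SequenceError(
            f"length mismatch: {len(original)} vs {len(variant)}"
        )
    if len(original) % 3 != 0:
        raise SequenceError(f"length {len(original)} is not a multiple of 3")
    return sum(
        table.code[original[i : i + 3]] != table.code[variant[i : i + 3]]
        for i in range(0, len(original), 3)
    )


# ---------------------------------------------------------------------------
# readers


def _record_from_seq(seq: str, rec_id: str, description: str, source: str):
    return CDSRecord(id=rec_id, sequence=seq, description=description, source=source)


def read_fasta(path: str | Path) -> list[CDSRecord]:
    """Read every record of a (multi-)FASTA file as a CDS.

    The record id is the first whitespace-delimited token of the header.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            _record_from_seq(
                str(rec.seq).upper(),
                rec.id,
                rec.description,
                f"{path}:{rec.id}",
            )
        )
    return records


def read_genbank(path: str | Path) -> list[CDSRecord]:
    """Extract every CDS feature of a GenBank file.

    Compound locations are joined and minus-strand features are
    reverse-complemented, so the returned sequence is always the coding
    strand read 5'→3'.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for i, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            seq = str(feat.extract(rec.seq)).upper()
            quals = feat.qualifiers
            cds_id = (
                quals.get("locus_tag", quals.get("gene", [f"{rec.id}_CDS{i}"]))[0]
            )
            desc = quals.get("product", [""])[0]
            records.append(
                _record_from_seq(seq, cds_id, desc, f"{path}:{rec.id}:CDS{i}")
            )
    return records


def read_cds_file(path: str | Path) -> list[CDSRecord]:
    """Dispatch on extension: GenBank (.gb/.gbk/.genbank) or FASTA otherwise."""
    path = Path(path)
    if path.suffix.lower() in {".gb", ".gbk", ".genbank"}:
        return read_genbank(path)
    return read_fasta(path)
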