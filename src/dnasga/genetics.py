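"""Codon-level consequences of code-suggested substitutions.

When identification places a sequence in the cloud of a codeword, the
single suggested nucleotide change falls inside one codon; translating
the before/after codons under the standard genetic code and a panel of
deviant (noncanonical) codes reveals whether the change is silent,
missense, or nonsense per code.  Reassignments such as TGA->Trp (most
mitochondria), AGA->Ser (invertebrate mitochondria), ATA->Met (several
mitochondrial lineages) and TGA->Cys (Euplotid nuclei) can make a
substitution that is non-synonymous under the standard code synonymous
under a deviant one.

Tables are the NCBI translation tables, obtained through Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio.Data import CodonTable as _BioCodonTable

from .pipeline import CLOUD, IdentificationResult

__all__ = [
    "GeneticCodeTable",
    "CodonAnnotation",
    "SHIPPED_TABLE_IDS",
    "genetic_code_table",
    "shipped_tables",
    "annotate",
    "classify_effect",
    "SILENT",
    "MISSENSE",
    "NONSENSE",
    "STOP_LOSS",
]

STOP = "*"

SILENT = "silent"
MISSENSE = "missense"
NONSENSE = "nonsense"
STOP_LOSS = "stop_loss"

#: NCBI translation-table ids shipped by default: the standard code, the
#: five deviant codes discussed alongside it, and the Euplotid nuclear
#: code carrying the TGA->Cys reassignment.
SHIPPED_TABLE_IDS: dict[int, str] = {
    1: "standard",
    2: "vertebrate-mito",
    3: "yeast-mito",
    4: "mold-protozoan-mito",
    5: "invertebrate-mito",
    6: "ciliate-nuclear",
    10: "euplotid-nuclear",
}

_BASES = "TCAG"


@dataclass(frozen=True)
class GeneticCodeTable:
    """A total map of the 64 codons to amino acids (``*`` = stop)."""

    name: str
    ncbi_id: int
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.mapping) != 64:
            raise ValueError(
                f"table {self.name!r} maps {len(self.mapping)} codons, not 64"
            )

    def translate(self, codon: str) -> str:
        return self.mapping[codon.upper()]

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.mapping.items() if aa == STOP)

    def differences_from(self, other: "GeneticCodeTable") -> dict[str, tuple[str, str]]:
        """Codons translated differently, as codon -> (self, other)."""
        return {
            c: (self.mapping[c], other.mapping[c])
            for c in self.mapping
            if self.mapping[c] != other.mapping[c]
        }


@lru_cache(maxsize=None)
def genetic_code_table(ncbi_id: int) -> GeneticCodeTable:
    """Build a total 64-codon table from an NCBI translation-table id."""
    bio = _BioCodonTable.unambiguous_dna_by_id[ncbi_id]
    mapping: dict[str, str] = {}
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                codon = b1 + b2 + b3
                mapping[codon] = bio.forward_table.get(codon, STOP)
    name = SHIPPED_TABLE_IDS.get(ncbi_id, bio.names[0].lower().replace(" ", "-"))
    return GeneticCodeTable(name=name, ncbi_id=ncbi_id, mapping=mapping)


def shipped_tables() -> list[GeneticCodeTable]:
    return [genetic_code_table(i) for i in SHIPPED_TABLE_IDS]


@dataclass(frozen=True)
class CodonAnnotation:
    """Before/after codon of a cloud verdict and its translations.

    ``codon_index`` is 1-based within the chosen reading frame;
    ``translations`` maps table name to ``(aa_before, aa_after)``;
    ``synonymous_under`` lists the tables where both codons translate
    identically (computed, never asserted).  ``translatable`` is False
    when the altered position falls in an incomplete trailing codon (or
    ahead of the frame offset).
    """

    codon_index: int | None
    before_codon: str | None
    after_codon: str | None
    translations: dict[str, tuple[str, str]]
    synonymous_under: tuple[str, ...]
    translatable: bool = True

    @property
    def aa_standard_before(self) -> str | None:
        pair = self.translations.get("standard")
        return pair[0] if pair else None

    @property
    def aa_standard_after(self) -> str | None:
        pair = self.translations.get("standard")
        return pair[1] if pair else None


def _not_translatable() -> CodonAnnotation:
    return CodonAnnotation(
        codon_index=None,
        before_codon=None,
        after_codon=None,
        translations={},
        synonymous_under=(),
        translatable=False,
    )


def annotate(
    result: IdentificationResult,
    frame_offset: int = 0,
    tables: Iterable[GeneticCodeTable] | None = None,
) -> CodonAnnotation:
    """Annotate the codon consequence of a cloud identification.

    The altered nucleotide's codon is extracted from both the input and
    the code-generated sequence given ``frame_offset`` (0, 1 or 2) and
    translated under every requested table (default: all shipped
    tables).
    """
    if result.status != CLOUD:
        raise ValueError("annotate requires a cloud identification result")
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    assert result.position is not None and result.generated_sequence is not None
    tabs = list(tables) if tables is not None else shipped_tables()

    pos0 = result.position - 1
    if pos0 < frame_offset:
        return _not_translatable()
    codon_idx0 = (pos0 - frame_offset) // 3
    start = frame_offset + 3 * codon_idx0
    before_seq = result.generated_sequence.residues  # codeword side
    # reconstruct the input sequence from the single difference
    after_list = list(before_seq)
    assert result.original_nt is not None
    after_list[pos0] = result.original_nt
    input_seq = "".join(after_list)
    if start + 3 > len(input_seq):
        return _not_translatable()

    before_codon = input_seq[start : start + 3]  # as observed
    after_codon = before_seq[start : start + 3]  # code-generated
    translations = {
        t.name: (t.translate(before_codon), t.translate(after_codon)) for t in tabs
    }
    synonymous = tuple(
        name for name, (b, a) in translations.items() if b == a
    )
    return CodonAnnotation(
        codon_index=codon_idx0 + 1,
        before_codon=before_codon,
        after_codon=after_codon,
        translations=translations,
        synonymous_under=synonymous,
    )


def classify_effect(annotation: CodonAnnotation) -> dict[str, str]:
    """Per-table effect class of the before -> after codon change."""
    if not annotation.translatable:
        raise ValueError("annotation is not translatable")
    out: dict[str, str] = {}
    for name, (before, after) in annotation.translations.items():
        if before == after:
            out[name] = SILENT
        elif after == STOP:
            out[name] = NONSENSE
        elif before == STOP:
            out[name] = STOP_LOSS
        else:
            out[name] = MISSENSE
    return out
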