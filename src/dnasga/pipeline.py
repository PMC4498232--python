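"""DNA-facing pipeline: labelings, identification, code-generated sequences.

A *labeling* is a bijection between the nucleotide alphabet {A, C, G, T}
and the four code symbols.  Under a labeling, a coding sequence of the
right length maps to a symbol vector; if that vector is a codeword the
sequence is *identified* as code-generated, and if it lies at Hamming
distance 1 from a codeword it belongs to the codeword's *cloud* — the
decoder then emits the code-generated sequence, the altered position
and the suggested (ancestral-candidate) nucleotide.

The four default labelings A–D are a fixed convention of this package
(the published table names them without defining the bijections):

=====  ==================
name   A, C, G, T  ->
=====  ==================
A      0, 1, 2, 3
B      0, 1, 3, 2
C      0, 2, 1, 3
D      0, 2, 3, 1
=====  ==================

For field codes the symbols 2 and 3 are read as the GF(4) elements
``a`` and ``b``.  Custom labelings may be supplied as any permutation.
Reported positions are 1-based (biologist-facing); internal vector
indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codes import CodeRegistryEntry, CodeSpec, build_code
from .decoding import CORRECTED, NO_ERROR, brute_force_identify, decode_single_error

__all__ = [
    "Labeling",
    "DnaSequence",
    "IdentificationResult",
    "DEFAULT_LABELINGS",
    "SequenceValidationError",
    "apply_labeling",
    "inverse_labeling",
    "identify",
    "scan",
]

NUCLEOTIDES = "ACGT"

CODEWORD = "codeword"
CLOUD = "cloud"
UNIDENTIFIED = "unidentified"
SKIPPED = "skipped"


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the unambiguous DNA alphabet."""


@dataclass(frozen=True)
class Labeling:
    """A bijection {A, C, G, T} -> {0, 1, 2, 3} (2 = a, 3 = b for GF(4))."""

    name: str
    mapping: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.mapping) != set(NUCLEOTIDES) or set(
            self.mapping.values()
        ) != {0, 1, 2, 3}:
            raise ValueError(
                f"labeling {self.name!r} must be a bijection ACGT -> 0..3"
            )

    @property
    def inverse(self) -> dict[int, str]:
        return {v: k for k, v in self.mapping.items()}

    def lut(self) -> np.ndarray:
        """256-entry LUT from ASCII code to symbol (4 = invalid)."""
        lut = np.full(256, 4, dtype=np.uint8)
        for nt, sym in self.mapping.items():
            lut[ord(nt)] = sym
        return lut


DEFAULT_LABELINGS: dict[str, Labeling] = {
    "A": Labeling("A", {"A": 0, "C": 1, "G": 2, "T": 3}),
    "B": Labeling("B", {"A": 0, "C": 1, "G": 3, "T": 2}),
    "C": Labeling("C", {"A": 0, "C": 2, "G": 1, "T": 3}),
    "D": Labeling("D", {"A": 0, "C": 2, "G": 3, "T": 1}),
}


@dataclass(frozen=True)
class DnaSequence:
    """An unambiguous DNA sequence (uppercase A/C/G/T only)."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        canon = self.residues.upper()
        bad = [i + 1 for i, c in enumerate(canon) if c not in NUCLEOTIDES]
        if bad:
            shown = ", ".join(map(str, bad[:10]))
            more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
            raise SequenceValidationError(
                f"record {self.identifier!r}: non-ACGT character at "
                f"position(s) {shown}{more}"
            )
        object.__setattr__(self, "residues", canon)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class IdentificationResult:
    """Verdict of identifying one sequence against one (code, labeling)."""

    sequence_id: str
    code_key: str
    labeling: str
    status: str  # codeword | cloud | unidentified | skipped
    position: int | None = None  # 1-based nucleotide coordinate (cloud only)
    original_nt: str | None = None
    suggested_nt: str | None = None
    generated_sequence: DnaSequence | None = field(repr=False, default=None)


def apply_labeling(seq: DnaSequence, lab: Labeling) -> np.ndarray:
    """Map a DNA sequence to its symbol vector through the bijection."""
    arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    return lab.lut()[arr]


def inverse_labeling(symbols: Sequence[int] | np.ndarray, lab: Labeling) -> str:
    """Map a symbol vector back to nucleotides."""
    inv = lab.inverse
    return "".join(inv[int(s)] for s in np.asarray(symbols))


def identify(
    seq: DnaSequence,
    code: CodeSpec,
    lab: Labeling,
    *,
    use_oracle: bool = False,
) -> IdentificationResult:
    """Identify a sequence against a code under a labeling.

    Returns status ``codeword`` when the labeled vector is a codeword,
    ``cloud`` (with the altered 1-based position, the original and the
    code-suggested nucleotide, and the code-generated sequence) when it
    lies at distance 1 from a codeword, and ``unidentified`` otherwise.
    ``use_oracle=True`` swaps the syndrome decoder for the brute-force
    membership oracle (verification aid; identical contract).
    """
    if len(seq) != code.n:
        raise ValueError(
            f"sequence {seq.identifier!r} has length {len(seq)}, "
            f"code {code.key or code.kind!r} expects {code.n}"
        )
    vec = apply_labeling(seq, lab)
    decoder = brute_force_identify if use_oracle else decode_single_error
    outcome = decoder(vec, code)
    if outcome.status == NO_ERROR:
        return IdentificationResult(
            sequence_id=seq.identifier,
            code_key=code.key,
            labeling=lab.name,
            status=CODEWORD,
            generated_sequence=seq,
        )
    if outcome.status == CORRECTED:
        assert outcome.corrected_vector is not None and outcome.position is not None
        generated = inverse_labeling(outcome.corrected_vector, lab)
        pos0 = outcome.position
        return IdentificationResult(
            sequence_id=seq.identifier,
            code_key=code.key,
            labeling=lab.name,
            status=CLOUD,
            position=pos0 + 1,
            original_nt=seq.residues[pos0],
            suggested_nt=generated[pos0],
            generated_sequence=DnaSequence(
                f"{seq.identifier}|code-generated", generated
            ),
        )
    return IdentificationResult(
        sequence_id=seq.identifier,
        code_key=code.key,
        labeling=lab.name,
        status=UNIDENTIFIED,
    )


def scan(
    seq: DnaSequence,
    registry: Iterable[CodeRegistryEntry],
    labelings: Iterable[Labeling] | None = None,
    *,
    codes_cache: dict[str, CodeSpec] | None = None,
) -> list[IdentificationResult]:
    """Identify one sequence against every length-compatible preset.

    One result per (code, labeling) pair, ordered by (code key, labeling
    name).  If no preset matches the sequence length, a single explicit
    skip record is returned.
    """
    labs = list(labelings) if labelings is not None else list(
        DEFAULT_LABELINGS.values()
    )
    cache = codes_cache if codes_cache is not None else {}
    results: list[IdentificationResult] = []
    for entry in sorted(registry, key=lambda e: e.key):
        code = cache.get(entry.key)
        if code is None:
            code = cache[entry.key] = build_code(entry)
        if code.n != len(seq):
            continue
        for lab in sorted(labs, key=lambda l: l.name):
            results.append(identify(seq, code, lab))
    if not results:
        results.append(
            IdentificationResult(
                sequence_id=seq.identifier,
                code_key=".",
                labeling=".",
                status=SKIPPED,
            )
        )
    return results
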