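"""Synthetic fixture generation: random codewords with planted errors.

The generator draws uniform random length-k messages, encodes them,
maps the codewords to DNA through a labeling, and plants the requested
number of single-nucleotide substitutions at recorded positions.  It
emulates the study conditions — coding sequences whose length matches a
code's block length, differing from a codeword in at most one
nucleotide — and makes the whole pipeline testable offline.  Given the
same (spec, seed) the output is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .codes import CodeSpec, encode
from .pipeline import DEFAULT_LABELINGS, DnaSequence, Labeling, inverse_labeling

__all__ = ["FixtureSpec", "PlantedError", "generate_fixtures", "write_truth_table"]


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible recipe for a batch of synthetic sequences."""

    code_key: str
    labeling: str = "A"
    n_sequences: int = 100
    errors_per_sequence: int = 1  # 0, 1 or 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.errors_per_sequence not in (0, 1, 2):
            raise ValueError("errors_per_sequence must be 0, 1 or 2")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")


@dataclass(frozen=True)
class PlantedError:
    """Ground truth for one planted substitution (1-based position)."""

    sequence_id: str
    position: int
    ref: str  # codeword nucleotide (what identification should suggest)
    alt: str  # planted nucleotide (what the record carries)


def generate_fixtures(
    spec: FixtureSpec,
    code: CodeSpec,
    labeling: Labeling | None = None,
) -> tuple[list[DnaSequence], list[PlantedError]]:
    """Draw random codeword-derived sequences with planted substitutions.

    Returns the records and a truth table of planted errors (empty when
    ``errors_per_sequence == 0``).  Multiple errors in one record are
    planted at distinct positions.
    """
    lab = labeling if labeling is not None else DEFAULT_LABELINGS[spec.labeling]
    rng = np.random.default_rng(spec.seed)
    records: list[DnaSequence] = []
    truth: list[PlantedError] = []
    inv = lab.inverse
    for i in range(spec.n_sequences):
        msg = rng.integers(0, 4, size=code.k, dtype=np.uint8)
        word = encode(msg, code)
        dna = list(inverse_labeling(word, lab))
        seq_id = f"{spec.code_key}_{spec.labeling}_e{spec.errors_per_sequence}_{i:04d}"
        if spec.errors_per_sequence:
            positions = rng.choice(
                code.n, size=spec.errors_per_sequence, replace=False
            )
            for pos in sorted(int(p) for p in positions):
                ref = dna[pos]
                others = [nt for nt in "ACGT" if nt != ref]
                alt = others[int(rng.integers(0, 3))]
                dna[pos] = alt
                truth.append(
                    PlantedError(
                        sequence_id=seq_id, position=pos + 1, ref=ref, alt=alt
                    )
                )
        records.append(DnaSequence(seq_id, "".join(dna)))
    return records, truth


def write_truth_table(truth: list[PlantedError], path: str | Path) -> None:
    """Write the planted-error ground truth as a TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("seq_id\tplanted_position\tref\talt\n")
        for t in truth:
            fh.write(f"{t.sequence_id}\t{t.position}\t{t.ref}\t{t.alt}\n")
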