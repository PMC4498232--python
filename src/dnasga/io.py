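"""FASTA input and TSV/JSON report output."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .genetics import CodonAnnotation
from .pipeline import DnaSequence, IdentificationResult, SequenceValidationError

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_report",
    "REPORT_COLUMNS",
    "NA",
]

NA = "."

REPORT_COLUMNS = [
    "seq_id",
    "code_key",
    "labeling",
    "status",
    "position_1based",
    "ref_nt",
    "alt_nt",
    "generated_sequence",
]

ANNOTATION_COLUMNS = [
    "codon_index",
    "before_codon",
    "after_codon",
    "aa_before",
    "aa_after",
    "effect_standard",
    "synonymous_under",
]


def read_fasta(path: str | Path) -> list[DnaSequence]:
    """Read a multi-record FASTA into validated DNA sequences.

    Rejects empty files, duplicate identifiers, and any record with
    characters outside A/C/G/T (ambiguity codes included), reporting
    the offending record and positions.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceValidationError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out: list[DnaSequence] = []
    for rec in records:
        if rec.id in seen:
            raise SequenceValidationError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        out.append(DnaSequence(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[DnaSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in seqs:
            fh.write(f">{s.identifier}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def _result_row(
    res: IdentificationResult, ann: CodonAnnotation | None = None
) -> dict[str, str]:
    row = {
        "seq_id": res.sequence_id,
        "code_key": res.code_key or NA,
        "labeling": res.labeling or NA,
        "status": res.status,
        "position_1based": str(res.position) if res.position is not None else NA,
        "ref_nt": res.original_nt or NA,
        "alt_nt": res.suggested_nt or NA,
        "generated_sequence": (
            res.generated_sequence.residues if res.generated_sequence else NA
        ),
    }
    if ann is not None:
        if ann.translatable:
            from .genetics import classify_effect

            effects = classify_effect(ann)
            row.update(
                {
                    "codon_index": str(ann.codon_index),
                    "before_codon": ann.before_codon or NA,
                    "after_codon": ann.after_codon or NA,
                    "aa_before": ann.aa_standard_before or NA,
                    "aa_after": ann.aa_standard_after or NA,
                    "effect_standard": effects.get("standard", NA),
                    "synonymous_under": (
                        ",".join(ann.synonymous_under) if ann.synonymous_under else NA
                    ),
                }
            )
        else:
            row.update({c: NA for c in ANNOTATION_COLUMNS})
            row["codon_index"] = "not-translatable"
    return row


def write_report(
    results: Sequence[IdentificationResult],
    path: str | Path,
    *,
    fmt: str = "tsv",
    annotations: Sequence[CodonAnnotation | None] | None = None,
    header_comment: str | None = None,
) -> None:
    """Write identification results (optionally with codon annotations).

    TSV: tab-separated with a header row, ``.`` for not-applicable
    fields, positions 1-based.  JSON mirrors the columns as keys.
    """
    cols = list(REPORT_COLUMNS)
    if annotations is not None:
        if len(annotations) != len(results):
            raise ValueError("annotations must parallel results")
        cols += ANNOTATION_COLUMNS
    rows = [
        _result_row(res, annotations[i] if annotations is not None else None)
        for i, res in enumerate(results)
    ]
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(row.get(c, NA) for c in cols) + "\n")
    elif fmt == "json":
        payload = {
            "comment": header_comment,
            "results": [{c: row.get(c, NA) for c in cols} for row in rows],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
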