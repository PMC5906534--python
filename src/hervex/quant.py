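"""Read assignment and counting under the zero-mismatch unique-mapping rule.

Paired-end reads are decoupled into single-end reads (to maximize assignment
to fragmented elements), then each read is looked up in the exact-match index:
a read is counted only if it matches exactly one element with zero mismatches.
Reads matching several elements (multi) or none (unmapped) are discarded but
audited.

Uniqueness granularity: "uniquely mapping to a single element" is enforced at
the element level by default — a read occurring at two positions *within one*
element is still unique to that element.  ``alignment_level=True`` instead
discards any read with more than one alignment position/strand, reproducing a
``-m 1``-style aligner filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from hervex.refindex import ExactMatchIndex

__all__ = [
    "AssignmentRecord",
    "read_fastq",
    "decouple_pairs",
    "assign_read",
    "count_sample",
    "count_samples",
]

_MATE_SUFFIX = re.compile(r"/[12]$")


@dataclass(frozen=True)
class AssignmentRecord:
    """Outcome of assigning one read: unique (to one element), multi, or unmapped."""

    read_id: str
    outcome: str  # "unique" | "multi" | "unmapped"
    element_id: str | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.outcome == "unique" and self.element_id is None:
            raise ValueError("unique outcome requires an element id")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTQ file (uppercased)."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def _normalize_name(name: str) -> str:
    return _MATE_SUFFIX.sub("", name.split()[0])


def decouple_pairs(
    r1: Iterable[tuple[str, str]] | str | Path,
    r2: Iterable[tuple[str, str]] | str | Path,
) -> list[tuple[str, str]]:
    """Decouple mates into independent single-end reads.

    Output is the full R1 block followed by the full R2 block (the chunk is
    the whole input), with ``/1``/``/2`` mate suffixes stripped so both reads
    trace to the pair name.  R1/R2 of unequal length is an error.
    """
    if isinstance(r1, (str, Path)):
        r1 = read_fastq(r1)
    if isinstance(r2, (str, Path)):
        r2 = read_fastq(r2)
    block1 = [(_normalize_name(n), s) for n, s in r1]
    block2 = [(_normalize_name(n), s) for n, s in r2]
    if len(block1) != len(block2):
        raise ValueError(
            f"R1/R2 length mismatch: {len(block1)} vs {len(block2)} reads"
        )
    return block1 + block2


def assign_read(
    read: tuple[str, str], index: ExactMatchIndex, alignment_level: bool = False
) -> AssignmentRecord:
    """Classify one read as unique / multi / unmapped against the index.

    Reads whose length differs from the index window length, or containing N,
    cannot match and are unmapped.  With ``alignment_level=True`` a read with
    more than one alignment (position x strand), even within a single element,
    is multi.
    """
    name, seq = read
    if len(seq) != index.read_length or "N" in seq:
        return AssignmentRecord(name, "unmapped")
    occ = index.query(seq)
    if not occ:
        return AssignmentRecord(name, "unmapped")
    elements = {eid for eid, _ in occ}
    if len(elements) > 1 or (alignment_level and len(occ) > 1):
        return AssignmentRecord(name, "multi")
    eid, strand = occ[0]
    return AssignmentRecord(name, "unique", element_id=eid, strand=strand)


def count_sample(
    reads: Iterable[tuple[str, str]],
    index: ExactMatchIndex,
    alignment_level: bool = False,
) -> tuple[pd.Series, dict[str, int]]:
    """Count unique assignments per element for one sample.

    Returns the counts column (indexed by the index's quantifiable element
    ids) and an audit dict ``{n_unique, n_multi, n_unmapped}`` partitioning
    the input reads.
    """
    counts = dict.fromkeys(index.element_ids, 0)
    audit = {"n_unique": 0, "n_multi": 0, "n_unmapped": 0}
    for read in reads:
        rec = assign_read(read, index, alignment_level=alignment_level)
        if rec.outcome == "unique":
            counts[rec.element_id] += 1
            audit["n_unique"] += 1
        elif rec.outcome == "multi":
            audit["n_multi"] += 1
        else:
            audit["n_unmapped"] += 1
    col = pd.Series(counts, name="count", dtype="int64")
    col.index.name = "element_id"
    return col, audit


def count_samples(
    fastq_pairs: dict[str, tuple[str | Path, str | Path]],
    index: ExactMatchIndex,
    alignment_level: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify several samples: {sample: (R1 path, R2 path)} -> counts, audit.

    The counts matrix is elements x samples; per-sample library size for cpm
    is the column sum (total unique-assigned reads).
    """
    cols, audits = {}, {}
    for sample, (p1, p2) in fastq_pairs.items():
        reads = decouple_pairs(p1, p2)
        col, audit = count_sample(reads, index, alignment_level=alignment_level)
        cols[sample] = col
        audits[sample] = audit
    counts = pd.DataFrame(cols)
    counts.index.name = "element_id"
    audit_df = pd.DataFrame(audits).T
    audit_df.index.name = "sample"
    return counts, audit_df
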