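"""Element library parsing, GTF annotation, and the exact-match read index.

The quantification strategy for multi-copy retroviral elements demands zero
mismatches and unique assignment, so alignment reduces to exact substring
matching: every length-L window of every element (and its reverse complement)
is indexed, and a read is assignable only when its window set points at exactly
one element.  This makes the uniqueness semantics explicit and testable without
an external aligner binary.

FASTA header dialect: ``>rv_NNNNNN|FAMILY`` — one ``|`` delimiter separating
the element id from its family label.  The parser is isolated in
:func:`parse_header` so an adapter for other catalogue dialects can be added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

__all__ = [
    "ElementRecord",
    "ElementLibrary",
    "ExactMatchIndex",
    "parse_header",
    "load_library",
    "write_library",
    "write_annotation",
    "build_index",
    "reverse_complement",
]

_VALID_BASES = frozenset("ACGTN")

#: minimum window length accepted by :func:`build_index`; shorter windows make
#: near-universal multi-mapping and defeat the uniqueness filter.
MIN_READ_LENGTH = 16

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ElementRecord:
    """A single element: catalogue id, family label, and uppercase sequence."""

    element_id: str
    family: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class ElementLibrary:
    """Ordered collection of :class:`ElementRecord` with unique ids.

    The reference universe for quantification: read assignment, annotation and
    ground-truth bookkeeping all key on ``element_id``.
    """

    def __init__(self, records: Iterable[ElementRecord]):
        self._records: list[ElementRecord] = []
        self._by_id: dict[str, ElementRecord] = {}
        for rec in records:
            if rec.element_id in self._by_id:
                raise ValueError(f"duplicate element id: {rec.element_id!r}")
            if not rec.sequence:
                raise ValueError(f"empty sequence for element {rec.element_id!r}")
            bad = set(rec.sequence) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"element {rec.element_id!r} contains invalid bases: {sorted(bad)}"
                )
            self._records.append(rec)
            self._by_id[rec.element_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ElementRecord]:
        return iter(self._records)

    def __getitem__(self, element_id: str) -> ElementRecord:
        return self._by_id[element_id]

    def __contains__(self, element_id: str) -> bool:
        return element_id in self._by_id

    @property
    def element_ids(self) -> list[str]:
        return [r.element_id for r in self._records]

    @property
    def families(self) -> dict[str, str]:
        """Mapping element id -> family label."""
        return {r.element_id: r.family for r in self._records}

    def min_length(self) -> int:
        return min(r.length for r in self._records)


def parse_header(header: str) -> tuple[str, str]:
    """Split a ``id|family`` FASTA header into its two parts.

    Raises ``ValueError`` naming the record on a malformed header.
    """
    parts = header.split("|")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ValueError(f"malformed library header (expected 'id|family'): {header!r}")
    return parts[0], parts[1]


def load_library(fasta_path: str | Path) -> ElementLibrary:
    """Parse an element FASTA into an :class:`ElementLibrary`.

    Sequences are uppercased; ids and family labels come from the header
    dialect.  Duplicate ids, empty sequences and malformed headers are errors.
    """
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        element_id, family = parse_header(rec.id)
        records.append(ElementRecord(element_id, family, str(rec.seq).upper()))
    return ElementLibrary(records)


def write_library(library: ElementLibrary, path: str | Path, width: int = 70) -> None:
    """Write the library as FASTA using the ``id|family`` header dialect."""
    with open(path, "w") as fh:
        for rec in library:
            fh.write(f">{rec.element_id}|{rec.family}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_annotation(library: ElementLibrary, out: TextIO | str | Path) -> None:
    """Emit one GTF exon feature per element spanning the full sequence.

    Each element is its own contig (seqname = element id); coordinates are
    1-based inclusive per the GTF standard; attributes carry ``gene_id`` and
    ``family``.
    """
    if len(library) == 0:
        raise ValueError("cannot annotate an empty library")

    def _write(fh: TextIO) -> None:
        for rec in library:
            attrs = f'gene_id "{rec.element_id}"; family "{rec.family}";'
            fh.write(
                "\t".join(
                    [
                        rec.element_id,
                        "hervex",
                        "exon",
                        "1",
                        str(rec.length),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )

    if hasattr(out, "write"):
        _write(out)  # type: ignore[arg-type]
    else:
        with open(out, "w") as fh:
            _write(fh)


@dataclass
class ExactMatchIndex:
    """Hash of every length-L window of the library, both strands.

    ``occurrences[window]`` lists ``(element_id, strand)`` for every position
    of every element whose forward ('+') or reverse-complement ('-') strand
    contains the window.  Windows containing N are not indexed.  Elements
    shorter than L are recorded in ``unquantifiable`` and not indexed.
    """

    read_length: int
    occurrences: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    element_ids: list[str] = field(default_factory=list)
    unquantifiable: list[str] = field(default_factory=list)
    stranded: bool = False

    def query(self, seq: str) -> list[tuple[str, str]]:
        """All (element, strand) occurrences of ``seq``; [] if unindexed."""
        return self.occurrences.get(seq, [])

    def element_hits(self, seq: str) -> set[str]:
        """Set of element ids containing ``seq`` on a searchable strand."""
        return {eid for eid, _ in self.occurrences.get(seq, [])}


def build_index(
    library: ElementLibrary, read_length: int, stranded: bool = False
) -> ExactMatchIndex:
    """Index every length-``read_length`` window of every element.

    By default both strands are searchable (each window and its reverse
    complement point at the source element), mirroring a double-strand
    aligner search; ``stranded=True`` indexes only the forward strand.
    Elements shorter than ``read_length`` cannot receive any read and are
    skipped with a warning.
    """
    if read_length < MIN_READ_LENGTH:
        raise ValueError(
            f"read_length {read_length} < {MIN_READ_LENGTH}: windows this short "
            "multi-map almost everywhere"
        )
    idx = ExactMatchIndex(read_length=read_length, stranded=stranded)
    for rec in library:
        if rec.length < read_length:
            idx.unquantifiable.append(rec.element_id)
            continue
        idx.element_ids.append(rec.element_id)
        seq = rec.sequence
        for i in range(rec.length - read_length + 1):
            window = seq[i : i + read_length]
            if "N" in window:
                continue
            idx.occurrences.setdefault(window, []).append((rec.element_id, "+"))
            if not stranded:
                idx.occurrences.setdefault(reverse_complement(window), []).append(
                    (rec.element_id, "-")
                )
    if idx.unquantifiable:
        warnings.warn(
            f"{len(idx.unquantifiable)} element(s) shorter than read length "
            f"{read_length} are unquantifiable and were skipped",
            stacklevel=2,
        )
    return idx
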