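"""Read-pool preparation: duplicate collapsing and Phred-20 filtering.

Shotgun read pools are prepared in two steps before consensus assembly and
mapping: exact sequence duplicates are reduced to a single representative
(keeping the copy with the highest mean quality), and low-quality reads and
bases are removed or masked.  Both operations act on :class:`ReadRecord`
objects and preserve first-occurrence order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, List, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReadRecord",
    "collapse_duplicates",
    "quality_filter",
    "read_fastq",
    "write_fastq",
]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, bases over {A,C,G,T,N} and per-base Phred scores."""

    id: str
    bases: str
    quals: tuple

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.quals)} quality values"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id!r}: negative Phred score")

    @property
    def mean_quality(self) -> float:
        """Arithmetic mean of the raw Phred scores (0.0 for an empty read)."""
        if not self.quals:
            return 0.0
        return sum(self.quals) / len(self.quals)


def collapse_duplicates(reads: Iterable[ReadRecord]) -> List[ReadRecord]:
    """Reduce exact sequence duplicates to a single representative.

    Reads with identical base strings (qualities ignored; ``N`` compares as a
    literal N) are collapsed to the record with the highest mean Phred score.
    Ties keep the earliest record.  Output order is first-occurrence order of
    each distinct sequence.
    """
    best: dict = {}
    order: List[str] = []
    for rec in reads:
        kept = best.get(rec.bases)
        if kept is None:
            best[rec.bases] = rec
            order.append(rec.bases)
        elif rec.mean_quality > kept.mean_quality:
            best[rec.bases] = rec
    return [best[b] for b in order]


def quality_filter(
    reads: Iterable[ReadRecord],
    min_mean_q: float = 20,
    min_base_q: int = 20,
) -> List[ReadRecord]:
    """Drop low-quality reads and mask low-quality bases with N.

    Reads whose mean Phred score is strictly below ``min_mean_q`` are removed.
    In the survivors, bases with a Phred score strictly below ``min_base_q``
    are replaced by ``N``; their quality values are preserved.
    """
    out: List[ReadRecord] = []
    for rec in reads:
        if rec.mean_quality < min_mean_q:
            continue
        if any(q < min_base_q for q in rec.quals):
            masked = "".join(
                "N" if q < min_base_q else b for b, q in zip(rec.bases, rec.quals)
            )
            rec = ReadRecord(rec.id, masked, rec.quals)
        out.append(rec)
    return out


def read_fastq(handle) -> Iterator[ReadRecord]:
    """Parse FASTQ (Phred+33) into :class:`ReadRecord` objects."""
    for rec in SeqIO.parse(handle, "fastq"):
        yield ReadRecord(
            rec.id,
            str(rec.seq).upper(),
            tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[ReadRecord], handle: TextIO) -> int:
    """Write reads as FASTQ (Phred+33); returns the number written."""
    n = 0
    for rec in reads:
        sr = SeqRecord(Seq(rec.bases), id=rec.id, description="")
        sr.letter_annotations["phred_quality"] = list(rec.quals)
        SeqIO.write(sr, handle, "fastq")
        n += 1
    return n
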