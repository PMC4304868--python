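"""Individual consensus assembly and association with the group reference.

Each individual's consensus is built by iterative majority calling against a
reference template (mapping reads, calling the most frequent base per column,
and remapping until the call stabilises).  The consensus is then globally
aligned to the group reference once, and the alignment is reduced to a
:class:`CoordinateMap` associating every reference position with its
homologous consensus position — the structure that lets per-sample tallies be
compared across distantly related individuals.  Insertions relative to the
reference have no reference partner and are discarded downstream.

All coordinates are 1-based, inclusive, on the forward strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, TextIO, Tuple

import numpy as np
from Bio import Align

from . import mapping as mp
from .preprocess import ReadRecord

__all__ = [
    "ConsensusSequence",
    "CoordinateMap",
    "build_consensus",
    "align_to_reference",
]

UNASSEMBLED = "N"

# majority ties broken by fixed base order A < C < G < T
_BASE_ORDER = "ACGT"


@dataclass
class ConsensusSequence:
    """Per-individual consensus: bases (``N`` marks unassembled, zero-coverage
    columns) plus per-position read depth."""

    bases: str
    coverage: np.ndarray

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.coverage):
            raise ValueError("bases and coverage length mismatch")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class CoordinateMap:
    """Association between group-reference positions and an individual
    consensus.

    ``ref_to_cons[i]`` is the 1-based consensus position matched to reference
    position ``i + 1``, or 0 when the reference position is absent from the
    consensus (a deletion).  ``insertions`` lists consensus positions with no
    reference partner.
    """

    ref_to_cons: np.ndarray
    insertions: Tuple[int, ...]
    ref_length: int
    cons_length: int

    def __post_init__(self) -> None:
        matched = self.ref_to_cons[self.ref_to_cons > 0]
        if matched.size and not np.all(np.diff(matched) > 0):
            raise ValueError("matched consensus positions must be strictly increasing")
        n_cons = matched.size + len(self.insertions)
        if n_cons != self.cons_length:
            raise ValueError(
                "every consensus position must appear exactly once as matched or inserted"
            )

    @property
    def n_deleted(self) -> int:
        return int(np.count_nonzero(self.ref_to_cons == 0))

    @property
    def n_inserted(self) -> int:
        return len(self.insertions)

    def to_tsv(self, handle: TextIO) -> None:
        handle.write("# coordinates: 1-based, inclusive\n")
        handle.write(f"# insertions: {','.join(map(str, self.insertions)) or '.'}\n")
        handle.write(f"# cons_length: {self.cons_length}\n")
        handle.write("ref_pos\tcons_pos\tflag\n")
        for i, c in enumerate(self.ref_to_cons, start=1):
            if c > 0:
                handle.write(f"{i}\t{c}\tM\n")
            else:
                handle.write(f"{i}\t.\tDEL\n")

    @classmethod
    def from_tsv(cls, handle: TextIO) -> "CoordinateMap":
        insertions: Tuple[int, ...] = ()
        cons_length = None
        mapped: List[int] = []
        header_seen = False
        for line in handle:
            line = line.strip()
            if line.startswith("# insertions:"):
                val = line.split(":", 1)[1].strip()
                insertions = tuple(int(x) for x in val.split(",")) if val != "." else ()
                continue
            if line.startswith("# cons_length:"):
                cons_length = int(line.split(":", 1)[1])
                continue
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            _, cons_pos, flag = line.split("\t")
            mapped.append(int(cons_pos) if flag == "M" else 0)
        arr = np.array(mapped, dtype=np.int64)
        if cons_length is None:
            cons_length = int(np.count_nonzero(arr)) + len(insertions)
        return cls(arr, insertions, len(arr), cons_length)


def build_consensus(
    reads: Sequence[ReadRecord],
    initial_reference: str,
    relaxed: bool = False,
    max_iter: int = 5,
) -> ConsensusSequence:
    """Iterative majority-call consensus against a reference template.

    Reads are mapped (ungapped) to the current template, the most frequent
    non-N base is called per column (ties broken A < C < G < T), and mapping
    repeats against the new call until no base changes or ``max_iter``
    rounds.  Zero-coverage columns are marked unassembled (``N``).
    """
    template = initial_reference
    L = len(template)
    alignments: List[mp.ReadAlignment] = []
    for _ in range(max_iter):
        alignments = mp.map_reads_ungapped(reads, template, relaxed=relaxed)
        if not alignments:
            raise ValueError("empty assembly: no reads mapped to the template")
        counts = mp.pileup_counts(alignments, L)
        called = _majority_call(counts, template)
        if called == template:
            template = called
            break
        template = called
    counts = mp.pileup_counts(
        mp.map_reads_ungapped(reads, template, relaxed=relaxed), L
    )
    coverage = counts[:4].sum(axis=0)
    bases = "".join(
        b if cov > 0 else UNASSEMBLED for b, cov in zip(template, coverage)
    )
    return ConsensusSequence(bases, coverage)


def _majority_call(counts: np.ndarray, template: str) -> str:
    """Most frequent A/C/G/T per column; zero-coverage columns keep the
    template base so mapping in the next round still has a target."""
    acgt = counts[:4]
    # argmax returns the lowest index on ties, which is the A<C<G<T order
    best = acgt.argmax(axis=0)
    cov = acgt.sum(axis=0)
    return "".join(
        _BASE_ORDER[b] if c > 0 else t for b, c, t in zip(best, cov, template)
    )


def align_to_reference(
    consensus: ConsensusSequence | str,
    group_reference: str,
    min_identity_warn: float = 0.70,
) -> CoordinateMap:
    """Globally align the consensus to the group reference and derive the
    coordinate map.

    Affine-gap global alignment (match +1, mismatch -1, gap open -4, gap
    extend -1); the first optimal alignment is taken, which makes the map
    deterministic.  An alignment identity below ``min_identity_warn`` over
    matched columns triggers a non-homologous-assembly warning.
    """
    cons = consensus.bases if isinstance(consensus, ConsensusSequence) else consensus
    if not cons or not group_reference:
        raise ValueError("both sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aln = aligner.align(group_reference, cons)[0]
    ref_to_cons = np.zeros(len(group_reference), dtype=np.int64)
    matched_cons = set()
    n_match = n_col = 0
    for (r0, r1), (c0, c1) in zip(*aln.aligned):
        block_len = r1 - r0
        ref_to_cons[r0:r1] = np.arange(c0 + 1, c1 + 1)
        matched_cons.update(range(c0 + 1, c1 + 1))
        n_col += block_len
        for i in range(block_len):
            if group_reference[r0 + i] == cons[c0 + i]:
                n_match += 1
    if n_col == 0 or n_match / n_col < min_identity_warn:
        warnings.warn("possible non-homologous assembly: alignment identity "
                      f"{(n_match / n_col if n_col else 0.0):.2f}")
    insertions = tuple(
        p for p in range(1, len(cons) + 1) if p not in matched_cons
    )
    return CoordinateMap(ref_to_cons, insertions, len(group_reference), len(cons))
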