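"""Desk-scale read mapping onto an individual consensus.

An exhaustive ungapped scan over every offset (and the reverse complement)
with per-length mismatch caps modelled on short-read mapper defaults: a
standard scheme allows 3 mismatches in an 80 bp read and 4 in a 100 bp read,
a relaxed scheme allows 4 and 5.  A gapped mode additionally permits one
insertion or deletion of up to ``max_indel`` bases.  Reads whose best
placement is tied between distinct offsets are discarded as ambiguous rather
than placed at random — a deterministic divergence from BWA's behaviour.

Alignments can also be imported from, and exported to, SAM for use with an
external mapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .preprocess import ReadRecord

__all__ = [
    "ReadAlignment",
    "max_mismatches",
    "map_reads_ungapped",
    "map_reads_gapped",
    "import_alignments",
    "write_sam",
    "pileup_counts",
    "encode",
]

# base encoding: A=0 C=1 G=2 T=3 N=4 (anything else also maps to 4)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadAlignment:
    """One read placed on the consensus.

    ``seq`` is the read oriented to the target strand; ``target_start`` is
    1-based.  ``cigar`` is a list of (op, length) with ops M/I/D covering the
    read.  ``indels`` lists (target_position, length, kind, bases) where for
    insertions ``target_position`` is the matched base immediately left of
    the event and ``bases`` the inserted read bases.
    """

    read_id: str
    target_start: int
    strand: str  # '+' | '-'
    seq: str
    n_mismatch: int
    cigar: List[Tuple[str, int]]
    indels: List[Tuple[int, int, str, str]] = field(default_factory=list)

    @property
    def target_end(self) -> int:
        """1-based inclusive end on the target."""
        span = sum(n for op, n in self.cigar if op in "MD")
        return self.target_start + span - 1

    def aligned_pairs(self) -> List[Tuple[Optional[int], Optional[int]]]:
        """(read_index, target_index) pairs, 0-based, None on the gapped side."""
        pairs: List[Tuple[Optional[int], Optional[int]]] = []
        r, t = 0, self.target_start - 1
        for op, n in self.cigar:
            if op == "M":
                pairs.extend((r + k, t + k) for k in range(n))
                r += n
                t += n
            elif op == "I":
                pairs.extend((r + k, None) for k in range(n))
                r += n
            elif op == "D":
                pairs.extend((None, t + k) for k in range(n))
                t += n
            else:  # pragma: no cover - constructors only emit M/I/D
                raise ValueError(f"unexpected CIGAR op {op}")
        return pairs


def max_mismatches(read_length: int, relaxed: bool = False) -> int:
    """Mismatch cap for a read of the given length.

    Piecewise-constant with the mapper-default anchors 80 bp -> 3 (standard)
    / 4 (relaxed) and 100 bp -> 4 / 5; short reads (< 50 bp) get 2.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if read_length < 50:
        return 2
    if read_length < 90:
        return 4 if relaxed else 3
    return 5 if relaxed else 4


def _oriented(read: Union[ReadRecord, Tuple[str, str]]) -> Tuple[str, str]:
    if isinstance(read, ReadRecord):
        return read.id, read.bases
    return read  # (id, bases)


def _mismatch_profile(cons_windows: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Mismatch count of read ``r`` at every offset; N in the read is ignored."""
    return ((cons_windows != r) & (r != 4)).sum(axis=1)


def map_reads_ungapped(
    reads: Iterable[Union[ReadRecord, Tuple[str, str]]],
    consensus: str,
    relaxed: bool = False,
    both_strands: bool = True,
) -> List[ReadAlignment]:
    """Exhaustively place each read (and its reverse complement) at every
    offset, keeping the unique fewest-mismatch placement if it meets the cap.

    Reads with tied best placements at distinct offsets/strands are discarded
    as ambiguous.  Reads longer than the consensus are unmapped.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    cons = encode(consensus)
    L = cons.size
    windows_cache: dict = {}
    out: List[ReadAlignment] = []
    for read in reads:
        read_id, bases = _oriented(read)
        m = len(bases)
        if m == 0 or m > L:
            continue
        if m not in windows_cache:
            windows_cache[m] = np.lib.stride_tricks.sliding_window_view(cons, m)
        win = windows_cache[m]
        cap = max_mismatches(m, relaxed)
        candidates = []  # (n_mismatch, offset, strand, oriented_seq)
        strands = ("+", "-") if both_strands else ("+",)
        for strand in strands:
            oriented = bases if strand == "+" else revcomp(bases)
            mm = _mismatch_profile(win, encode(oriented))
            best = int(mm.min())
            if best <= cap:
                for off in np.flatnonzero(mm == best):
                    candidates.append((best, int(off), strand, oriented))
        if not candidates:
            continue
        lowest = min(c[0] for c in candidates)
        winners = [c for c in candidates if c[0] == lowest]
        if len(winners) > 1:
            continue  # ambiguous placement
        n_mm, off, strand, oriented = winners[0]
        out.append(
            ReadAlignment(read_id, off + 1, strand, oriented, n_mm, [("M", m)])
        )
    return out


def map_reads_gapped(
    reads: Iterable[Union[ReadRecord, Tuple[str, str]]],
    consensus: str,
    relaxed: bool = False,
    max_indel: int = 5,
    both_strands: bool = True,
) -> List[ReadAlignment]:
    """Like :func:`map_reads_ungapped` but placements may contain one gap of
    up to ``max_indel`` bases on either the read (insertion) or the target
    (deletion) side.

    Score = mismatches + 1 per gap opened (gap length is free up to the
    bound); mismatches must still meet the per-length cap.  An ungapped
    placement wins ties against gapped ones.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    if max_indel < 1:
        raise ValueError("max_indel must be >= 1")
    cons = encode(consensus)
    L = cons.size
    out: List[ReadAlignment] = []
    for read in reads:
        read_id, bases = _oriented(read)
        m = len(bases)
        if m == 0 or m > L:
            continue
        cap = max_mismatches(m, relaxed)
        win = np.lib.stride_tricks.sliding_window_view(cons, m)
        # candidate: (score, n_mismatch, offset, strand, seq, cigar, indels)
        ungapped: List[tuple] = []
        gapped: List[tuple] = []
        strands = ("+", "-") if both_strands else ("+",)
        for strand in strands:
            oriented = bases if strand == "+" else revcomp(bases)
            r = encode(oriented)
            M = (win != r) & (r != 4)  # (L - m + 1, m) mismatch matrix
            # C[s, k] = mismatches of read[:k] at offset s
            C = np.zeros((M.shape[0], m + 1), dtype=np.int32)
            np.cumsum(M, axis=1, out=C[:, 1:])
            mm = C[:, m]
            bu = int(mm.min())
            if bu <= cap:
                for off in np.flatnonzero(mm == bu):
                    ungapped.append(
                        (bu, bu, int(off), strand, oriented, [("M", m)], [])
                    )
            n_off = M.shape[0]
            for g in range(1, max_indel + 1):
                # deletion of g target bases after read position k (1..m-1)
                smax = L - m - g  # inclusive max start
                if smax >= 0:
                    s = np.arange(smax + 1)
                    # prefix C[s, k] + suffix (C[s+g, m] - C[s+g, k])
                    tot = C[s, :][:, 1:m] + (mm[s + g, None] - C[s + g, 1:m])
                    _collect_gap_candidates(
                        gapped, tot, s, cap, strand, oriented, g, "del", m
                    )
                # insertion of g read bases starting at read position k
                s = np.arange(g, min(L - (m - g), n_off - 1) + 1)
                if s.size:
                    ks = np.arange(1, m - g)  # internal split points
                    if ks.size:
                        tot = C[s, :][:, ks] + (mm[s - g, None] - C[s - g, :][:, ks + g])
                        _collect_gap_candidates(
                            gapped, tot, s, cap, strand, oriented, g, "ins", m
                        )
        ubest = min((c[0] for c in ungapped), default=np.inf)
        gbest = min((c[0] for c in gapped), default=np.inf)
        if ungapped and ubest <= gbest:  # ungapped preferred on ties
            winners = [c for c in ungapped if c[0] == ubest]
            if len(winners) > 1:
                continue  # ambiguous placement
            chosen = winners[0]
        elif gapped:
            winners = [c for c in gapped if c[0] == gbest]
            starts = {(c[2], c[3]) for c in winners}
            if len(starts) > 1:
                continue  # ambiguous placement
            # same offset/strand: canonical choice = leftmost split, del first
            winners.sort(key=lambda c: (c[5][0][1], c[6][0][2] == "ins"))
            chosen = winners[0]
        else:
            continue
        score, n_mm, off, strand, oriented, cigar, indels = chosen
        out.append(ReadAlignment(read_id, off + 1, strand, oriented, n_mm, cigar, indels))
    return out


def _collect_gap_candidates(acc, tot, s_arr, cap, strand, oriented, g, kind, m):
    """Append qualifying single-gap placements from a (offset x split) mismatch
    total matrix; score = mismatches + 1 for the opened gap."""
    best = int(tot.min()) if tot.size else np.iinfo(np.int32).max
    if best > cap:
        return
    cur = min((c[0] for c in acc), default=np.iinfo(np.int32).max)
    if best + 1 > cur:
        # cannot improve on what we already hold; still record equal scores
        if best + 1 != cur:
            return
    for i, j in zip(*np.nonzero(tot == best)):
        off = int(s_arr[i])
        k = int(j) + 1  # split after k read bases (dels) / before insert (ins)
        if kind == "del":
            cigar = [("M", k), ("D", g), ("M", m - k)]
            indels = [(off + k, g, "del", "")]
        else:
            cigar = [("M", k), ("I", g), ("M", m - k - g)]
            indels = [(off + k, g, "ins", oriented[k : k + g])]
        acc.append((best + 1, best, off, strand, oriented, cigar, indels))


def import_alignments(sam_source, consensus_name: str) -> List[ReadAlignment]:
    """Convert SAM records (path or pysam-compatible stream) targeting
    ``consensus_name`` into :class:`ReadAlignment` objects.

    Unmapped, secondary and supplementary records are skipped; soft-clipped
    ends are trimmed; records with unsupported CIGAR ops are skipped with a
    warning.  A record mapped to a different reference raises.
    """
    out: List[ReadAlignment] = []
    with pysam.AlignmentFile(sam_source, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name != consensus_name:
                raise ValueError(
                    f"record {rec.query_name} mapped to {rec.reference_name!r}, "
                    f"expected {consensus_name!r}"
                )
            cig = rec.cigartuples or []
            ops = {op for op, _ in cig}
            # 0=M 1=I 2=D 4=S 7='=' 8=X
            if not ops <= {0, 1, 2, 4, 7, 8}:
                warnings.warn(
                    f"record {rec.query_name}: unsupported CIGAR op, skipped"
                )
                continue
            seq = rec.query_sequence or ""
            # trim soft clips
            if cig and cig[0][0] == 4:
                seq = seq[cig[0][1]:]
                cig = cig[1:]
            if cig and cig[-1][0] == 4:
                seq = seq[: len(seq) - cig[-1][1]]
                cig = cig[:-1]
            cigar: List[Tuple[str, int]] = []
            for op, n in cig:
                sym = {0: "M", 7: "M", 8: "M", 1: "I", 2: "D"}[op]
                if cigar and cigar[-1][0] == sym:
                    cigar[-1] = (sym, cigar[-1][1] + n)
                else:
                    cigar.append((sym, n))
            indels: List[Tuple[int, int, str, str]] = []
            t = rec.reference_start  # 0-based
            r = 0
            for sym, n in cigar:
                if sym == "M":
                    t += n
                    r += n
                elif sym == "D":
                    indels.append((t, n, "del", ""))
                    t += n
                else:
                    indels.append((t, n, "ins", seq[r : r + n]))
                    r += n
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            n_mismatch = max(0, int(nm) - sum(n for _, n, _, _ in indels))
            out.append(
                ReadAlignment(
                    rec.query_name,
                    rec.reference_start + 1,
                    "-" if rec.is_reverse else "+",
                    seq,
                    n_mismatch,
                    cigar,
                    indels,
                )
            )
    return out


def write_sam(
    alignments: Iterable[ReadAlignment],
    consensus: str,
    consensus_name: str,
    path,
) -> None:
    """Export alignments as SAM against the given consensus sequence."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": consensus_name, "LN": len(consensus)}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as sam:
        for aln in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = aln.read_id
            rec.query_sequence = aln.seq
            rec.flag = 16 if aln.strand == "-" else 0
            rec.reference_id = 0
            rec.reference_start = aln.target_start - 1
            rec.mapping_quality = 255
            rec.cigartuples = [
                ({"M": 0, "I": 1, "D": 2}[op], n) for op, n in aln.cigar
            ]
            rec.set_tag("NM", aln.n_mismatch + sum(n for _, n, _, _ in aln.indels))
            sam.write(rec)


def pileup_counts(
    alignments: Iterable[ReadAlignment], target_length: int
) -> np.ndarray:
    """Per-position base counts from alignments: array of shape (5, L) with
    rows A, C, G, T, N in target coordinates (0-based rows of the array map
    to 1-based target positions)."""
    counts = np.zeros((5, target_length), dtype=np.int64)
    for aln in alignments:
        codes = encode(aln.seq)
        if len(aln.cigar) == 1 and aln.cigar[0][0] == "M":
            t0 = aln.target_start - 1
            m = aln.cigar[0][1]
            np.add.at(counts, (codes[:m], np.arange(t0, t0 + m)), 1)
        else:
            for r_idx, t_idx in aln.aligned_pairs():
                if r_idx is not None and t_idx is not None:
                    counts[codes[r_idx], t_idx] += 1
    return counts
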