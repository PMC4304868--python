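"""Per-position polymorphism detection among copies of a high-copy locus.

The core computation: at every consensus position, tally the reads differing
from the consensus call; positions where 2% or more of reads differ are
polymorphic, and 10% or more highly polymorphic (both cutoffs inclusive).
Tallies are computed in consensus space and projected into group-reference
coordinates, discarding insertions relative to the reference so homologous
positions stay aligned across individuals.  N-masked bases carry no call and
are excluded from both numerator and denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, TextIO, Tuple

import numpy as np
import pandas as pd

from . import mapping as mp
from .consensus_map import ConsensusSequence, CoordinateMap
from .synth import RegionInterval

__all__ = [
    "SiteStatus",
    "Thresholds",
    "PositionTally",
    "PolymorphismProfile",
    "tally_column",
    "classify_site",
    "classify_fractions",
    "profile_sample",
    "count_indel_polymorphisms",
    "cross_sample_matrix",
    "CrossSampleMatrix",
    "maf_screen",
]

_BASES = "ACGT"


class SiteStatus(enum.IntEnum):
    UNASSEMBLED = 0
    MONO = 1
    POLY = 2
    HIGH = 3


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs as fractions of reads differing from the
    consensus; both are inclusive ("2% or more", "10% or more")."""

    poly: float = 0.02
    high: float = 0.10
    min_coverage: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.poly <= self.high <= 1:
            raise ValueError("need 0 < poly <= high <= 1")


@dataclass(frozen=True)
class PositionTally:
    """Base counts at one consensus position.

    N-masked bases are excluded from ``coverage`` but recorded in ``n_count``.
    The consensus call is the most frequent base (ties broken A < C < G < T);
    ``differing_fraction`` pools every non-consensus base and is None when
    the position has no coverage.
    """

    counts: Mapping[str, int]
    n_count: int = 0

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())

    @property
    def consensus_base(self) -> Optional[str]:
        if self.coverage == 0:
            return None
        return max(_BASES, key=lambda b: self.counts.get(b, 0))

    @property
    def differing_fraction(self) -> Optional[float]:
        cov = self.coverage
        if cov == 0:
            return None
        return (cov - self.counts.get(self.consensus_base, 0)) / cov


def tally_column(bases: Iterable[str]) -> PositionTally:
    """Tally one pileup column of base calls (A/C/G/T/N)."""
    counts = {b: 0 for b in _BASES}
    n = 0
    for b in bases:
        b = b.upper()
        if b == "N":
            n += 1
        elif b in counts:
            counts[b] += 1
        else:
            raise ValueError(f"unexpected base {b!r}")
    return PositionTally(counts, n)


def classify_site(tally: PositionTally, thresholds: Thresholds = Thresholds()) -> SiteStatus:
    """Classify one position from its tally (inclusive 2%/10% cutoffs)."""
    cov = tally.coverage
    if cov == 0 or cov < thresholds.min_coverage:
        return SiteStatus.UNASSEMBLED
    frac = tally.differing_fraction
    if frac >= thresholds.high:
        return SiteStatus.HIGH
    if frac >= thresholds.poly:
        return SiteStatus.POLY
    return SiteStatus.MONO


def classify_fractions(
    coverage: np.ndarray, fractions: np.ndarray, thresholds: Thresholds = Thresholds()
) -> np.ndarray:
    """Vectorized :func:`classify_site` over per-position coverage/fraction arrays."""
    status = np.full(coverage.shape, SiteStatus.MONO, dtype=np.int8)
    assembled = (coverage > 0) & (coverage >= thresholds.min_coverage)
    status[~assembled] = SiteStatus.UNASSEMBLED
    with np.errstate(invalid="ignore"):
        status[assembled & (fractions >= thresholds.poly)] = SiteStatus.POLY
        status[assembled & (fractions >= thresholds.high)] = SiteStatus.HIGH
    return status


@dataclass
class PolymorphismProfile:
    """Per-reference-position polymorphism status for one sample.

    ``status`` and ``differing_fraction`` are reference-length arrays
    (fraction is NaN where unassembled).  Percentages are taken over
    sequenced (assembled) positions only.
    """

    sample_id: str
    status: np.ndarray
    differing_fraction: np.ndarray

    def __post_init__(self) -> None:
        if len(self.status) != len(self.differing_fraction):
            raise ValueError("status/fraction length mismatch")

    @property
    def ref_length(self) -> int:
        return len(self.status)

    @property
    def n_sequenced(self) -> int:
        return int(np.count_nonzero(self.status != SiteStatus.UNASSEMBLED))

    @property
    def n_poly(self) -> int:
        return int(np.count_nonzero(self.status >= SiteStatus.POLY))

    @property
    def n_high(self) -> int:
        return int(np.count_nonzero(self.status == SiteStatus.HIGH))

    @property
    def pct_poly(self) -> float:
        n = self.n_sequenced
        return 100.0 * self.n_poly / n if n else 0.0

    @property
    def pct_high(self) -> float:
        n = self.n_sequenced
        return 100.0 * self.n_high / n if n else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ref_pos": np.arange(1, self.ref_length + 1),
                "status": [SiteStatus(s).name for s in self.status],
                "fraction": self.differing_fraction,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_id: str = "sample") -> "PolymorphismProfile":
        status = np.array([SiteStatus[s] for s in frame["status"]], dtype=np.int8)
        return cls(sample_id, status, frame["fraction"].to_numpy(dtype=float))


def _tallies_from_alignments(
    alignments: Sequence[mp.ReadAlignment], length: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(coverage, differing_fraction, consensus_call_codes) per consensus
    position, pooled over all non-consensus bases."""
    counts = mp.pileup_counts(alignments, length)
    acgt = counts[:4]
    coverage = acgt.sum(axis=0)
    call = acgt.argmax(axis=0)  # ties resolve to A<C<G<T via argmax
    top = np.take_along_axis(acgt, call[None, :], axis=0)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(coverage > 0, (coverage - top) / np.maximum(coverage, 1), np.nan)
    return coverage, frac, call


def profile_sample(
    alignments: Sequence[mp.ReadAlignment],
    consensus: ConsensusSequence | str,
    coordmap: CoordinateMap,
    thresholds: Thresholds = Thresholds(),
    sample_id: str = "sample",
) -> PolymorphismProfile:
    """Tally differing reads per consensus position and project the calls
    into group-reference coordinates.

    Consensus positions that are insertions relative to the reference are
    dropped; reference positions deleted in the consensus (no partner) are
    unassembled — zero reads called a base there.
    """
    cons_len = len(consensus) if not isinstance(consensus, str) else len(consensus)
    if cons_len != coordmap.cons_length:
        raise ValueError("coordinate map does not match consensus length")
    coverage, frac, _ = _tallies_from_alignments(alignments, cons_len)
    cons_status = classify_fractions(coverage, frac, thresholds)
    L = coordmap.ref_length
    status = np.full(L, SiteStatus.UNASSEMBLED, dtype=np.int8)
    fractions = np.full(L, np.nan)
    matched = coordmap.ref_to_cons > 0
    cons_idx = coordmap.ref_to_cons[matched] - 1
    status[matched] = cons_status[cons_idx]
    fractions[matched] = frac[cons_idx]
    return PolymorphismProfile(sample_id, status, fractions)


def count_indel_polymorphisms(
    alignments: Sequence[mp.ReadAlignment],
    consensus: ConsensusSequence | str,
    thresholds: Thresholds = Thresholds(),
) -> int:
    """Count consensus positions carrying a polymorphic indel.

    Reads supporting an identical indel (same start, length, kind and, for
    insertions, inserted bases) are pooled; the indel is polymorphic when its
    supporters are at least the ``poly`` fraction of reads covering the
    position.  Returns the number of distinct positions with at least one
    qualifying indel.
    """
    length = len(consensus)
    support: Dict[Tuple[int, int, str, str], int] = {}
    cover = np.zeros(length + 2, dtype=np.int64)
    for aln in alignments:
        cover[aln.target_start] += 1
        cover[aln.target_end + 1] -= 1
        for key in aln.indels:
            support[key] = support.get(key, 0) + 1
    depth = np.cumsum(cover)[1 : length + 1]  # depth[i] = reads covering pos i+1
    positions = set()
    for (pos, _glen, _kind, _bases), n in support.items():
        p = min(max(pos, 1), length)
        cov = int(depth[p - 1])
        if cov > 0 and n / cov >= thresholds.poly:
            positions.add(pos)
    return len(positions)


@dataclass
class CrossSampleMatrix:
    """Per-reference-position counts of samples polymorphic / highly
    polymorphic at the position."""

    poly_counts: np.ndarray
    high_counts: np.ndarray
    n_profiles: int

    def fraction_any_poly(self) -> float:
        """Fraction of reference positions polymorphic in >= 1 sample."""
        return float(np.mean(self.poly_counts >= 1)) if self.poly_counts.size else 0.0

    def region_fractions(
        self, regions: Sequence[RegionInterval], high: bool = False
    ) -> Dict[str, float]:
        """Per-region fraction of positions polymorphic (or highly
        polymorphic) in at least one sample."""
        counts = self.high_counts if high else self.poly_counts
        out = {}
        for iv in regions:
            seg = counts[iv.start - 1 : iv.end]
            out[iv.name] = float(np.mean(seg >= 1)) if seg.size else 0.0
        return out


def cross_sample_matrix(profiles: Sequence[PolymorphismProfile]) -> CrossSampleMatrix:
    """Aggregate per-sample profiles into per-position sample counts.

    Unassembled positions contribute nothing.  All profiles must share one
    reference length.
    """
    if not profiles:
        return CrossSampleMatrix(np.zeros(0, dtype=int), np.zeros(0, dtype=int), 0)
    L = profiles[0].ref_length
    if any(p.ref_length != L for p in profiles):
        raise ValueError("profiles have mixed reference lengths")
    poly = np.zeros(L, dtype=np.int64)
    high = np.zeros(L, dtype=np.int64)
    for p in profiles:
        poly += (p.status >= SiteStatus.POLY).astype(np.int64)
        high += (p.status == SiteStatus.HIGH).astype(np.int64)
    return CrossSampleMatrix(poly, high, len(profiles))


def maf_screen(
    profile: PolymorphismProfile, maf_threshold: float
) -> List[Tuple[int, float]]:
    """Reference positions whose minor (non-consensus) allele fraction meets
    the threshold; elevated profiles can flag hybrid or mixed ancestry.

    Returns (1-based position, differing_fraction) pairs.
    """
    frac = profile.differing_fraction
    ok = (profile.status != SiteStatus.UNASSEMBLED) & (
        np.nan_to_num(frac, nan=-1.0) >= maf_threshold
    )
    return [(int(i) + 1, float(frac[i])) for i in np.flatnonzero(ok)]


def summary_row(profile: PolymorphismProfile) -> Dict[str, object]:
    """One summary-table row (sample, Poly #, Poly %, High #, High %)."""
    return {
        "sample": profile.sample_id,
        "poly_n": profile.n_poly,
        "poly_pct": profile.pct_poly,
        "high_n": profile.n_high,
        "high_pct": profile.pct_high,
    }
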