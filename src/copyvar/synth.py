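"""Synthetic fixtures with known ground truth.

The generator emulates the data a genome-skimming study of a high-copy locus
produces: an nrDNA-like locus laid out as 18S-ITS1-5.8S-ITS2-26S, a pool of
nearly identical copies (default 960, the estimated nrDNA copy number in
*Asclepias syriaca*) with variants planted at chosen frequencies, uniform-error
single-end short reads at a chosen fold-coverage (the study's locus coverage
was ~97x with 80 bp reads), and trees with traits evolved under
lambda-scaled Brownian motion bounded below at zero.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, TextIO, Tuple

import numpy as np

from .preprocess import ReadRecord

__all__ = [
    "REGION_ORDER",
    "SUBUNIT_REGIONS",
    "RegionInterval",
    "VariantSpec",
    "IndelSpec",
    "CopyPool",
    "ReadSimParams",
    "make_locus",
    "make_copy_pool",
    "sequence_reads",
    "make_tree_and_traits",
    "write_fasta",
    "write_regions_tsv",
    "write_variants_tsv",
]

REGION_ORDER: Tuple[str, ...] = ("18S", "ITS1", "5.8S", "ITS2", "26S")
SUBUNIT_REGIONS = frozenset({"18S", "5.8S", "26S"})

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RegionInterval:
    """One cistron region as a 1-based inclusive interval on the locus."""

    name: str
    start: int
    end: int

    @property
    def region_class(self) -> str:
        return "subunit" if self.name in SUBUNIT_REGIONS else "spacer"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class VariantSpec:
    """A substitution present in a subset of copies.

    position is 1-based on the locus; frequency is the fraction of copies
    carrying alt_base.
    """

    position: int
    alt_base: str
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")
        if self.alt_base not in "ACGT":
            raise ValueError(f"alt_base must be one of A/C/G/T, got {self.alt_base!r}")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")


@dataclass(frozen=True)
class IndelSpec:
    """A copy-level indel (<= 5 bp by convention) at a given frequency.

    For an insertion, ``bases`` are inserted after ``position``; for a
    deletion, ``length`` bases starting at ``position`` are removed.
    """

    position: int
    kind: str  # "ins" | "del"
    length: int
    frequency: float
    bases: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ins", "del"):
            raise ValueError("kind must be 'ins' or 'del'")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind == "ins" and len(self.bases) != self.length:
            raise ValueError("insertion bases must match length")


@dataclass
class CopyPool:
    """An ordered pool of locus copies (substitution variants keep all copies
    equal length; planted indels may not)."""

    copies: List[str]
    locus: str
    variants: Tuple[VariantSpec, ...] = ()
    indels: Tuple[IndelSpec, ...] = ()

    @property
    def n_copies(self) -> int:
        return len(self.copies)


@dataclass(frozen=True)
class ReadSimParams:
    """Read-simulation settings.

    coverage: mean fold-coverage of the locus.
    read_length: bases per single-end read.
    error_rate: per-base probability of a uniform substitution error.
    quality: constant Phred value assigned to every base, or use
        ``low_q_fraction`` > 0 for a two-level model where that fraction of
        bases (chosen uniformly) gets ``low_q`` instead.
    """

    coverage: float = 97.0
    read_length: int = 80
    error_rate: float = 0.0
    quality: int = 40
    low_q: int = 10
    low_q_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


def make_locus(
    region_lengths: Mapping[str, int], seed: int = 0
) -> Tuple[str, List[RegionInterval]]:
    """Generate a random locus with the five cistron regions in canonical order.

    Returns the sequence and a list of 1-based inclusive intervals covering
    every position exactly once, in the order 18S, ITS1, 5.8S, ITS2, 26S.
    """
    missing = [r for r in REGION_ORDER if r not in region_lengths]
    if missing:
        raise ValueError(f"missing region lengths for: {missing}")
    for name in REGION_ORDER:
        if region_lengths[name] < 1:
            raise ValueError(f"region {name} has non-positive length")
    rng = np.random.default_rng(seed)
    total = sum(region_lengths[r] for r in REGION_ORDER)
    seq = rng.choice(_BASES, size=total).tobytes().decode("ascii")
    intervals: List[RegionInterval] = []
    pos = 1
    for name in REGION_ORDER:
        n = region_lengths[name]
        intervals.append(RegionInterval(name, pos, pos + n - 1))
        pos += n
    return seq, intervals


def make_copy_pool(
    locus: str,
    variants: Sequence[VariantSpec] = (),
    n_copies: int = 960,
    seed: int = 0,
    indels: Sequence[IndelSpec] = (),
) -> CopyPool:
    """Plant variants into a pool of ``n_copies`` copies of the locus.

    Exactly ``round(frequency * n_copies)`` copies carry each alt base; which
    copies carry it is randomized by the seed, independently per site.
    Optional copy-level indels are planted the same way (applied from the
    highest position down so coordinates stay valid).
    """
    L = len(locus)
    positions = [v.position for v in variants]
    if len(set(positions)) != len(positions):
        raise ValueError("variant positions must be unique")
    for v in variants:
        if v.position > L:
            raise ValueError(f"variant position {v.position} beyond locus length {L}")
        if v.alt_base == locus[v.position - 1]:
            raise ValueError(
                f"alt_base at position {v.position} equals the reference base"
            )
    rng = np.random.default_rng(seed)
    arr = np.tile(np.frombuffer(locus.encode("ascii"), dtype=np.uint8), (n_copies, 1))
    for v in variants:
        k = int(round(v.frequency * n_copies))
        carriers = rng.choice(n_copies, size=k, replace=False)
        arr[carriers, v.position - 1] = ord(v.alt_base)
    copies = [row.tobytes().decode("ascii") for row in arr]
    for spec in sorted(indels, key=lambda s: -s.position):
        k = int(round(spec.frequency * n_copies))
        carriers = rng.choice(n_copies, size=k, replace=False)
        for i in carriers:
            c = copies[i]
            if spec.kind == "ins":
                copies[i] = c[: spec.position] + spec.bases + c[spec.position :]
            else:
                copies[i] = c[: spec.position - 1] + c[spec.position - 1 + spec.length :]
    return CopyPool(copies, locus, tuple(variants), tuple(indels))


def sequence_reads(pool: CopyPool, params: ReadSimParams) -> List[ReadRecord]:
    """Simulate uniform-coverage single-end reads from a copy pool.

    Each read is drawn from a uniformly chosen copy at a uniform start
    position (no wrap-around, so locus edges get lower coverage, as in real
    shotgun data).  Each base is flipped to a uniformly chosen different base
    with probability ``error_rate``.  The number of reads is
    ``round(coverage * locus_length / read_length)``.
    """
    m = params.read_length
    L = len(pool.locus)
    if m > L:
        raise ValueError(f"read_length {m} exceeds locus length {L}")
    rng = np.random.default_rng(params.seed)
    n_reads = int(round(params.coverage * L / m))
    reads: List[ReadRecord] = []
    copy_idx = rng.integers(0, pool.n_copies, size=n_reads)
    for i in range(n_reads):
        copy = pool.copies[copy_idx[i]]
        start = int(rng.integers(0, len(copy) - m + 1))
        bases = np.frombuffer(copy[start : start + m].encode("ascii"), dtype=np.uint8).copy()
        if params.error_rate > 0:
            err = rng.random(m) < params.error_rate
            if err.any():
                # uniform choice among the three other bases
                idx = np.flatnonzero(err)
                cur = bases[idx]
                shift = rng.integers(1, 4, size=idx.size)
                code = np.searchsorted(_BASES, cur)  # _BASES is sorted (ACGT)
                bases[idx] = _BASES[(code + shift) % 4]
        quals = np.full(m, params.quality, dtype=int)
        if params.low_q_fraction > 0:
            low = rng.random(m) < params.low_q_fraction
            quals[low] = params.low_q
        reads.append(
            ReadRecord(f"read_{i}", bases.tobytes().decode("ascii"), tuple(int(q) for q in quals))
        )
    return reads


def make_tree_and_traits(
    n_tips: int,
    lam: float = 1.0,
    sigma2: float = 1.0,
    root_state: float = 0.0,
    seed: int = 0,
):
    """Random bifurcating tree plus one trait value per tip.

    The topology is built by sequential random joins; every edge gets an
    Exponential(1) length.  Traits evolve under Brownian motion with rate
    ``sigma2`` on the lambda-transformed tree, reflected at zero (counts
    cannot go negative).  Returns a :class:`~copyvar.phylo_signal.PhyloTrait`.
    """
    from . import phylo_signal as ps

    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if root_state < 0:
        raise ValueError("root_state must be within the [0, inf) bounds")
    rng = np.random.default_rng(seed)
    tree = random_bifurcating_tree(n_tips, rng)
    transformed = ps.lambda_transform(tree, lam)
    sims, labels = ps.simulate_bm_bounded(
        transformed, sigma2, root_state, n_sims=1, seed=int(rng.integers(2**31))
    )
    values = dict(zip(labels, (float(x) for x in sims[0])))
    return ps.PhyloTrait(tree=tree, values=values)


def random_bifurcating_tree(n_tips: int, rng: np.random.Generator):
    """Random bifurcating dendropy tree: sequential random joins,
    Exponential(1) branch lengths."""
    import dendropy

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(1, n_tips + 1)])
    nodes = []
    for tax in taxa:
        leaf = dendropy.Node(taxon=tax)
        leaf.edge.length = float(rng.exponential(1.0))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(1.0))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = nodes[0]
    root.edge.length = None
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# writers


def write_fasta(records: Iterable[Tuple[str, str]], handle: TextIO, width: int = 70) -> None:
    for name, seq in records:
        handle.write(f">{name}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")


def write_regions_tsv(intervals: Sequence[RegionInterval], handle: TextIO) -> None:
    """Region intervals as TSV with 1-based inclusive coordinates (not UCSC BED)."""
    handle.write("# coordinates: 1-based, inclusive\n")
    handle.write("name\tstart\tend\tclass\n")
    for iv in intervals:
        handle.write(f"{iv.name}\t{iv.start}\t{iv.end}\t{iv.region_class}\n")


def read_regions_tsv(handle: TextIO) -> List[RegionInterval]:
    """Read a region-interval TSV (1-based inclusive; comment lines ignored)."""
    intervals: List[RegionInterval] = []
    header_seen = False
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        name, start, end = line.split("\t")[:3]
        intervals.append(RegionInterval(name, int(start), int(end)))
    return intervals


def write_variants_tsv(variants: Sequence[VariantSpec], handle: TextIO) -> None:
    handle.write("position\talt_base\tfrequency\n")
    for v in variants:
        handle.write(f"{v.position}\t{v.alt_base}\t{v.frequency}\n")
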