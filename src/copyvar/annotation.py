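"""Region and secondary-structure annotation of reference positions.

Every reference position gets a cistron region label (18S/ITS1/5.8S/ITS2/26S,
classed as subunit or spacer) and a pairing state (paired = stem, unpaired =
loop) read from minimum-free-energy structures in dot-bracket notation.
Structures are consumed, not predicted: each record is three lines — region
name, sequence, then the dot-bracket string followed by its MFE in kcal/mol,
e.g. ``((..)) (-1.20)``.  Co-folded regions (the 5.8S and 26S are typically
folded together) keep both strands in one record, separated by ``&`` at the
same index of the sequence and structure lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, TextIO, Tuple

import pandas as pd

from .synth import RegionInterval, SUBUNIT_REGIONS

__all__ = [
    "StructureRecord",
    "SiteAnnotation",
    "parse_structure_file",
    "annotate_sites",
]

_MFE_RE = re.compile(r"^(?P<struct>\S+)\s*\(\s*(?P<mfe>-?\d+(?:\.\d+)?)\s*\)\s*$")


@dataclass(frozen=True)
class StructureRecord:
    """One region's predicted structure: name, sequence (U and T equivalent),
    dot-bracket string and minimum free energy (kcal/mol, metadata only)."""

    name: str
    sequence: str
    dotbracket: str
    mfe: float

    @property
    def strands(self) -> Tuple[str, ...]:
        """Dot-bracket split at the co-fold separator."""
        return tuple(self.dotbracket.split("&"))

    def pairing(self) -> List[bool]:
        """True where paired (stem), per position, separators removed."""
        return [c in "()" for c in self.dotbracket if c != "&"]


@dataclass(frozen=True)
class SiteAnnotation:
    """Region and pairing labels for one 1-based reference position."""

    position: int
    region: str
    region_class: str
    pairing: str  # "paired" | "unpaired"


def _validate_record(name: str, seq: str, struct: str) -> None:
    if any(c in "[]{}" for c in struct):
        raise ValueError(f"record {name!r}: pseudoknot symbols are not supported")
    bad = set(struct) - set("().&")
    if bad:
        raise ValueError(f"record {name!r}: unexpected structure symbols {sorted(bad)}")
    if len(seq) != len(struct):
        raise ValueError(
            f"record {name!r}: sequence length {len(seq)} != structure length {len(struct)}"
        )
    for i, (b, s) in enumerate(zip(seq, struct)):
        if (b == "&") != (s == "&"):
            raise ValueError(
                f"record {name!r}: '&' separator mismatch at index {i}"
            )
    seq_letters = set(seq.upper().replace("&", ""))
    if not seq_letters <= set("ACGTUN"):
        raise ValueError(f"record {name!r}: non-nucleotide characters in sequence")
    depth = 0
    for c in struct:
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"record {name!r}: unbalanced brackets")
    if depth != 0:
        raise ValueError(f"record {name!r}: unbalanced brackets")


def parse_structure_file(stream: Iterable[str]) -> List[StructureRecord]:
    """Parse three-line structure records (name / sequence / dot-bracket with
    trailing MFE)."""
    lines = [ln.strip() for ln in stream if ln.strip()]
    if len(lines) % 3 != 0:
        raise ValueError("structure file must consist of 3-line records")
    records: List[StructureRecord] = []
    for i in range(0, len(lines), 3):
        name = lines[i].lstrip(">").strip()
        seq = lines[i + 1]
        m = _MFE_RE.match(lines[i + 2])
        if m is None:
            raise ValueError(
                f"record {name!r}: structure line must end with '(<MFE>)'"
            )
        struct = m.group("struct")
        _validate_record(name, seq, struct)
        records.append(StructureRecord(name, seq, struct, float(m.group("mfe"))))
    return records


def _pairings_by_region(
    regions: Sequence[RegionInterval], structures: Sequence[StructureRecord]
) -> Dict[str, List[bool]]:
    """Match structure records to regions; a co-fold record named e.g.
    '5.8S+26S' is split at '&' and distributed to both regions."""
    region_names = [iv.name for iv in regions]
    out: Dict[str, List[bool]] = {}
    for rec in structures:
        parts = [p.strip() for p in rec.name.replace("&", "+").split("+")]
        strands = rec.dotbracket.split("&")
        if len(parts) > 1:
            if len(strands) != len(parts):
                raise ValueError(
                    f"record {rec.name!r}: {len(parts)} region names but "
                    f"{len(strands)} strands"
                )
            for part, strand in zip(parts, strands):
                out[part] = [c in "()" for c in strand]
        else:
            out[rec.name] = rec.pairing()
    missing = [n for n in region_names if n not in out]
    if missing:
        raise ValueError(f"no structure provided for region(s): {missing}")
    return out


def annotate_sites(
    regions: Sequence[RegionInterval], structures: Sequence[StructureRecord]
) -> pd.DataFrame:
    """Position-wise join of region layout and pairing state.

    Returns a DataFrame with one row per reference position and columns
    position (1-based), region, region_class and pairing; the row count
    equals the reference length.
    """
    pairings = _pairings_by_region(regions, structures)
    rows = {"position": [], "region": [], "region_class": [], "pairing": []}
    for iv in regions:
        pairing = pairings[iv.name]
        if len(pairing) != iv.length:
            raise ValueError(
                f"region {iv.name}: structure length {len(pairing)} != "
                f"region length {iv.length}"
            )
        for offset, paired in enumerate(pairing):
            rows["position"].append(iv.start + offset)
            rows["region"].append(iv.name)
            rows["region_class"].append(iv.region_class)
            rows["pairing"].append("paired" if paired else "unpaired")
    return pd.DataFrame(rows)
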