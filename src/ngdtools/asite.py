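"""Footprint size classes, A-site/cut-point inference, and offset calibration.

Three monosome footprint sizes report three ribosome states: 21 nt fragments
come from classical (unrotated) ribosomes waiting to decode the A-site codon,
28 nt fragments from rotated pre-translocation ribosomes, and 16 nt fragments
from ribosomes that have run into the truncated 3' end of a cleaved mRNA.
A-site positions are inferred from the 5' end plus a length-specific offset;
for the truncated 16 nt class the 3' end itself marks the endonucleolytic cut
point.  Disome (collided ribosome pair) footprints follow the same scheme with
their own offsets, and long in vitro cleavage fragments use 3' ends.

Conventions: "A-site position" is the first nucleotide of the A-site codon;
"cut point" is the first nucleotide beyond the protected fragment (half-open
end), so "cleavage before position x" is single-valued.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .reads import AlignedFootprint

logger = logging.getLogger("ngdtools")

A_SITE = "a_site_codon_start"
CUT_POINT = "cut_point"


@dataclasses.dataclass(frozen=True)
class ClassRule:
    """Inference rule for one size class.

    ``offsets`` maps read length -> 5'-end-to-A-site offset in nt; if
    ``offsets`` is None the class uses the 3' end as a cut point.
    """

    name: str
    lengths: frozenset[int]
    offsets: Mapping[int, int] | None  # None => threeprime_end rule

    @property
    def is_cut_rule(self) -> bool:
        return self.offsets is None


@dataclasses.dataclass(frozen=True)
class OffsetTable:
    mode: str  # monosome | disome | invitro
    rules: tuple[ClassRule, ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for rule in self.rules:
            if rule.lengths & seen:
                raise ValueError(f"overlapping length sets in {self.mode} table")
            seen |= rule.lengths
            if rule.offsets is not None:
                if set(rule.offsets) != set(rule.lengths):
                    raise ValueError(f"offsets/lengths mismatch for class {rule.name}")
                if any(o < 0 for o in rule.offsets.values()):
                    raise ValueError("negative offset")

    def classify(self, length: int) -> ClassRule | None:
        for rule in self.rules:
            if length in rule.lengths:
                return rule
        return None

    def rule(self, name: str) -> ClassRule:
        for r in self.rules:
            if r.name == name:
                return r
        raise KeyError(name)

    def class_names(self) -> list[str]:
        return [r.name for r in self.rules]


DEFAULT_MONOSOME = OffsetTable(
    mode="monosome",
    rules=(
        ClassRule("16", frozenset({15, 16, 17}), None),
        ClassRule("21", frozenset({20, 21, 22}), {20: 16, 21: 17, 22: 17}),
        ClassRule(
            "28",
            frozenset({27, 28, 29, 30, 31, 32}),
            {27: 16, 28: 16, 29: 17, 30: 17, 31: 17, 32: 17},
        ),
    ),
)

DEFAULT_DISOME = OffsetTable(
    mode="disome",
    rules=(
        ClassRule("46", frozenset({44, 45, 46, 47, 48}), None),
        ClassRule("54", frozenset({51, 52, 53, 54}), {n: 47 for n in range(51, 55)}),
        ClassRule("60", frozenset(range(57, 63)), {n: 47 for n in range(57, 63)}),
    ),
)

DEFAULT_INVITRO = OffsetTable(
    mode="invitro",
    rules=(ClassRule("invitro", frozenset(range(60, 66)), None),),
)

DEFAULT_TABLES = {
    "monosome": DEFAULT_MONOSOME,
    "disome": DEFAULT_DISOME,
    "invitro": DEFAULT_INVITRO,
}


def classify_footprint(length: int, mode: str = "monosome") -> str | None:
    """Size-class label for a footprint length, or None if unclassified.

    Monosome lengths 18-19 and 23-26 nt fall between classes and are
    deliberately unclassified (no interpolation).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rule = DEFAULT_TABLES[mode].classify(length)
    return rule.name if rule is not None else None


@dataclasses.dataclass(frozen=True)
class SiteCall:
    transcript_id: str
    position: int
    kind: str  # A_SITE | CUT_POINT
    size_class: str
    read_id: str


def infer_site(
    fp: AlignedFootprint,
    table: OffsetTable,
    transcript_length: int | None = None,
) -> SiteCall | None:
    """Convert one aligned footprint to an A-site or cut-point call.

    Returns None for unclassified lengths or positions falling outside the
    transcript (callers count drops).
    """
    rule = table.classify(fp.length)
    if rule is None:
        return None
    if rule.is_cut_rule:
        pos, kind = fp.end, CUT_POINT
    else:
        pos, kind = fp.start + rule.offsets[fp.length], A_SITE
    if pos < 0 or (transcript_length is not None and pos > transcript_length):
        return None
    return SiteCall(fp.transcript_id, pos, kind, rule.name, fp.read_id)


@dataclasses.dataclass
class OccupancyTrack:
    """Per-nucleotide counts of inferred sites on one transcript."""

    transcript_id: str
    size_class: str
    counts: np.ndarray  # int array, one slot per transcript nt (+1 for half-open cuts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for pos in np.flatnonzero(self.counts):
                fh.write(
                    f"{self.transcript_id}\t{pos}\t{pos + 1}\t{int(self.counts[pos])}\n"
                )


def build_track(
    calls: Iterable[SiteCall], transcript_id: str, transcript_length: int,
    size_class: str = "",
) -> OccupancyTrack:
    # +1 slot: a cut point can sit at the half-open transcript end
    counts = np.zeros(transcript_length + 1, dtype=np.int64)
    for call in calls:
        if call.transcript_id != transcript_id:
            raise ValueError(
                f"call on {call.transcript_id} added to track for {transcript_id}"
            )
        counts[call.position] += 1
    return OccupancyTrack(transcript_id, size_class, counts)


def build_tracks_by_class(
    calls: Iterable[SiteCall], transcript_id: str, transcript_length: int
) -> dict[str, OccupancyTrack]:
    by_class: dict[str, list[SiteCall]] = defaultdict(list)
    for c in calls:
        if c.transcript_id == transcript_id:
            by_class[c.size_class].append(c)
    return {
        name: build_track(cs, transcript_id, transcript_length, size_class=name)
        for name, cs in by_class.items()
    }


# ---------------------------------------------------------------------------
# Offset calibration from start codons
# ---------------------------------------------------------------------------

CALIBRATION_WINDOW = (-40, 20)  # 5' ends considered, relative to the start codon


def calibrate_offsets(
    alignments: Iterable[AlignedFootprint],
    cds_intervals: Mapping[str, tuple[int, int]],
    lengths: Sequence[int] | None = None,
    min_reads: int = 100,
    fallback: OffsetTable = DEFAULT_MONOSOME,
) -> OffsetTable:
    """Calibrate 5'-end A-site offsets from the start-codon metagene.

    Initiation-proximal ribosomes hold the AUG in the P site, so the A site
    sits at start+3; the offset for length L is (start+3) minus the modal
    5'-end position of L-length reads near starts.  Lengths with fewer than
    ``min_reads`` reads in the window fall back to the default table with a
    warning.  Ties between modal bins resolve toward the smaller offset.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("no alignments to calibrate from")
    if lengths is None:
        lengths = sorted(
            {fp.length for fp in alignments if fallback.classify(fp.length) is not None
             and not fallback.classify(fp.length).is_cut_rule}
        )

    hist: dict[int, Counter[int]] = defaultdict(Counter)
    for fp in alignments:
        cds = cds_intervals.get(fp.transcript_id)
        if cds is None:
            continue
        rel = fp.start - cds[0]
        if CALIBRATION_WINDOW[0] <= rel < CALIBRATION_WINDOW[1]:
            hist[fp.length][rel] += 1

    calibrated: dict[int, int] = {}
    for L in lengths:
        counts = hist.get(L, Counter())
        n = sum(counts.values())
        if n < min_reads:
            logger.warning(
                "length %d: %d reads near starts (< %d); using default offset", L, n, min_reads
            )
            continue
        best = max(counts.values())
        # larger modal 5'-end position (closer to start) <=> smaller offset
        modal_rel = max(pos for pos, c in counts.items() if c == best)
        if sum(1 for c in counts.values() if c == best) > 1:
            warnings.warn(f"tied modal bins for length {L}; choosing smaller offset")
        calibrated[L] = 3 - modal_rel

    rules = []
    for rule in fallback.rules:
        if rule.is_cut_rule:
            rules.append(rule)
        else:
            offsets = {
                L: calibrated.get(L, rule.offsets[L]) for L in rule.lengths
            }
            rules.append(ClassRule(rule.name, rule.lengths, offsets))
    return OffsetTable(mode=fallback.mode, rules=tuple(rules))


# ---------------------------------------------------------------------------
# Plain-text (de)serialization of offset tables
# ---------------------------------------------------------------------------

def write_offset_table(table: OffsetTable, path: str | Path) -> None:
    """Rows: class <tab> length <tab> rule <tab> offset (`.` for 3'-end rules)."""
    with open(path, "w") as fh:
        fh.write(f"#mode\t{table.mode}\n")
        for rule in table.rules:
            for L in sorted(rule.lengths):
                if rule.is_cut_rule:
                    fh.write(f"{rule.name}\t{L}\tthreeprime_end\t.\n")
                else:
                    fh.write(f"{rule.name}\t{L}\tfiveprime_offset\t{rule.offsets[L]}\n")


def read_offset_table(path: str | Path) -> OffsetTable:
    mode = "monosome"
    by_class: dict[str, dict[int, int | None]] = defaultdict(dict)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#mode"):
                mode = line.split("\t")[1]
                continue
            name, L, rule_kind, off = line.split("\t")
            by_class[name][int(L)] = None if rule_kind == "threeprime_end" else int(off)
    rules = []
    for name, entries in by_class.items():
        if all(v is None for v in entries.values()):
            rules.append(ClassRule(name, frozenset(entries), None))
        else:
            rules.append(ClassRule(name, frozenset(entries), {k: v for k, v in entries.items()}))
    return OffsetTable(mode=mode, rules=tuple(rules))
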