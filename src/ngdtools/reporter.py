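"""Reporter transcript models for No-Go Decay (NGD) analysis.

The stalling reporter is a single ORF encoding GFP-2A-FLAG-His3.  Stall
variants carry a run of 12 identical codons — (CGA)x12, decoded slowly by the
low-copy ICG-tRNA(Arg), or (AAA)x12, mimicking a poly(A) tail — inserted 90
codons into the HIS3 portion.  An RFP transcript serves as the normalization
control for reporter expression.

The true vector sequences are not required for any downstream geometry, so the
segments shipped here are deterministic stand-in ORFs of realistic lengths
(GFP 717 nt, 2A 60 nt, FLAG 24 nt, HIS3 660 nt including its stop), generated
once from a fixed seed with sense codons only, no (CGA)(CGA) dinucleotide-codon
runs and no A6 homopolymers outside the insert.  That keeps stall peaks and
untemplated-A calls unambiguous on synthetic data.

Coordinates are 0-based, half-open everywhere internally; GFF3 output is
1-based closed per the format.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

# Segment lengths in nt (HIS3 includes the terminal stop codon).
SEGMENT_LENGTHS = {"GFP": 717, "2A": 60, "FLAG": 24, "HIS3": 660}
DEFAULT_UTR5 = 50
DEFAULT_UTR3 = 50
_SEQUENCE_SEED = 49117  # fixed: stand-in sequences are part of the reference


@dataclasses.dataclass(frozen=True)
class StallInsert:
    codon: str
    repeat_count: int
    insertion_codon_index: int  # counted within HIS3, insert placed after this many HIS3 codons


@dataclasses.dataclass(frozen=True)
class ReporterConstruct:
    """A reporter transcript with CDS and (optional) stall-insert annotation."""

    name: str
    segments: tuple[tuple[str, str], ...]
    stall_insert: StallInsert | None
    transcript_seq: str
    cds_interval: tuple[int, int]
    stall_interval: tuple[int, int] | None

    @property
    def cds_seq(self) -> str:
        return self.transcript_seq[self.cds_interval[0] : self.cds_interval[1]]

    def __len__(self) -> int:
        return len(self.transcript_seq)


def _bad_run(seq_tail: str) -> bool:
    # reject CGA-CGA codon runs and A6 homopolymers anywhere in the tail
    return "CGACGA" in seq_tail or "AAAAAA" in seq_tail


def _random_orf(rng: np.random.Generator, n_nt: int, *, start: bool = False,
                stop: bool = False) -> str:
    """Sense-codon ORF of n_nt with no CGA-CGA runs or A6 homopolymers."""
    if n_nt % 3:
        raise ValueError("ORF length must be a multiple of 3")
    codons: list[str] = []
    n_codons = n_nt // 3
    for i in range(n_codons):
        if i == 0 and start:
            codons.append("ATG")
            continue
        if i == n_codons - 1 and stop:
            codons.append("TAA")
            continue
        while True:
            cand = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
            if cand == "CGA":  # keep the stall codon exclusive to the insert
                continue
            if not _bad_run("".join(codons[-3:]) + cand):
                codons.append(cand)
                break
    return "".join(codons)


def _random_utr(rng: np.random.Generator, n_nt: int) -> str:
    out: list[str] = []
    for _ in range(n_nt):
        while True:
            base = "ACGT"[rng.integers(4)]
            if not _bad_run("".join(out[-7:]) + base):
                out.append(base)
                break
    return "".join(out)


def _standin_segments() -> tuple[tuple[str, str], ...]:
    rng = np.random.default_rng(_SEQUENCE_SEED)
    segs = []
    for name, n in SEGMENT_LENGTHS.items():
        segs.append(
            (name, _random_orf(rng, n, start=(name == "GFP"), stop=(name == "HIS3")))
        )
    return tuple(segs)


_STANDIN_SEGMENTS = _standin_segments()
_STANDIN_UTR5 = _random_utr(np.random.default_rng(_SEQUENCE_SEED + 1), DEFAULT_UTR5)
_STANDIN_UTR3 = _random_utr(np.random.default_rng(_SEQUENCE_SEED + 2), DEFAULT_UTR3)

REPORTER_KINDS = ("OPT", "NGD-CGA", "NGD-AAA", "custom")


def build_reporter(
    kind: str = "OPT",
    insert_codon: str | None = None,
    repeat_count: int = 12,
    insertion_codon_index: int = 90,
    segments: Sequence[tuple[str, str]] | None = None,
) -> ReporterConstruct:
    """Assemble a GFP-2A-FLAG-His3 reporter transcript.

    ``kind`` selects the canonical constructs: ``OPT`` (no insert),
    ``NGD-CGA`` ((CGA)x12 after HIS3 codon 90) and ``NGD-AAA`` ((AAA)x12,
    same position).  ``custom`` uses the explicit insert arguments.
    """
    if kind not in REPORTER_KINDS:
        raise ValueError(f"unknown reporter kind {kind!r}")
    segs = tuple(segments) if segments is not None else _STANDIN_SEGMENTS
    if kind == "OPT":
        insert = None
    else:
        if kind == "NGD-CGA":
            insert_codon = "CGA"
        elif kind == "NGD-AAA":
            insert_codon = "AAA"
        elif insert_codon is None:
            raise ValueError("custom reporter requires insert_codon")
        insert_codon = insert_codon.upper()
        if len(insert_codon) != 3 or set(insert_codon) - set("ACGT"):
            raise ValueError(f"insert codon must be a 3-nt DNA codon, got {insert_codon!r}")
        if insert_codon in STOP_CODONS:
            raise ValueError(f"stall insert must be a sense codon, got stop {insert_codon}")
        his3 = dict(segs)["HIS3"]
        his3_codons = len(his3) // 3
        if not 1 <= insertion_codon_index < his3_codons:
            raise ValueError(
                f"insertion_codon_index {insertion_codon_index} outside HIS3 "
                f"({his3_codons} codons)"
            )
        if repeat_count < 1:
            raise ValueError("repeat_count must be >= 1")
        insert = StallInsert(insert_codon, repeat_count, insertion_codon_index)

    utr5, utr3 = _STANDIN_UTR5, _STANDIN_UTR3
    parts = [utr5]
    pos = len(utr5)
    cds_start = pos
    stall_interval = None
    for seg_name, seg_seq in segs:
        if insert is not None and seg_name == "HIS3":
            cut = 3 * insert.insertion_codon_index
            parts.append(seg_seq[:cut])
            pos += cut
            stall_interval = (pos, pos + 3 * insert.repeat_count)
            parts.append(insert.codon * insert.repeat_count)
            pos = stall_interval[1]
            parts.append(seg_seq[cut:])
            pos += len(seg_seq) - cut
        else:
            parts.append(seg_seq)
            pos += len(seg_seq)
    cds_end = pos
    parts.append(utr3)
    transcript = "".join(parts)

    construct = ReporterConstruct(
        name=kind if kind != "custom" else f"custom-{insert_codon}x{repeat_count}",
        segments=segs,
        stall_insert=insert,
        transcript_seq=transcript,
        cds_interval=(cds_start, cds_end),
        stall_interval=stall_interval,
    )
    _check_invariants(construct)
    return construct


def _check_invariants(c: ReporterConstruct) -> None:
    seg_total = sum(len(s) for _, s in c.segments)
    insert_nt = 3 * c.stall_insert.repeat_count if c.stall_insert else 0
    cds_len = c.cds_interval[1] - c.cds_interval[0]
    if cds_len != seg_total + insert_nt:
        raise AssertionError("CDS length != segments + insert")
    if cds_len % 3:
        raise AssertionError("CDS length not a multiple of 3")
    if c.stall_interval is not None:
        s, e = c.stall_interval
        if e - s != insert_nt:
            raise AssertionError("stall interval length mismatch")
        if (s - c.cds_interval[0]) % 3:
            raise AssertionError("stall insert off the codon frame")
        upstream = c.transcript_seq[c.cds_interval[0] : s]
    else:
        upstream = c.cds_seq[:-3]
    for i in range(0, len(upstream) - 2, 3):
        if upstream[i : i + 3] in STOP_CODONS:
            raise AssertionError(f"internal stop codon at CDS offset {i}")


def stall_window(construct: ReporterConstruct, upstream_nt: int) -> tuple[int, int]:
    """Transcript interval from ``upstream_nt`` before the stall insert to its end.

    The occupancy-ratio statistic uses 300 nt upstream of the (CGA)x12 through
    the end of the insert.  Clipped at the transcript start.
    """
    if construct.stall_interval is None:
        raise ValueError(f"construct {construct.name!r} has no stall insert")
    if upstream_nt < 0:
        raise ValueError("upstream_nt must be >= 0")
    s, e = construct.stall_interval
    return (max(0, s - upstream_nt), e)


def build_rfp_control(name: str = "RFP", cds_nt: int = 678) -> ReporterConstruct:
    """Stand-in RFP control transcript (single ORF, same conventions)."""
    rng = np.random.default_rng(_SEQUENCE_SEED + 3)
    orf = _random_orf(rng, cds_nt, start=True, stop=True)
    utr5 = _random_utr(np.random.default_rng(_SEQUENCE_SEED + 4), DEFAULT_UTR5)
    utr3 = _random_utr(np.random.default_rng(_SEQUENCE_SEED + 5), DEFAULT_UTR3)
    return ReporterConstruct(
        name=name,
        segments=((name, orf),),
        stall_insert=None,
        transcript_seq=utr5 + orf + utr3,
        cds_interval=(len(utr5), len(utr5) + cds_nt),
        stall_interval=None,
    )


def random_cds_transcripts(
    n: int, rng: np.random.Generator, cds_codons_range: tuple[int, int] = (150, 300)
) -> list[ReporterConstruct]:
    """Generic single-ORF transcripts (used for metagene offset calibration)."""
    out = []
    for i in range(n):
        n_codons = int(rng.integers(*cds_codons_range))
        orf = _random_orf(rng, 3 * n_codons, start=True, stop=True)
        utr5 = _random_utr(rng, DEFAULT_UTR5)
        utr3 = _random_utr(rng, DEFAULT_UTR3)
        out.append(
            ReporterConstruct(
                name=f"gene{i:03d}",
                segments=((f"gene{i:03d}", orf),),
                stall_insert=None,
                transcript_seq=utr5 + orf + utr3,
                cds_interval=(len(utr5), len(utr5) + 3 * n_codons),
                stall_interval=None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reference output: FASTA + BED (0-based half-open) + GFF3 (1-based closed)
# ---------------------------------------------------------------------------

def write_reference(
    constructs: Iterable[ReporterConstruct],
    fasta_path: str | Path,
    bed_path: str | Path | None = None,
    gff_path: str | Path | None = None,
) -> None:
    """Write transcript FASTA plus CDS/stall annotations.

    BED rows are 0-based half-open; GFF3 rows 1-based closed.  Stall inserts
    appear as a second feature row named ``stall``.
    """
    constructs = list(constructs)
    if not constructs:
        raise ValueError("no constructs to write")
    names = [c.name for c in constructs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate construct names: {sorted(names)}")

    records = [
        SeqRecord(Seq(c.transcript_seq), id=c.name, description="")
        for c in constructs
    ]
    SeqIO.write(records, str(fasta_path), "fasta")

    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for c in constructs:
                s, e = c.cds_interval
                fh.write(f"{c.name}\t{s}\t{e}\tCDS\t0\t+\n")
                if c.stall_interval is not None:
                    ss, se = c.stall_interval
                    fh.write(f"{c.name}\t{ss}\t{se}\tstall\t0\t+\n")
    if gff_path is not None:
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c in constructs:
                s, e = c.cds_interval
                fh.write(
                    f"{c.name}\tngdtools\tCDS\t{s + 1}\t{e}\t.\t+\t0\tID=cds-{c.name}\n"
                )
                if c.stall_interval is not None:
                    ss, se = c.stall_interval
                    fh.write(
                        f"{c.name}\tngdtools\tsequence_feature\t{ss + 1}\t{se}\t.\t+\t."
                        f"\tID=stall-{c.name}\n"
                    )


def read_reference(
    fasta_path: str | Path, bed_path: str | Path | None = None
) -> tuple[dict[str, str], dict[str, tuple[int, int]], dict[str, tuple[int, int]]]:
    """Parse a reference back: (sequences, cds intervals, stall intervals)."""
    seqs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    cds: dict[str, tuple[int, int]] = {}
    stall: dict[str, tuple[int, int]] = {}
    if bed_path is not None:
        with open(bed_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, s, e, feat = line.split("\t")[:4]
                if feat == "CDS":
                    cds[chrom] = (int(s), int(e))
                elif feat == "stall":
                    stall[chrom] = (int(s), int(e))
    return seqs, cds, stall
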