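"""Adapter/UMI trimming, contaminant filtering, and ungapped transcript placement.

The library structure is: 4 random 5' nt (RT-primer UMI), the footprint, then
a 3' adapter whose first 6 nt are random (ligation UMI) followed by the
constant sequence CACTCGGGCACCAAGGA.  Trimming strips the constant adapter
(allowing a truncated adapter at the read end and one mismatch), the 6-nt UMI
preceding it, and the 4-nt 5' UMI.

Placement is ungapped against a small transcriptome (the reporter + controls),
with unique-best-hit and <=10% mismatch-rate contracts.  Terminal read bases
that fail to match are soft-clip-like: they count as untemplated adenosines
only when the whole trailing run is A and at least 15 nt of the read match the
reference — the diagnostic of ribosomes translating into a premature poly(A)
tail.  An A in the tail that matches the reference is templated (maximal
templated extension).  Spliced/gapped placement is out of scope; externally
produced transcriptome SAM/BAM can be imported instead.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

logger = logging.getLogger("ngdtools")

ADAPTER_CONSTANT = "CACTCGGGCACCAAGGA"
UMI5_LEN = 4
UMI3_LEN = 6
MIN_ADAPTER_OVERLAP = 5
MAX_ADAPTER_MISMATCH = 1
MIN_INSERT = 15
DEFAULT_MAX_INSERT = 90  # gel cut upper bound across all library types
SEED_LEN = 15


@dataclasses.dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    insert_seq: str
    umi5: str
    umi3: str
    status: str  # kept | no_adapter | too_short | too_long


@dataclasses.dataclass(frozen=True)
class AlignedFootprint:
    """One footprint's placement on a transcript (templated portion only)."""

    read_id: str
    transcript_id: str
    start: int
    end: int  # 0-based half-open
    untemplated_A: int = 0
    mismatches: int = 0
    multimapped: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class ReadAccounting:
    """Every raw read lands in exactly one terminal category."""

    total: int = 0
    kept: int = 0
    no_adapter: int = 0
    too_short: int = 0
    too_long: int = 0
    contaminant: int = 0
    unaligned: int = 0
    multimapped: int = 0
    aligned: int = 0

    def conserved(self) -> bool:
        return self.total == (
            self.no_adapter + self.too_short + self.too_long
            + self.contaminant + self.unaligned + self.multimapped + self.aligned
        )

    def as_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_read(read_id: str, raw_seq: str, max_insert: int = DEFAULT_MAX_INSERT) -> TrimmedRead:
    """Strip 5' UMI, 3' UMI and constant adapter from one raw read.

    The constant adapter may be truncated by the sequencing read length; a
    prefix of >= 5 nt at the read end qualifies, with at most one mismatch.
    The leftmost qualifying position wins (inserts never contain the adapter).
    """
    if not raw_seq:
        raise ValueError("empty read")
    raw_seq = raw_seq.upper()
    n = len(raw_seq)
    found = -1
    for p in range(n - MIN_ADAPTER_OVERLAP + 1):
        overlap = min(len(ADAPTER_CONSTANT), n - p)
        if overlap < len(ADAPTER_CONSTANT) and p + overlap < n:
            continue  # partial adapter only allowed flush with the read end
        if _hamming(raw_seq[p : p + overlap], ADAPTER_CONSTANT[:overlap]) <= MAX_ADAPTER_MISMATCH:
            found = p
            break
    if found < 0:
        return TrimmedRead(read_id, "", "", "", "no_adapter")
    insert_end = found - UMI3_LEN
    if insert_end < UMI5_LEN + MIN_INSERT:
        return TrimmedRead(
            read_id,
            raw_seq[UMI5_LEN : max(insert_end, UMI5_LEN)],
            raw_seq[:UMI5_LEN],
            raw_seq[max(insert_end, 0) : found],
            "too_short",
        )
    insert = raw_seq[UMI5_LEN:insert_end]
    if len(insert) > max_insert:
        return TrimmedRead(read_id, insert, raw_seq[:UMI5_LEN], raw_seq[insert_end:found], "too_long")
    return TrimmedRead(read_id, insert, raw_seq[:UMI5_LEN], raw_seq[insert_end:found], "kept")


def trim_fastq(
    fastq_path: str | Path,
    max_insert: int = DEFAULT_MAX_INSERT,
    accounting: ReadAccounting | None = None,
) -> list[TrimmedRead]:
    """Trim a whole FASTQ; returns kept reads and updates accounting."""
    acc = accounting if accounting is not None else ReadAccounting()
    kept = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        acc.total += 1
        tr = trim_read(rec.id, str(rec.seq))
        if tr.status == "kept":
            kept.append(tr)
            acc.kept += 1
        else:
            setattr(acc, tr.status, getattr(acc, tr.status) + 1)
    return kept


# ---------------------------------------------------------------------------
# Contaminant filtering (rRNA / ncRNA)
# ---------------------------------------------------------------------------

def filter_contaminants(
    reads: Sequence[TrimmedRead],
    contaminants: Mapping[str, str],
    max_mismatch_frac: float = 0.10,
) -> tuple[list[TrimmedRead], list[TrimmedRead]]:
    """Partition reads into (kept, contaminant).

    A read is a contaminant when it matches inside any contaminant sequence
    ungapped with a mismatch fraction <= ``max_mismatch_frac`` of its length.
    """
    if not contaminants:
        return list(reads), []
    cont_arrays = {
        name: np.frombuffer(seq.upper().encode(), dtype="S1")
        for name, seq in contaminants.items()
    }
    kept, removed = [], []
    for read in reads:
        q = np.frombuffer(read.insert_seq.encode(), dtype="S1")
        max_mm = int(max_mismatch_frac * len(q))
        hit = False
        for arr in cont_arrays.values():
            if len(arr) < len(q):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, len(q))
            if (windows != q).sum(axis=1).min() <= max_mm:
                hit = True
                break
        (removed if hit else kept).append(read)
    return kept, removed


# ---------------------------------------------------------------------------
# Ungapped placement with untemplated-A awareness
# ---------------------------------------------------------------------------

class TranscriptomeIndex:
    """Seed index (exact k-mers) over a small transcriptome for ungapped search."""

    def __init__(self, sequences: Mapping[str, str], seed_len: int = SEED_LEN):
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        self.seed_len = seed_len
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for tid, seq in self.sequences.items():
            for i in range(len(seq) - seed_len + 1):
                self._seeds[seq[i : i + seed_len]].append((tid, i))

    def candidates(self, read: str) -> set[tuple[str, int]]:
        """Candidate (transcript, read-start) placements from seed hits.

        Two disjoint seeds (read start and read end) tolerate one mismatch
        landing inside either; reads failing both fall back to a full scan.
        """
        L = len(read)
        cands: set[tuple[str, int]] = set()
        offsets = [0]
        if L >= 2 * self.seed_len:
            offsets.append(L - self.seed_len)
        elif L > self.seed_len:
            offsets.append(L - self.seed_len)
        for off in offsets:
            for tid, pos in self._seeds.get(read[off : off + self.seed_len], ()):
                if pos - off >= 0:
                    cands.add((tid, pos - off))
        if not cands:  # rare: both seeds mutated -> brute scan
            q = np.frombuffer(read.encode(), dtype="S1")
            for tid, seq in self.sequences.items():
                arr = np.frombuffer(seq.encode(), dtype="S1")
                if len(arr) < MIN_INSERT:
                    continue
                m = min(len(q), len(arr))
                windows = np.lib.stride_tricks.sliding_window_view(arr, MIN_INSERT)
                # anchor on the first 15 nt with <=2 mismatches
                mm = (windows != q[:MIN_INSERT]).sum(axis=1)
                for pos in np.flatnonzero(mm <= 2):
                    cands.add((tid, int(pos)))
        return cands


def _evaluate_placement(
    read: str, ref: str, pos: int, max_mismatch_frac: float
) -> tuple[int, int, int, int] | None:
    """Score an ungapped placement of ``read`` with its first base at ``pos``.

    Returns (mismatches, templated_len, untemplated_A, end) or None if the
    placement violates the mismatch contract or runs off the transcript with
    a non-A overhang.
    """
    L = len(read)
    avail = len(ref) - pos
    if pos < 0 or avail < MIN_INSERT:
        return None
    k = min(L, avail)
    overhang = read[k:]
    if overhang and set(overhang) != {"A"}:
        return None
    # trailing run of non-matching bases (maximal templated extension)
    t = k
    while t > 0 and read[t - 1] != ref[pos + t - 1]:
        t -= 1
    tail = read[t:k]
    if (tail or overhang) and t >= MIN_INSERT and set(tail) <= {"A"}:
        templated = t
        untemplated = (k - t) + len(overhang)
    else:
        if overhang:  # off-end overhang with a non-A-qualifying tail
            return None
        templated = k
        untemplated = 0
    mismatches = _hamming(read[:templated], ref[pos : pos + templated])
    if templated < MIN_INSERT or mismatches > max_mismatch_frac * templated:
        return None
    return (mismatches, templated, untemplated, pos + templated)


def align_footprint(
    read_id: str,
    insert_seq: str,
    index: TranscriptomeIndex,
    max_mismatch_frac: float = 0.10,
) -> AlignedFootprint | None:
    """Place one trimmed insert on the transcriptome, ungapped.

    Best placement minimizes mismatches then maximizes templated length;
    a tie between distinct placements returns a multimapped (dropped) record.
    """
    if len(insert_seq) < MIN_INSERT:
        return None
    insert_seq = insert_seq.upper()
    best_key = None
    best: list[AlignedFootprint] = []
    for tid, pos in index.candidates(insert_seq):
        scored = _evaluate_placement(insert_seq, index.sequences[tid], pos, max_mismatch_frac)
        if scored is None:
            continue
        mism, templated, untA, end = scored
        key = (mism, -templated)
        fp = AlignedFootprint(read_id, tid, pos, end, untA, mism)
        if best_key is None or key < best_key:
            best_key, best = key, [fp]
        elif key == best_key:
            best.append(fp)
    if not best:
        return None
    if len(best) > 1:
        return dataclasses.replace(best[0], multimapped=True)
    return best[0]


def align_reads(
    reads: Sequence[TrimmedRead],
    index: TranscriptomeIndex,
    max_mismatch_frac: float = 0.10,
    accounting: ReadAccounting | None = None,
) -> list[AlignedFootprint]:
    acc = accounting if accounting is not None else ReadAccounting()
    out = []
    for read in reads:
        fp = align_footprint(read.read_id, read.insert_seq, index, max_mismatch_frac)
        if fp is None:
            acc.unaligned += 1
        elif fp.multimapped:
            acc.multimapped += 1
        else:
            acc.aligned += 1
            out.append(fp)
    return out


def dedup_umis(
    alignments: Sequence[AlignedFootprint],
    trimmed: Mapping[str, TrimmedRead],
) -> list[AlignedFootprint]:
    """Optional UMI collapse: one read per (transcript, start, end, umi5, umi3).

    Off by default in the pipeline — the library uses random nucleotides but
    the analysis counts raw footprints.
    """
    seen: set[tuple] = set()
    out = []
    for fp in alignments:
        tr = trimmed[fp.read_id]
        key = (fp.transcript_id, fp.start, fp.end, tr.umi5, tr.umi3)
        if key not in seen:
            seen.add(key)
            out.append(fp)
    return out


# ---------------------------------------------------------------------------
# SAM import/export (untemplated tails as 3' soft-clips)
# ---------------------------------------------------------------------------

def write_sam(
    alignments: Iterable[AlignedFootprint],
    sequences: Mapping[str, str],
    path: str | Path,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": tid, "LN": len(seq)} for tid, seq in sequences.items()],
    }
    tids = {tid: i for i, tid in enumerate(sequences)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for fp in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = fp.read_id
            a.reference_id = tids[fp.transcript_id]
            a.reference_start = fp.start
            a.mapping_quality = 0 if fp.multimapped else 255
            seq = sequences[fp.transcript_id][fp.start : fp.end]
            cigar = [(0, fp.length)]
            if fp.untemplated_A:
                seq += "A" * fp.untemplated_A
                cigar.append((4, fp.untemplated_A))
            a.query_sequence = seq
            a.cigartuples = cigar
            a.flag = 0
            a.set_tag("NM", fp.mismatches)
            out.write(a)


def read_sam(path: str | Path) -> tuple[list[AlignedFootprint], int]:
    """Import transcriptome SAM/BAM; returns (footprints, n_skipped_indel).

    Untemplated adenosines are reconstructed from 3' soft-clips whose bases
    are all A; other soft-clipped bases are ignored.  Records containing
    insertions/deletions cannot be represented by the ungapped model and are
    skipped with a logged count.
    """
    out = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            ops = {op for op, _ in rec.cigartuples}
            if ops & {1, 2, 3}:  # I, D, N
                skipped += 1
                continue
            untA = 0
            last_op, last_len = rec.cigartuples[-1]
            if last_op == 4 and rec.query_sequence:
                clipped = rec.query_sequence[-last_len:]
                if set(clipped) == {"A"}:
                    untA = last_len
            out.append(
                AlignedFootprint(
                    read_id=rec.query_name,
                    transcript_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    untemplated_A=untA,
                    mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    multimapped=rec.mapping_quality == 0,
                )
            )
    if skipped:
        logger.info("read_sam: skipped %d records with indels", skipped)
    return out, skipped
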