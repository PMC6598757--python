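"""Peak calling, collided-ribosome spacing, occupancy ratios, and cut-site
concordance on occupancy tracks.

The signature of endonucleolytic cleavage at a stall is geometric: lead
ribosomes (21 nt RPF A sites) sit on the slowly decoded codons, collided
ribosomes (28 nt RPF A sites) stack exactly one ribosome (~30 nt) upstream,
and truncated-mRNA footprints (16 nt RPF cut points) end at the collided
ribosome's A site — again 30 nt upstream of the lead.  ``peak_spacing``
measures that modal lag between two peak sets; ``windowed_occupancy`` is the
RFP-normalized 21+28 nt density over the stall window used to compare
genotypes; ``cut_site_concordance`` asks how much in vitro SMR-endonuclease
cut weight falls on in vivo cut positions.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter

import numpy as np

from .asite import OccupancyTrack


@dataclasses.dataclass(frozen=True)
class Peak:
    position: int
    count: int
    fraction_of_track: float


@dataclasses.dataclass(frozen=True)
class PeakSet:
    transcript_id: str
    size_class: str
    peaks: tuple[Peak, ...]

    def positions(self) -> list[int]:
        return [p.position for p in self.peaks]


@dataclasses.dataclass(frozen=True)
class SpacingResult:
    modal_spacing: int
    spacing_histogram: dict[int, float]
    n_pairs: int


@dataclasses.dataclass(frozen=True)
class OccupancyRatio:
    numerator_genotype: str
    denominator_genotype: str
    window: tuple[int, int]
    numerator_occupancies: tuple[float, ...]
    denominator_occupancies: tuple[float, ...]

    @property
    def ratio(self) -> float:
        den = float(np.mean(self.denominator_occupancies))
        if den <= 0:
            raise ZeroDivisionError("denominator occupancy is zero")
        return float(np.mean(self.numerator_occupancies)) / den


def call_peaks(
    track: OccupancyTrack, min_fraction: float = 0.05, min_count: int = 5
) -> PeakSet:
    """Local maxima (within +-1 nt) carrying at least ``min_fraction`` of the
    track and ``min_count`` reads."""
    counts = track.counts
    total = counts.sum()
    peaks = []
    if total > 0:
        padded = np.pad(counts.astype(np.int64), 1)
        for pos in np.flatnonzero(
            (padded[1:-1] > padded[:-2]) & (padded[1:-1] > padded[2:])
        ):
            c = int(counts[pos])
            frac = c / total
            if c >= min_count and frac >= min_fraction:
                peaks.append(Peak(int(pos), c, float(frac)))
    return PeakSet(track.transcript_id, track.size_class, tuple(peaks))


def peak_spacing(
    upstream: PeakSet, downstream: PeakSet, max_lag: int = 60
) -> SpacingResult:
    """Modal positive lag between an upstream and a downstream peak set.

    Every ordered pair with 0 < lag <= max_lag contributes weight
    min(counts); ties in the histogram resolve toward the smaller lag.
    """
    if not upstream.peaks or not downstream.peaks:
        raise ValueError("peak_spacing requires nonempty peak sets")
    hist: Counter[int] = Counter()
    n_pairs = 0
    for u in upstream.peaks:
        for d in downstream.peaks:
            lag = d.position - u.position
            if 0 < lag <= max_lag:
                hist[lag] += min(u.count, d.count)
                n_pairs += 1
    if not hist:
        raise ValueError(f"no peak pairs within {max_lag} nt")
    best = max(hist.values())
    modal = min(lag for lag, w in hist.items() if w == best)
    if sum(1 for w in hist.values() if w == best) > 1:
        warnings.warn(f"tied modal spacings; choosing smallest ({modal} nt)")
    return SpacingResult(modal, dict(hist), n_pairs)


def windowed_occupancy(
    track21: OccupancyTrack,
    track28: OccupancyTrack,
    window: tuple[int, int],
    rfp_track21: OccupancyTrack,
    rfp_track28: OccupancyTrack,
    rfp_cds: tuple[int, int],
) -> float:
    """Combined 21+28 nt density in a window, normalized to RFP density.

    (window counts / window nt) / (RFP CDS counts / RFP CDS nt); used with the
    stall window (300 nt upstream of the insert through its end).
    """
    lo, hi = window
    if not (0 <= lo < hi <= len(track21.counts)):
        raise ValueError(f"window {window} outside transcript")
    win = int(track21.counts[lo:hi].sum() + track28.counts[lo:hi].sum())
    rlo, rhi = rfp_cds
    rfp = int(rfp_track21.counts[rlo:rhi].sum() + rfp_track28.counts[rlo:rhi].sum())
    if rfp == 0:
        raise ZeroDivisionError("RFP control has no 21/28 nt reads; ratio undefined")
    return (win / (hi - lo)) / (rfp / (rhi - rlo))


def cut_site_concordance(
    invitro_track: OccupancyTrack,
    invivo_track: OccupancyTrack,
    tolerance_nt: int = 1,
    min_fraction: float = 0.05,
    min_count: int = 5,
) -> float:
    """Fraction of in vitro cut weight within ``tolerance_nt`` of an in vivo peak.

    In vivo peaks are extracted with ``call_peaks``; the statistic is the share
    of the total in vitro track falling on those positions (+- tolerance).
    """
    total = invitro_track.total
    if total == 0:
        raise ValueError("empty in vitro track; concordance undefined")
    invivo_peaks = call_peaks(invivo_track, min_fraction, min_count)
    mask = np.zeros(len(invitro_track.counts), dtype=bool)
    for pos in invivo_peaks.positions():
        lo = max(0, pos - tolerance_nt)
        hi = min(len(mask), pos + tolerance_nt + 1)
        mask[lo:hi] = True
    return float(invitro_track.counts[mask].sum() / total)
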