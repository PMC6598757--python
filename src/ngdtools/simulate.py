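"""Synthetic footprint libraries and colony-array plates.

The generator emulates the deposited libraries' structure so every analysis
stage runs without downloads: monosome ribosome-protected fragments (RPFs) in
the 16/21/28 nt size classes with the stall geometry of the GFP-2A-FLAG-His3
reporter, disome RPFs (44-62 nt), long in vitro cleavage fragments, reads
carrying untemplated 3' adenosines, and 1536-format reporter-SGA plate pairs
with spatial artifacts.

Geometry (the study conditions): lead ribosomes stall with their A sites on
stall codons 2-5 of the insert (21 nt class); a collided ribosome stacks
immediately behind with its A site exactly 30 nt upstream (28 nt class); the
endonucleolytic cut falls at the 5' boundary of the collided ribosome's A-site
codon, so 16 nt class fragments end exactly 30 nt upstream of the lead A site.
The generator inverts the A-site offset tables used for inference, which makes
every spacing statistic integer-exact and lets round-trip tests pin the
pipeline to the drawn ground truth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .asite import (
    A_SITE,
    CUT_POINT,
    DEFAULT_DISOME,
    DEFAULT_MONOSOME,
    OffsetTable,
)
from .reads import ADAPTER_CONSTANT, UMI3_LEN, UMI5_LEN
from .reporter import ReporterConstruct

DEFAULT_READ_LENGTH = 51  # sequencing cycles; disome libraries need more
DISOME_READ_LENGTH = 100
_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Scenario configuration (genotype-dependent RPF populations)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ScenarioConfig:
    """Study conditions for one simulated library."""

    genotype_label: str
    class_weights: dict[str, float]
    stall_codon_weights: dict[int, float] = dataclasses.field(
        default_factory=lambda: {2: 1.0, 3: 1.0, 4: 1.0, 5: 1.0}
    )
    background_rate: float = 0.5  # reads per CDS nt, spread over all transcripts
    n_reads: int = 50_000
    seed: int = 0
    mismatch_rate: float = 0.0
    read_length: int = DEFAULT_READ_LENGTH

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if any(w < 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be nonnegative")
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class weights sum to {total}, expected 1")
        if any(w < 0 for w in self.stall_codon_weights.values()):
            raise ValueError("stall codon weights must be nonnegative")
        if not 0 <= self.mismatch_rate < 1:
            raise ValueError("mismatch_rate in [0, 1)")


# Genotype presets: RPF class balance and how much signal accumulates at the
# stall.  ski2d backgrounds stabilize decay intermediates; dom34d additionally
# stabilizes 16 nt RPFs; cue2d abolishes them; slh1d loss increases stalled /
# collided ribosome load roughly 2.5-fold over its CUE2-deleted control.
GENOTYPE_PRESETS: dict[str, dict] = {
    "ski2d": {"class_weights": {"16": 0.05, "21": 0.55, "28": 0.40}, "background_rate": 0.5},
    "dom34d ski2d": {"class_weights": {"16": 0.30, "21": 0.40, "28": 0.30}, "background_rate": 0.5},
    "cue2d dom34d ski2d": {"class_weights": {"16": 0.0, "21": 0.57, "28": 0.43}, "background_rate": 0.5},
    "slh1d dom34d ski2d": {"class_weights": {"16": 0.45, "21": 0.30, "28": 0.25}, "background_rate": 0.5},
    # Fig-4H-style pair: stall occupancy builds up ~2.5x when SLH1 is lost
    "slh1d cue2d dom34d ski2d": {
        "class_weights": {"16": 0.0, "21": 0.57, "28": 0.43},
        "background_rate": 0.2,
    },
}


# disome size classes carry the same genotype logic: cut-rule fragments (46)
# behave like the 16 nt class, lead-ribosome fragments (60) like 21, and the
# second conformation (54) like 28
_MONO_TO_DISOME_CLASS = {"16": "46", "21": "60", "28": "54"}


def make_scenario(genotype_label: str, n_reads: int = 50_000, seed: int = 0,
                  mode: str = "monosome", **overrides) -> ScenarioConfig:
    """Scenario with the preset RPF population for a genotype label."""
    preset = GENOTYPE_PRESETS.get(genotype_label, {})
    kwargs = {"genotype_label": genotype_label, "n_reads": n_reads, "seed": seed}
    kwargs.update({k: (dict(v) if isinstance(v, dict) else v) for k, v in preset.items()})
    kwargs.update(overrides)
    if "class_weights" not in kwargs:
        raise ValueError(f"no preset for {genotype_label!r}; pass class_weights")
    if mode == "disome":
        kwargs["class_weights"] = {
            _MONO_TO_DISOME_CLASS.get(k, k): w for k, w in kwargs["class_weights"].items()
        }
        kwargs.setdefault("read_length", DISOME_READ_LENGTH)
    return ScenarioConfig(**kwargs)


@dataclasses.dataclass(frozen=True)
class PolyASpec:
    """A premature polyadenylation event to simulate on one gene."""

    gene_id: str
    junction_position: int  # transcript coordinate where the poly(A) tail starts
    tail_read_count: int
    untemplated_A_per_read: int


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read (the oracle for round trips)."""

    read_id: str
    transcript_id: str
    size_class: str
    site_kind: str  # A_SITE | CUT_POINT
    site_pos: int
    start: int
    end: int
    is_background: bool


@dataclasses.dataclass
class SimulatedLibrary:
    reads: list[tuple[str, str]]  # (read_id, raw sequence)
    truth: list[TruthRecord]
    n_skipped: int  # placements too close to a transcript boundary

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Read placement (inverts the inference offset tables)
# ---------------------------------------------------------------------------

def place_monosome_read(
    position: int,
    size_class: str,
    rng: np.random.Generator,
    table: OffsetTable = DEFAULT_MONOSOME,
) -> tuple[int, int, int]:
    """Draw a footprint interval for a ribosome at ``position``.

    For 5'-offset classes ``position`` is the A-site codon start; for cut-rule
    classes (16 nt) it is the cut point, i.e. the footprint's half-open 3' end.
    Returns (start, end, length).  Raises ValueError when the footprint would
    run past the transcript 5' end (callers skip and count).
    """
    rule = table.rule(size_class)
    lengths = sorted(rule.lengths)
    length = int(lengths[rng.integers(len(lengths))])
    if rule.is_cut_rule:
        start, end = position - length, position
    else:
        start = position - rule.offsets[length]
        end = start + length
    if start < 0:
        raise ValueError(f"footprint start {start} before transcript 5' end")
    return start, end, length


def attach_adapter_umis(
    footprint_seq: str,
    rng: np.random.Generator,
    read_length: int = DEFAULT_READ_LENGTH,
) -> str:
    """Wrap a footprint in the raw library layout, truncated to the read length.

    Layout: [4 random nt][footprint][6 random nt][constant adapter].
    """
    if not footprint_seq:
        raise ValueError("empty footprint")
    umi5 = b"".join(_BASES[rng.integers(4, size=UMI5_LEN)]).decode()
    umi3 = b"".join(_BASES[rng.integers(4, size=UMI3_LEN)]).decode()
    raw = umi5 + footprint_seq + umi3 + ADAPTER_CONSTANT
    return raw[:read_length]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def _weighted_choice(rng: np.random.Generator, items: list, weights: list[float]):
    w = np.asarray(weights, dtype=float)
    return items[rng.choice(len(items), p=w / w.sum())]


def _simulate_library(
    reference: Sequence[ReporterConstruct],
    construct: ReporterConstruct | None,
    scenario: ScenarioConfig,
    table: OffsetTable,
    collided_spacing: int = 30,
) -> SimulatedLibrary:
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    transcripts = {c.name: c for c in reference}
    if construct is not None:
        transcripts.setdefault(construct.name, construct)

    class_names = [n for n, w in scenario.class_weights.items()]
    class_w = [scenario.class_weights[n] for n in class_names]
    stall_codons = sorted(scenario.stall_codon_weights)
    stall_w = [scenario.stall_codon_weights[k] for k in stall_codons]

    needs_stall = construct is not None and any(w > 0 for w in class_w)
    if needs_stall and construct.stall_interval is None and any(
        w > 0 for w in stall_w
    ):
        raise ValueError("stall-geometry scenario requires a construct with a stall insert")

    cds_nt = {name: c.cds_interval[1] - c.cds_interval[0] for name, c in transcripts.items()}
    total_cds_nt = sum(cds_nt.values())
    bg_names = list(transcripts)
    bg_w = [cds_nt[n] for n in bg_names]
    p_background = min(1.0, scenario.background_rate * total_cds_nt / max(scenario.n_reads, 1))

    reads: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    n_skipped = 0
    for i in range(scenario.n_reads):
        rid = f"sim{i:06d}"
        size_class = _weighted_choice(rng, class_names, class_w)
        rule = table.rule(size_class)
        is_bg = bool(rng.random() < p_background)
        if is_bg:
            tname = _weighted_choice(rng, bg_names, bg_w)
            tr = transcripts[tname]
            s, e = tr.cds_interval
            lo = s + (max(rule.offsets.values()) if rule.offsets else max(rule.lengths))
            hi = e
            if hi <= lo:
                n_skipped += 1
                continue
            position = int(rng.integers(lo, hi))
        else:
            tr = construct
            tname = construct.name
            k = _weighted_choice(rng, stall_codons, stall_w)
            lead_a = construct.stall_interval[0] + 3 * (k - 1)
            if rule.is_cut_rule:
                position = lead_a - collided_spacing  # cut at collided A-site 5' edge
            elif size_class in ("28", "60", "54"):
                # collided ribosome (28) / lead ribosome of the disome (60, 54)
                position = lead_a - collided_spacing if size_class == "28" else lead_a
            else:
                position = lead_a
        try:
            start, end, length = place_monosome_read(position, size_class, rng, table)
        except ValueError:
            n_skipped += 1
            continue
        seq = tr.transcript_seq
        if end > len(seq):
            n_skipped += 1
            continue
        footprint = _mutate(seq[start:end], scenario.mismatch_rate, rng)
        raw = attach_adapter_umis(footprint, rng, scenario.read_length)
        reads.append((rid, raw))
        truth.append(
            TruthRecord(
                rid, tname, size_class,
                CUT_POINT if rule.is_cut_rule else A_SITE,
                position, start, end, is_bg,
            )
        )
    return SimulatedLibrary(reads, truth, n_skipped)


def simulate_ngd_library(
    reference: Sequence[ReporterConstruct],
    construct: ReporterConstruct,
    scenario: ScenarioConfig,
) -> SimulatedLibrary:
    """Monosome RPF library (16/21/28 nt classes) with the NGD stall geometry.

    ``reference`` holds the control transcripts (at least the RFP control);
    the reporter itself is added automatically.
    """
    return _simulate_library(reference, construct, scenario, DEFAULT_MONOSOME)


def simulate_disome_library(
    reference: Sequence[ReporterConstruct],
    construct: ReporterConstruct,
    scenario: ScenarioConfig,
) -> SimulatedLibrary:
    """Disome RPF library (46/54/60 nt classes); lead A sites as in monosomes."""
    if scenario.read_length < DISOME_READ_LENGTH:
        scenario = dataclasses.replace(scenario, read_length=DISOME_READ_LENGTH)
    return _simulate_library(reference, construct, scenario, DEFAULT_DISOME)


def valid_polyA_junctions(
    construct: ReporterConstruct,
    untemplated_A: int,
    size_range: tuple[int, int] = (15, 34),
) -> list[int]:
    """CDS positions where a simulated poly(A) tail stays fully untemplated.

    The first ``untemplated_A`` reference bases at/after the junction must be
    non-A, otherwise part of the tail would match the reference and the
    ground-truth untemplated count would be ambiguous.
    """
    seq = construct.transcript_seq
    s, e = construct.cds_interval
    lo = max(s, size_range[1])
    return [
        j
        for j in range(lo, e + 1)
        if "A" not in seq[j : j + untemplated_A] and len(seq[j : j + untemplated_A]) == untemplated_A
    ]


def simulate_polyA_reads(
    reference: Sequence[ReporterConstruct],
    specs: Sequence[PolyASpec],
    rng: np.random.Generator,
    read_length: int = DEFAULT_READ_LENGTH,
    size_range: tuple[int, int] = (15, 34),
) -> SimulatedLibrary:
    """Monosome-size reads ending at a poly(A) junction with untemplated A's.

    The aligned (templated) portion ends exactly at the junction; the read
    continues with the configured number of adenosines absent from the
    reference.  Sequencing errors never touch the untemplated tail.
    """
    transcripts = {c.name: c for c in reference}
    reads, truth = [], []
    counter = 0
    for spec in specs:
        tr = transcripts[spec.gene_id]
        j, n_a = spec.junction_position, spec.untemplated_A_per_read
        if n_a < 0:
            raise ValueError("untemplated_A_per_read must be >= 0")
        s, e = tr.cds_interval
        if not s <= j <= e:
            raise ValueError(f"junction {j} outside CDS of {spec.gene_id}")
        if j < size_range[1]:
            raise ValueError(
                f"junction {j} within {size_range[1]} nt of the transcript start"
            )
        if "A" in tr.transcript_seq[j : j + n_a]:
            raise ValueError(
                f"reference carries an A within {n_a} nt after junction {j}; "
                "the untemplated tail would be ambiguous (see valid_polyA_junctions)"
            )
        lo, hi = size_range[0], max(size_range[0], size_range[1] - n_a)
        for _ in range(spec.tail_read_count):
            length = int(rng.integers(lo, hi + 1))
            footprint = tr.transcript_seq[j - length : j] + "A" * n_a
            rid = f"polyA{counter:06d}"
            counter += 1
            reads.append((rid, attach_adapter_umis(footprint, rng, read_length)))
            truth.append(
                TruthRecord(rid, spec.gene_id, "polyA", CUT_POINT, j, j - length, j, False)
            )
    return SimulatedLibrary(reads, truth, 0)


def simulate_start_codon_fixture(
    n_genes: int = 20,
    reads_per_length: int = 250,
    seed: int = 0,
    lengths: Sequence[int] = (20, 21, 22, 27, 28, 29, 30, 31, 32),
    initiation_fraction: float = 0.6,
    table: OffsetTable = DEFAULT_MONOSOME,
):
    """Start-codon metagene fixture for offset calibration.

    Places reads by the default offset table with a dominant
    initiation-proximal peak (AUG in the P site, A site at start+3) and a
    downstream-codon tail.  Returns (transcripts, aligned footprints).
    """
    from .reads import AlignedFootprint
    from .reporter import random_cds_transcripts

    rng = np.random.default_rng(seed)
    genes = random_cds_transcripts(n_genes, rng)
    fps = []
    i = 0
    for gene in genes:
        start = gene.cds_interval[0]
        for L in lengths:
            offset = table.classify(L).offsets[L]
            for _ in range(reads_per_length):
                if rng.random() < initiation_fraction:
                    a = start + 3
                else:
                    a = start + 3 + 3 * int(rng.integers(1, 4))
                fps.append(
                    AlignedFootprint(f"cal{i:06d}", gene.name, a - offset, a - offset + L)
                )
                i += 1
    return genes, fps


# ---------------------------------------------------------------------------
# Reporter-SGA plate pairs (1536 format, four colonies per strain)
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ["plate_id", "row", "col", "strain", "gfp", "rfp", "size_px", "is_border"]


def make_strain_layout(
    n_strains: int, n_rows: int = 32, n_cols: int = 48, border: int = 2
) -> dict[str, tuple[int, int]]:
    """Assign each strain a 2x2 colony block inside the border, row-major."""
    block_rows = (n_rows - 2 * border) // 2
    block_cols = (n_cols - 2 * border) // 2
    if n_strains > block_rows * block_cols:
        raise ValueError(
            f"{n_strains} strains do not fit in {block_rows * block_cols} interior blocks"
        )
    layout = {}
    for i in range(n_strains):
        br, bc = divmod(i, block_cols)
        layout[f"strain{i:04d}"] = (border + 2 * br, border + 2 * bc)
    return layout


@dataclasses.dataclass
class PlateGradient:
    """Smooth multiplicative spatial artifact, amplitudes in log2 units."""

    gfp_col_amp: float = 0.30
    gfp_row_amp: float = 0.20
    rfp_col_amp: float = 0.15
    rfp_row_amp: float = 0.10

    @classmethod
    def flat(cls) -> "PlateGradient":
        return cls(0.0, 0.0, 0.0, 0.0)

    def log2_factor(self, channel: str, row: np.ndarray, col: np.ndarray,
                    n_rows: int, n_cols: int) -> np.ndarray:
        ca = self.gfp_col_amp if channel == "gfp" else self.rfp_col_amp
        ra = self.gfp_row_amp if channel == "gfp" else self.rfp_row_amp
        return ca * np.sin(np.pi * col / (n_cols - 1)) + ra * np.cos(
            np.pi * row / (n_rows - 1)
        )


def simulate_plate_pair(
    strain_layout: Mapping[str, tuple[int, int]],
    spike_hits: Mapping[str, float] | None = None,
    gradient_params: PlateGradient | None = None,
    seed: int = 0,
    n_rows: int = 32,
    n_cols: int = 48,
    border: int = 2,
    gfp_mean: float = 1000.0,
    rfp_mean: float = 800.0,
    colony_sigma_log2: float = 0.15,
    strain_sigma_log2: float = 0.05,
    size_mean_px: float = 3500.0,
    size_sd_px: float = 600.0,
    size_outlier_fraction: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate matched NGD and OPT reporter plates in 1536 format.

    Colony intensities are log-normal around strain means, multiplied by a
    smooth spatial gradient; ``spike_hits`` maps strain -> log2 GFP shift
    applied on the NGD plate only (negative for Cue2-like reduced GFP).
    Colony sizes are normal with ``size_outlier_fraction`` resampled outside
    the 1500-6000 px acceptance band.
    """
    rng = np.random.default_rng(seed)
    spike_hits = dict(spike_hits or {})
    gradient = gradient_params if gradient_params is not None else PlateGradient()
    for strain, (r, c) in strain_layout.items():
        if not (border <= r <= n_rows - border - 2 and border <= c <= n_cols - border - 2):
            raise ValueError(f"strain {strain} block at ({r},{c}) outside the interior")
    unknown = set(spike_hits) - set(strain_layout)
    if unknown:
        raise ValueError(f"spiked strains missing from layout: {sorted(unknown)}")

    strain_effect = {
        s: rng.normal(0.0, strain_sigma_log2) for s in strain_layout
    }

    plates = {}
    for plate_id, reporter in (("NGD", "NGD-CGA"), ("OPT", "OPT")):
        rows_out = []
        occupied = {}
        for strain, (r0, c0) in strain_layout.items():
            for dr in (0, 1):
                for dc in (0, 1):
                    occupied[(r0 + dr, c0 + dc)] = strain
        for r in range(n_rows):
            for c in range(n_cols):
                is_border = r < border or c < border or r >= n_rows - border or c >= n_cols - border
                strain = "BORDER" if is_border else occupied.get((r, c), "EMPTY")
                if strain == "EMPTY":
                    continue
                g_log2 = (
                    np.log2(gfp_mean)
                    + (strain_effect.get(strain, 0.0))
                    + rng.normal(0.0, colony_sigma_log2)
                    + gradient.log2_factor("gfp", np.array(r), np.array(c), n_rows, n_cols)
                )
                if plate_id == "NGD" and strain in spike_hits:
                    g_log2 += spike_hits[strain]
                f_log2 = (
                    np.log2(rfp_mean)
                    + rng.normal(0.0, colony_sigma_log2)
                    + gradient.log2_factor("rfp", np.array(r), np.array(c), n_rows, n_cols)
                )
                size = rng.normal(size_mean_px, size_sd_px)
                if rng.random() < size_outlier_fraction:
                    size = rng.uniform(600, 1400) if rng.random() < 0.5 else rng.uniform(6100, 9000)
                rows_out.append(
                    {
                        "plate_id": f"{plate_id}-{reporter}",
                        "row": r,
                        "col": c,
                        "strain": strain,
                        "gfp": float(2.0 ** g_log2),
                        "rfp": float(2.0 ** f_log2),
                        "size_px": float(np.clip(size, 50, None)),
                        "is_border": bool(is_border),
                    }
                )
        plates[plate_id] = pd.DataFrame(rows_out, columns=PLATE_COLUMNS)
    return plates["NGD"], plates["OPT"]
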