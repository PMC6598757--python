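"""End-to-end pipeline: simulate -> trim -> filter -> align -> classify ->
tracks -> analyses, with a run manifest and full read accounting.

A run is driven by a single YAML config; every threshold the analyses use is
overridable there.  Deterministic stages are byte-identical across reruns with
the same config and seed; the manifest records the seed, parameter values and
per-stage read accounting so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asite import (
    DEFAULT_MONOSOME,
    build_tracks_by_class,
    calibrate_offsets,
    infer_site,
    read_offset_table,
    write_offset_table,
)
from .ngd import call_peaks, peak_spacing, windowed_occupancy
from .polya import flag_premature_polyA
from .reads import (
    ReadAccounting,
    TranscriptomeIndex,
    align_reads,
    filter_contaminants,
    trim_fastq,
)
from .reporter import build_reporter, build_rfp_control, stall_window, write_reference
from .screen import call_hits, score_plate
from .simulate import (
    PolyASpec,
    make_scenario,
    make_strain_layout,
    simulate_ngd_library,
    simulate_plate_pair,
    simulate_polyA_reads,
    valid_polyA_junctions,
)

logger = logging.getLogger("ngdtools")


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ("reference", "ngd", "polya", "screen")
    genotype: str = "dom34d ski2d"
    n_reads: int = 50_000
    reporter_kind: str = "NGD-CGA"
    offset_source: str = "default"  # default | calibrated | <path>
    contaminants_fasta: Path | None = None
    peak_min_fraction: float = 0.05
    peak_min_count: int = 5
    polya_min_reads: int = 3
    polya_min_A: int = 2
    alpha: float = 0.005
    screen_cutoff: float = 2.5
    screen_span: float = 0.5
    screen_aggregator: str = "median"
    n_strains: int = 300
    n_spiked_hits: int = 10
    spike_log2_effect: float = -1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "outdir" not in kwargs:
            raise ValueError("config requires 'outdir'")
        kwargs["outdir"] = Path(kwargs["outdir"])
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if kwargs.get("contaminants_fasta"):
            kwargs["contaminants_fasta"] = Path(kwargs["contaminants_fasta"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        valid = {"reference", "ngd", "polya", "screen"}
        if set(self.stages) - valid:
            raise ValueError(f"unknown stages: {set(self.stages) - valid}")
        if self.contaminants_fasta is not None and not self.contaminants_fasta.exists():
            raise ValueError(f"contaminants FASTA not found: {self.contaminants_fasta}")
        if self.offset_source not in ("default", "calibrated") and not Path(
            self.offset_source
        ).exists():
            raise ValueError(f"offset table not found: {self.offset_source}")


def demo_config(outdir: str | Path) -> RunConfig:
    """Small, fast demonstration run covering every stage."""
    return RunConfig(outdir=Path(outdir), n_reads=20_000, n_strains=150)


def process_library(
    fastq_path: str | Path,
    index: TranscriptomeIndex,
    contaminants: Mapping[str, str] | None = None,
    max_mismatch_frac: float = 0.10,
):
    """trim -> contaminant filter -> align, with conserved read accounting."""
    acc = ReadAccounting()
    trimmed = trim_fastq(fastq_path, accounting=acc)
    kept, removed = filter_contaminants(trimmed, contaminants or {})
    acc.contaminant = len(removed)
    acc.kept -= len(removed)
    alignments = align_reads(kept, index, max_mismatch_frac, accounting=acc)
    return alignments, trimmed, acc


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the manifest (also written to disk)."""
    config.validate()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "ngdtools_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    reporter = build_reporter(config.reporter_kind)
    opt = build_reporter("OPT")
    rfp = build_rfp_control()
    constructs = [reporter, opt, rfp] if config.reporter_kind != "OPT" else [reporter, rfp]

    if "reference" in config.stages:
        write_reference(
            constructs, out / "reference.fa", out / "reference.bed", out / "reference.gff3"
        )
        manifest["stages"]["reference"] = {
            "transcripts": [c.name for c in constructs],
            "files": ["reference.fa", "reference.bed", "reference.gff3"],
        }

    # each strain carries a single reporter, so the alignment reference holds
    # only the simulated library's transcripts (OPT is written for reference
    # output but would make every non-insert read ambiguous if indexed too)
    index = TranscriptomeIndex(
        {c.name: c.transcript_seq for c in (reporter, rfp)}
    )
    contaminants = {}
    if config.contaminants_fasta is not None:
        from Bio import SeqIO

        contaminants = {
            r.id: str(r.seq) for r in SeqIO.parse(str(config.contaminants_fasta), "fasta")
        }

    if "ngd" in config.stages:
        scenario = make_scenario(
            config.genotype, n_reads=config.n_reads, seed=config.seed
        )
        lib = simulate_ngd_library([rfp], reporter, scenario)
        fastq = out / "ngd_library.fastq"
        lib.write_fastq(fastq)
        alignments, _, acc = process_library(fastq, index, contaminants)

        if config.offset_source == "default":
            table = DEFAULT_MONOSOME
        elif config.offset_source == "calibrated":
            cds = {c.name: c.cds_interval for c in constructs}
            table = calibrate_offsets(alignments, cds)
        else:
            table = read_offset_table(config.offset_source)
        write_offset_table(table, out / "offsets.tsv")

        calls, dropped = [], 0
        for fp in alignments:
            call = infer_site(fp, table, len(index.sequences[fp.transcript_id]))
            if call is None:
                dropped += 1
            else:
                calls.append(call)
        tracks = build_tracks_by_class(calls, reporter.name, len(reporter))
        rfp_tracks = build_tracks_by_class(calls, rfp.name, len(rfp))
        for name, track in tracks.items():
            track.to_bedgraph(out / f"track_{name}nt.bedgraph")

        ngd_results: dict[str, Any] = {"read_accounting": acc.as_dict(), "dropped_calls": dropped}
        peak_sets = {
            name: call_peaks(t, config.peak_min_fraction, config.peak_min_count)
            for name, t in tracks.items()
        }
        pd.DataFrame(
            [
                {"size_class": n, "position": p.position, "count": p.count,
                 "fraction": p.fraction_of_track}
                for n, ps in peak_sets.items()
                for p in ps.peaks
            ]
        ).to_csv(out / "peaks.tsv", sep="\t", index=False)
        if "16" in peak_sets and "21" in peak_sets and peak_sets["16"].peaks:
            ngd_results["spacing_16_to_21_nt"] = peak_spacing(
                peak_sets["16"], peak_sets["21"]
            ).modal_spacing
        if "28" in peak_sets and "21" in peak_sets and peak_sets["28"].peaks:
            ngd_results["spacing_28_to_21_nt"] = peak_spacing(
                peak_sets["28"], peak_sets["21"]
            ).modal_spacing
        if reporter.stall_interval and {"21", "28"} <= set(tracks) and {"21", "28"} <= set(rfp_tracks):
            ngd_results["stall_window_occupancy"] = windowed_occupancy(
                tracks["21"], tracks["28"], stall_window(reporter, 300),
                rfp_tracks["21"], rfp_tracks["28"], rfp.cds_interval,
            )
        manifest["stages"]["ngd"] = ngd_results
        if not acc.conserved():
            raise RuntimeError("read accounting violated in ngd stage")

    if "polya" in config.stages:
        rng = np.random.default_rng(config.seed + 1)
        junction = next(
            j for j in valid_polyA_junctions(rfp, 3) if j >= rfp.cds_interval[0] + 300
        )
        specs = [PolyASpec(rfp.name, junction, tail_read_count=6, untemplated_A_per_read=3)]
        flags = {}
        for rep in ("rep1", "rep2"):
            lib = simulate_polyA_reads([rfp, reporter], specs, rng)
            fq = out / f"polya_{rep}.fastq"
            lib.write_fastq(fq)
            alignments, _, _ = process_library(fq, index, contaminants)
            flags[rep] = alignments
        flagged = flag_premature_polyA(
            flags, ["rep1", "rep2"], config.polya_min_reads, config.polya_min_A
        )
        (out / "polya_genes.txt").write_text("".join(f"{g}\n" for g in sorted(flagged)))
        manifest["stages"]["polya"] = {"flagged_genes": sorted(flagged)}

    if "screen" in config.stages:
        layout = make_strain_layout(config.n_strains)
        rng = np.random.default_rng(config.seed + 2)
        spiked = {
            s: config.spike_log2_effect
            for s in rng.choice(sorted(layout), size=config.n_spiked_hits, replace=False)
        }
        ngd_plate, opt_plate = simulate_plate_pair(layout, spiked, seed=config.seed + 3)
        ngd_scores = score_plate(ngd_plate, config.screen_aggregator, config.screen_span)
        opt_scores = score_plate(opt_plate, config.screen_aggregator, config.screen_span)
        hits = call_hits(ngd_scores, opt_scores, config.screen_cutoff)
        hits.to_csv(out / "screen_hits.tsv", sep="\t", index=False)
        manifest["stages"]["screen"] = {
            "n_strains": config.n_strains,
            "spiked": sorted(spiked),
            "hits": sorted(hits.loc[hits["is_hit"], "strain_id"]),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
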