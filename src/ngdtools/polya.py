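"""Premature-polyadenylation detection and Cue2-target calling.

Ribosomes translating into a premature poly(A) tail leave monosome footprints
whose 3' ends carry adenosines absent from the reference.  A gene is flagged
as prematurely polyadenylated when every required replicate contributes at
least ``min_reads`` footprints of 15-34 nt carrying more than one untemplated
A.  Cue2 targets are genes whose 15-17 nt (truncated-mRNA) footprint counts
drop reproducibly upon CUE2 deletion, assessed with a negative-binomial
two-condition Wald test (median-of-ratios size factors, method-of-moments
dispersions shrunk toward a 1/mean trend, Benjamini-Hochberg adjustment,
adjusted p < 0.005 and negative fold change).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .reads import AlignedFootprint


@dataclasses.dataclass(frozen=True)
class GeneFootprintStats:
    gene_id: str
    sample_id: str
    count_15_17: int
    count_20_32: int
    count_15_34: int
    polyA_read_count: int


@dataclasses.dataclass(frozen=True)
class TargetCallResult:
    gene_id: str
    log2_fold_change: float
    pvalue: float
    padj: float
    is_target: bool


def gene_footprint_stats(
    alignments: Iterable[AlignedFootprint],
    sample_id: str,
    min_A: int = 2,
) -> dict[str, GeneFootprintStats]:
    """Per-gene footprint size-class counts for one sample.

    Footprint size is the templated length; the poly(A) count is footprints of
    15-34 nt with >= ``min_A`` untemplated terminal adenosines.
    """
    acc: dict[str, list[int]] = {}
    for fp in alignments:
        c = acc.setdefault(fp.transcript_id, [0, 0, 0, 0])
        L = fp.length
        if 15 <= L <= 17:
            c[0] += 1
        if 20 <= L <= 32:
            c[1] += 1
        if 15 <= L <= 34:
            c[2] += 1
            if fp.untemplated_A >= min_A:
                c[3] += 1
    return {
        g: GeneFootprintStats(g, sample_id, *counts) for g, counts in acc.items()
    }


def flag_premature_polyA(
    samples: Mapping[str, Iterable[AlignedFootprint]],
    required_samples: Sequence[str],
    min_reads: int = 3,
    min_A: int = 2,
    size_range: tuple[int, int] = (15, 34),
) -> set[str]:
    """Genes with >= min_reads poly(A)-evidence footprints in EVERY required sample.

    A qualifying footprint has templated length inside ``size_range`` and more
    than ``min_A - 1`` (i.e. >= min_A) untemplated terminal A's.
    """
    missing = [s for s in required_samples if s not in samples]
    if missing:
        raise ValueError(f"missing required replicate sample(s): {missing}")
    flagged: set[str] | None = None
    for sample in required_samples:
        counts: dict[str, int] = {}
        for fp in samples[sample]:
            if size_range[0] <= fp.length <= size_range[1] and fp.untemplated_A >= min_A:
                counts[fp.transcript_id] = counts.get(fp.transcript_id, 0) + 1
        qualifying = {g for g, n in counts.items() if n >= min_reads}
        flagged = qualifying if flagged is None else flagged & qualifying
    return flagged or set()


def short_long_ratio(stats_: GeneFootprintStats, pseudocount: float = 1.0) -> float:
    """(16 nt class + pc) / (20-32 nt class + pc): truncation burden of a gene."""
    return (stats_.count_15_17 + pseudocount) / (stats_.count_20_32 + pseudocount)


# ---------------------------------------------------------------------------
# Negative-binomial two-condition test on 16 nt class counts
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (genes x samples matrix)."""
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) == 0:
        totals = counts.sum(axis=0).astype(float)
        sf = totals / np.exp(np.mean(np.log(totals)))
        return sf
    log_geo = np.log(positive).mean(axis=1)
    sf = np.exp((np.log(positive).sub(log_geo, axis=0)).median(axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def _dispersion_trend(mu: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Fit disp ~ a0 + a1/mu (both >= 0) robustly; returns (a0, a1)."""
    ok = (mu > 0) & (disp > 1e-7)
    if ok.sum() < 3:
        return (float(np.median(disp)) if len(disp) else 0.1, 0.0)
    x, y = 1.0 / mu[ok], disp[ok]
    a0, a1 = float(np.median(y)), 0.0
    for _ in range(2):  # one trimming pass
        coef, _ = optimize.nnls(np.column_stack([np.ones_like(x), x]), y)
        a0, a1 = float(coef[0]), float(coef[1])
        resid = y - (a0 + a1 * x)
        keep = np.abs(resid) < 3 * max(float(np.std(resid)), 1e-12)
        if keep.all() or keep.sum() < 3:
            break
        x, y = x[keep], y[keep]
    return max(a0, 1e-8), max(a1, 0.0)


def call_cue2_targets(
    counts: pd.DataFrame,
    control_samples: Sequence[str],
    deletion_samples: Sequence[str],
    alpha: float = 0.005,
    shrink_weight: float = 0.8,
    min_dispersion: float = 0.01,
    strict_per_replicate: bool = False,
) -> list[TargetCallResult]:
    """NB Wald test for reproducible 16 nt RPF reduction upon CUE2 deletion.

    ``counts`` is a genes x samples matrix of 15-17 nt footprint counts.
    Genes with zero counts in all samples are excluded from testing (not
    assigned p = 1) to avoid diluting the BH adjustment.  ``strict_per_
    replicate`` additionally requires a reduction in every replicate pairing.
    """
    if len(control_samples) < 2 or len(deletion_samples) < 2:
        raise ValueError("need >= 2 replicates per condition")
    cols = list(control_samples) + list(deletion_samples)
    k = counts[cols]
    if (k[control_samples].to_numpy().sum() == 0) or (
        k[deletion_samples].to_numpy().sum() == 0
    ):
        raise ValueError("a condition has zero total counts")
    tested = k[(k.sum(axis=1) > 0)]
    sf = size_factors(k)
    q = tested / sf

    qa, qb = q[list(control_samples)].to_numpy(), q[list(deletion_samples)].to_numpy()
    na, nb = qa.shape[1], qb.shape[1]
    mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)
    mu = q.to_numpy().mean(axis=1)

    # method-of-moments dispersion from pooled within-condition variance:
    # E[var_pooled] = mean(mu_c) + disp * mean(mu_c^2), so divide by the mean
    # of squared condition means (the overall mean squared would bias the
    # estimate upward for genes with a real fold change)
    ss = ((qa - mu_a[:, None]) ** 2).sum(axis=1) + ((qb - mu_b[:, None]) ** 2).sum(axis=1)
    var_pooled = ss / (na + nb - 2)
    mu_sq = (mu_a**2 + mu_b**2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_raw = np.where(mu > 0, (var_pooled - mu) / np.maximum(mu_sq, 1e-12), 0.0)
    disp_raw = np.clip(disp_raw, 1e-8, 10.0)

    a0, a1 = _dispersion_trend(mu, disp_raw)
    trend = np.maximum(a0 + a1 / np.maximum(mu, 1e-12), 1e-8)
    # with few replicates the per-gene moment estimate carries ~2 df of noise;
    # clip it to a band around the trend before the log-space shrinkage so a
    # single wild estimate can neither inflate nor deflate the SE
    disp_clipped = np.clip(disp_raw, trend / 10.0, trend * 100.0)
    disp = np.exp(
        (1 - shrink_weight) * np.log(disp_clipped) + shrink_weight * np.log(trend)
    )
    disp = np.maximum(disp, min_dispersion)

    pc = 0.5  # stabilizes lfc and SE at low counts
    mu_a_s, mu_b_s = np.maximum(mu_a, pc), np.maximum(mu_b, pc)
    lfc = np.log2(mu_b_s / mu_a_s)
    se = np.sqrt((1.0 / mu_a_s + disp) / na + (1.0 / mu_b_s + disp) / nb) / np.log(2)
    z = lfc / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")

    results = []
    for i, gene in enumerate(tested.index):
        is_target = bool(padj[i] < alpha and lfc[i] < 0)
        if is_target and strict_per_replicate:
            a_norm = qa[i]
            b_norm = qb[i]
            is_target = bool(b_norm.max() < a_norm.min())
        results.append(
            TargetCallResult(str(gene), float(lfc[i]), float(pvals[i]), float(padj[i]), is_target)
        )
    return results


def overlap_sets(polyA_genes: set[str], cue2_dependent_genes: set[str]) -> tuple[int, int, int]:
    """(n poly(A) genes, n Cue2-dependent genes, n overlap)."""
    return (
        len(polyA_genes),
        len(cue2_dependent_genes),
        len(polyA_genes & cue2_dependent_genes),
    )


def results_table(results: Sequence[TargetCallResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in results],
        columns=["gene_id", "log2_fold_change", "pvalue", "padj", "is_target"],
    )
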