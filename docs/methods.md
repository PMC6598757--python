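# Methods

## Model and conventions

All coordinates are 0-based, half-open, on transcript space; GFF3 output is
1-based closed. An **A-site position** is the first nucleotide of the codon
in the ribosomal A site. A **cut point** is the first nucleotide beyond the
3′ end of a protected fragment, so "cleavage before position x" is
single-valued.

The collision geometry implemented (and generated) is: lead ribosomes stall
with A sites on stall-insert codons 2–5; a collided ribosome's A site sits
exactly 30 nt upstream of its lead's; the endonucleolytic cut is placed at
the 5′ boundary of the collided ribosome's A-site codon. Published track
figures show the cut within the collided A site; placing it at the codon's
5′ edge makes every spacing statistic integer-exact, and sub-codon placement
remains configurable in the generator. With these conventions the modal
16 nt→21 nt and 28 nt→21 nt peak spacings are both exactly 30 nt, which the
pipeline reproduces end-to-end from raw FASTQ.

### Offset tables

| mode | class | lengths (nt) | rule |
|---|---|---|---|
| monosome | 16 | 15–17 | 3′ end = cut point |
| monosome | 21 | 20:16, 21:17, 22:17 | 5′ end + offset = A site |
| monosome | 28 | 27:16, 28:16, 29–32:17 | 5′ end + offset |
| disome | 46 | 44–48 | 3′ end = cut point |
| disome | 54 | 51–54: 47 | 5′ end + offset |
| disome | 60 | 57–62: 47 | 5′ end + offset |
| in vitro | — | 60–65 | 3′ end = cut point |

Monosome lengths 18–19 and 23–26 nt are deliberately unclassified; no
interpolation is attempted. Calibration anchors on start codons: the
dominant initiation-proximal peak is taken to hold the AUG in the P site, so
the A site is at start+3 and offset(L) = (start+3) − modal 5′-end position of
L-length reads within [start−40, start+20). Lengths with fewer than 100
reads near starts fall back to the defaults with a warning; tied modal bins
resolve toward the smaller offset.

## Reporter constructs

The reporter is a single ORF, GFP-2A-FLAG-His3, with stall variants carrying
(CGA)×12 or (AAA)×12 inserted after 90 HIS3 codons ("inserted 90 codons
into HIS3" is read as insertion after codon 90; replacement starting at
codon 90 would shift every downstream coordinate by 36 nt and is not
implemented). The true vector sequences are not required by any analysis —
everything downstream depends on geometry — so the shipped segments are
deterministic stand-ins of realistic lengths (GFP 717, 2A 60, FLAG 24,
HIS3 660 nt including the stop), generated once from a fixed seed with sense
codons only, no CGA codons outside the insert, and no A₆ homopolymers, so
stall peaks and untemplated-A calls are unambiguous. Transcripts carry 50 nt
UTRs. An RFP control transcript (678 nt ORF) provides the normalization
denominator.

## Synthetic data: what it emulates, what it does not

The generator inverts the inference offset tables: for a drawn length the
5′ end is placed at (A site − offset), or the 3′ end at the cut point, then
the footprint is wrapped as [4 random nt][footprint][6 random nt][constant
adapter CACTCGGGCACCAAGGA] and truncated to the sequencing read length
(default 51 cycles; disome libraries default to 100 cycles because a 62 nt
footprint plus 10 UMI nt and a ≥5 nt adapter overlap cannot fit in 51).
Sequencing errors (default rate 0) touch only templated bases, never the
untemplated-A tail, keeping poly(A) ground truth exact. Qualities are
constant; the pipeline ignores them.

Genotype presets set the RPF class balance (fractions of 16/21/28 nt reads)
to qualitatively mirror the published track panels: *dom34Δ ski2Δ*
(16-class stabilized) 0.30/0.40/0.30; *cue2Δ dom34Δ ski2Δ* 0/0.57/0.43;
the Fig-4H-style pair differs in background rate (0.2 vs 0.5 reads per CDS
nt) so the SLH1-deleted scenario concentrates ~2.5× more 21+28 nt signal in
the stall window. Background reads are uniform over all CDSs (reporter and
RFP) at an absolute per-nt rate — at very small library sizes background
therefore dominates, which is intentional. Stall codon weights default to
uniform over insert codons 2–5.

Not modeled: ligation/PCR bias, rRNA contamination composition, MNase
sequence bias, UMI collisions, spliced transcripts. Passing tests therefore
demonstrate the correctness of the pipeline's logic and geometry, not
robustness to those real-data artifacts; real libraries enter via SAM import
instead.

Plate simulation: 32×48 (1536) grids with a 2-position border, each strain a
2×2 colony block; log-normal colony intensities (σ = 0.15 log₂ units per
colony, 0.05 between strains), a smooth multiplicative spatial gradient with
different amplitudes for GFP and RFP (so the ratio retains a removable
trend), spiked hits as log₂ GFP shifts on the NGD plate only, and colony
sizes normal(3500, 600 px) with a configurable fraction resampled outside
the 1500–6000 px acceptance band.

## Read processing

Trimming locates the constant adapter allowing a truncated match at the read
end (minimum 5 nt overlap) and ≤1 mismatch, then strips the 6 nt UMI before
it and the 4 nt UMI at the 5′ end. Kept inserts are 15–90 nt. Placement is
ungapped against the small transcriptome via exact 15-mer seeds at both read
ends with a brute-force rescue scan; the paper-scale genome alignment is out
of scope (real data enter as transcriptome SAM/BAM). Best placement
minimizes mismatches, then maximizes templated length; ties are dropped as
multimapped (unique-hit contract), and the mismatch fraction over the
templated portion must be ≤0.1.

Trailing read bases that fail to match are counted as **untemplated
adenosines** only when the entire trailing run is A and ≥15 nt of the read
match the reference; an A in the tail that happens to match the reference is
templated (maximal templated extension, the soft-clip semantics used on SAM
import, where 3′ soft-clips of all-A bases are reconstructed as untemplated).
Consequence: at a junction where the reference itself continues with A's,
part of a real poly(A) tail is absorbed as templated sequence and the
untemplated count deflates. The stand-in reference avoids long A-runs, and
the generator refuses junctions where this ambiguity would arise
(`valid_polyA_junctions`); on real references this deflation is a documented
limitation, not silently corrected. UMI deduplication exists
(`dedup_umis`) but is off by default — the library description includes
random nucleotides but no dedup step.

Every raw read lands in exactly one terminal category (kept/no-adapter/
too-short/too-long/contaminant/unaligned/multimapped/aligned); this
conservation is asserted in the pipeline.

## Analyses

**Peaks** are strict local maxima (±1 nt) carrying ≥5 reads and ≥5% of the
track; both thresholds are configurable and are repository defaults chosen to
be robust on the quadruplet fixtures across seeds (the source analyses show
tracks without a stated peak rule). **Spacing** weights each ordered peak
pair (0 < lag ≤ 60 nt) by min(counts); ties resolve to the smaller lag with
a warning. **Windowed occupancy** is per-nt density in the stall window
(300 nt upstream of the insert through its end) divided by per-nt density
over the RFP CDS; per-nt density was chosen over total-count normalization
because it is invariant to the control transcript's length. **Cut-site
concordance** is the fraction of total in vitro cut weight within ±1 nt of
an in vivo cut peak.

**Premature poly(A) flagging**: a gene qualifies when every required
replicate has ≥3 footprints of templated length 15–34 nt with ≥2 untemplated
A's. **Cue2 targets**: genes × samples 16 nt count matrices are tested with
a negative-binomial Wald test — median-of-ratios size factors; per-gene
method-of-moments dispersions (unbiased denominator: the mean of squared
condition means) clipped to [trend/10, trend×100] and shrunk 80% toward a
robust a₀ + a₁/μ trend in log space, floored at 0.01; Wald z on log₂ fold
change with delta-method SE; Benjamini–Hochberg adjustment. Genes with zero
counts everywhere are excluded rather than assigned p = 1, to avoid diluting
the adjustment. The heavy shrinkage reflects the 2 residual degrees of
freedom per gene at n = 2+2; on matched simulations this caller recovers
more true 8-fold reductions than pydeseq2 (used as an independent
cross-check in the tests) while holding the null rejection fraction at
adjusted p < 0.005 to ≤0.005. "Reproducible reduction" is operationalized
as the pooled-replicate test; a strict mode additionally requires every
deletion replicate below every control replicate.

**Screen scoring**: border and size-outlier colonies removed (band inclusive
at 1500 and 6000 px); per-strain median (mean selectable) GFP and RFP;
log₂(GFP/RFP); per-plate LOESS (statsmodels lowess, span 0.5) sequentially
against column then row index — chosen because plate artifacts are spatial;
the covariate set is configurable; Z-scores use the sample standard
deviation. The source description mixes "median GFP and RFP values" with
"log₂(mean GFP/mean RFP)"; the median is the default for robustness. Hits:
|Z| strictly > 2.5 on the NGD plate and Z strictly inside (−2.5, 2.5) on the
OPT plate. Plates with <10 strains skip LOESS and center on the median.

## Problem sizes and determinism

Test and acceptance runs use 10k–50k-read libraries, 20-transcript
calibration fixtures (250 reads per length per CDS), 200–2000-gene count
matrices, and 300-strain plate pairs — sizes at which every statistic of
interest is far from its noise floor while the whole suite runs in about a
minute. All randomness flows from explicit seeds; identical seeds give
byte-identical FASTQ and identical manifests (timestamps excluded).

## Known limitations

* Ungapped, transcriptome-only placement: indel-containing SAM records are
  skipped (counted), spliced alignment unsupported.
* Untemplated-A deflation at A-rich junctions (above).
* The NB test is a self-contained stand-in with moment dispersions; it does
  not implement Cox–Reid adjusted likelihood or outlier refitting.
* LOESS normalization estimates the spatial trend from the plate itself; a
  plate whose true biology is spatially structured would be partially
  flattened.
* Stand-in reporter segments share only length and composition constraints
  with the real vector; sequence-specific effects are out of scope.
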