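# ngdtools

Size-resolved ribosome-footprint analysis of **No-Go Decay (NGD)** — the mRNA
surveillance pathway that cleaves transcripts on which ribosomes stall — plus
the reporter-SGA screen scoring by which the NGD endonuclease **Cue2** was
identified. The package is a tested pipeline driven by a synthetic-data
generator, so every stage runs at desk scale with no downloads; real
transcriptome alignments can be imported as SAM/BAM.

It is written for researchers analyzing yeast ribosome profiling of stalling
reporters or colony-array fluorescence screens.

## The science in brief

Three monosome footprint sizes report three ribosome states:

* **21 nt** — classical (unrotated) ribosomes waiting to decode the A-site
  codon. On a GFP-2A-FLAG-His3 reporter carrying (CGA)×12 inserted 90 codons
  into *HIS3*, their A sites pile onto stall codons 2–5 (a quadruplet).
* **28 nt** — rotated pre-translocation ribosomes; collided ribosomes stack
  with their A sites exactly **30 nt upstream** of the lead's (A site to A
  site distance of a stacked ribosome).
* **16 nt** — ribosomes that ran into a truncated 3′ end. Their 3′ ends mark
  the endonucleolytic **cut point**, which falls in the collided ribosome's
  A site — again 30 nt upstream of the lead.

A-site positions are inferred from the 5′ end plus a length-specific offset
(21 nt class: 20→16, 21→17, 22→17; 28 nt class: 27→16, 28→16, 29–32→17;
disomes: offset 47), calibrated from start-codon metagenes; 15–17 nt
fragments use their 3′ ends directly. Genes translating into premature
poly(A) tails leave footprints with ≥2 untemplated 3′ adenosines; Cue2
targets are genes whose 16 nt footprint counts drop reproducibly upon *CUE2*
deletion (negative-binomial Wald test, BH-adjusted p < 0.005). The screen
scores 1536-format plates: drop borders and size outliers (<1500 or >6000
px), take per-strain median GFP and RFP, LOESS-normalize log₂(GFP/RFP) per
plate, Z-score, and call strains with |Z| > 2.5 on an NGD reporter but not on
the control (OPT) reporter.

## Worked example

```bash
ngdtools run --demo --outdir demo_run
```

runs every stage (reference build, 20 000-read simulation, trim → align →
classify → tracks → peaks → spacing, poly(A) flagging, plate-pair screen) and
prints:

```
run complete; manifest at demo_run/manifest.json
  reference: ['files', 'transcripts']
  ngd: ['dropped_calls', 'read_accounting', 'spacing_16_to_21_nt', 'spacing_28_to_21_nt']
  polya: ['flagged_genes']
  screen: ['hits', 'n_strains', 'spiked']
```

`demo_run/manifest.json` then contains, among per-stage read accounting:

```
"spacing_16_to_21_nt": 30,
"spacing_28_to_21_nt": 30,
"stall_window_occupancy": 115.05,
```

The two spacings are the modal distances between cleavage-site / collided-
ribosome peaks and the lead-ribosome peaks — exactly 30 nt, the stacked-
ribosome geometry. The occupancy value is the RFP-normalized 21+28 nt
density over the stall window (300 nt upstream of the insert through its
end), the statistic used to compare genotypes. The same steps are available
as individual subcommands (`build-ref`, `simulate`, `trim`, `align`,
`calibrate`, `tracks`, `ngd`, `polya`, `targets`, `screen`, `plot`) and as
library functions.

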