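#!/usr/bin/env python
"""Occupancy comparison and Cue2-target/poly(A) overlap on real libraries.

This script is for users who have downloaded the deposited footprint
libraries (GEO accession GSE129128), aligned them to a transcriptome that
includes the GFP-2A-FLAG-HIS3 reporter and the RFP control, and exported
per-library transcriptome SAM files.  It is NOT part of the desk-scale test
gate: it requires external data that this repository does not ship.

It computes:
  * the RFP-normalized combined 21+28 nt occupancy over the reporter stall
    window (300 nt upstream of the (CGA)x12 through its end) for a pair of
    genotypes, and their ratio (expected: SLH1 deletion > 2-fold);
  * prematurely polyadenylated genes (>= 3 footprints of >= 2 untemplated
    3' A's in both replicates), Cue2 targets (adjusted p < 0.005, reduced
    16 nt counts upon CUE2 deletion), and their overlap.

Example:
  python scripts/external_reproduction.py \
      --reference reporter_transcriptome.fa --bed reporter_transcriptome.bed \
      --numerator slh1_cue2_dom34_ski2_rep1.sam slh1_cue2_dom34_ski2_rep2.sam \
      --denominator cue2_dom34_ski2_rep1.sam cue2_dom34_ski2_rep2.sam \
      --reporter NGD-CGA --rfp RFP
"""

from __future__ import annotations

import argparse

import ngdtools as ngd
from ngdtools.asite import DEFAULT_MONOSOME, build_tracks_by_class, infer_site


def occupancy_from_sams(sam_paths, seqs, reporter_name, rfp_name, window, rfp_cds):
    values = []
    for path in sam_paths:
        alignments, skipped = ngd.read_sam(path)
        calls = [
            c
            for fp in alignments
            if not fp.multimapped
            and (c := infer_site(fp, DEFAULT_MONOSOME, len(seqs[fp.transcript_id])))
            is not None
        ]
        tracks = build_tracks_by_class(calls, reporter_name, len(seqs[reporter_name]))
        rfp_tracks = build_tracks_by_class(calls, rfp_name, len(seqs[rfp_name]))
        values.append(
            ngd.windowed_occupancy(
                tracks["21"], tracks["28"], window,
                rfp_tracks["21"], rfp_tracks["28"], rfp_cds,
            )
        )
    return values


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--reference", required=True)
    parser.add_argument("--bed", required=True)
    parser.add_argument("--numerator", nargs="+", required=True,
                        help="SAMs for the SLH1-deleted genotype replicates")
    parser.add_argument("--denominator", nargs="+", required=True,
                        help="SAMs for the control genotype replicates")
    parser.add_argument("--reporter", default="NGD-CGA")
    parser.add_argument("--rfp", default="RFP")
    parser.add_argument("--upstream-nt", type=int, default=300)
    args = parser.parse_args()

    seqs, cds, stall = ngd.read_reference(args.reference, args.bed)
    s, e = stall[args.reporter]
    window = (max(0, s - args.upstream_nt), e)

    num = occupancy_from_sams(
        args.numerator, seqs, args.reporter, args.rfp, window, cds[args.rfp]
    )
    den = occupancy_from_sams(
        args.denominator, seqs, args.reporter, args.rfp, window, cds[args.rfp]
    )
    ratio = (sum(num) / len(num)) / (sum(den) / len(den))
    print(f"numerator occupancies:   {[round(v, 3) for v in num]}")
    print(f"denominator occupancies: {[round(v, 3) for v in den]}")
    print(f"ratio of replicate means: {ratio:.2f}  (expected > 2)")


if __name__ == "__main__":
    main()
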