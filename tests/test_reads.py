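"""Trimming, contaminant filtering, placement and SAM round trips, checked
against brute-force oracles."""

import dataclasses

import numpy as np
import pytest

import ngdtools as ngd
from ngdtools.reads import (
    ADAPTER_CONSTANT,
    MIN_INSERT,
    TranscriptomeIndex,
    trim_read,
)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestTrimRead:
    def test_roundtrip_over_random_footprints(self, rng):
        """attach_adapter_umis -> trim_read recovers the footprint exactly."""
        for _ in range(1000):
            n = int(rng.integers(15, 35))
            footprint = random_seq(rng, n)
            raw = ngd.attach_adapter_umis(footprint, rng, read_length=51)
            tr = trim_read("r", raw)
            assert tr.status == "kept"
            assert tr.insert_seq == footprint

    def test_adapter_only_read_too_short(self):
        raw = "ACGT" + "CCGGTA" + ADAPTER_CONSTANT
        assert trim_read("r", raw).status == "too_short"

    def test_single_mismatch_in_adapter_still_trimmed(self, rng):
        footprint = random_seq(rng, 21)
        raw = ngd.attach_adapter_umis(footprint, rng, read_length=60)
        pos = raw.index(ADAPTER_CONSTANT) + 8
        mutated = raw[:pos] + ("G" if raw[pos] != "G" else "T") + raw[pos + 1 :]
        tr = trim_read("r", mutated)
        assert tr.status == "kept" and tr.insert_seq == footprint

    def test_no_adapter(self, rng):
        assert trim_read("r", random_seq(rng, 51)).status == "no_adapter"

    def test_oversized_insert_too_long(self, rng):
        footprint = random_seq(rng, 95)
        raw = ngd.attach_adapter_umis(footprint, rng, read_length=150)
        assert trim_read("r", raw).status == "too_long"

    def test_umis_recovered(self, rng):
        footprint = random_seq(rng, 20)
        raw = ngd.attach_adapter_umis(footprint, rng, read_length=60)
        tr = trim_read("r", raw)
        assert raw.startswith(tr.umi5) and len(tr.umi5) == 4
        assert raw[4 + 20 : 4 + 20 + 6] == tr.umi3


class TestFilterContaminants:
    CONTAMINANT = {"rRNA": "ACGTACGTTTGCACGGTTAGCCGGATTTACGGCGGCATTACG"}

    def test_empty_set_is_identity(self, rng):
        reads = [ngd.TrimmedRead(f"r{i}", random_seq(rng, 20), "", "", "kept") for i in range(5)]
        kept, removed = ngd.filter_contaminants(reads, {})
        assert kept == reads and removed == []

    def test_exact_substring_removed(self):
        read = ngd.TrimmedRead("r", self.CONTAMINANT["rRNA"][5:30], "", "", "kept")
        kept, removed = ngd.filter_contaminants([read], self.CONTAMINANT)
        assert removed == [read] and kept == []

    def test_three_mismatches_in_21nt_kept(self):
        sub = list(self.CONTAMINANT["rRNA"][5:26])
        for i in (2, 9, 15):
            sub[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sub[i]]
        read = ngd.TrimmedRead("r", "".join(sub), "", "", "kept")
        kept, removed = ngd.filter_contaminants([read], self.CONTAMINANT)
        assert kept == [read]  # 3/21 > 10%

    def test_two_mismatches_in_21nt_removed(self):
        sub = list(self.CONTAMINANT["rRNA"][5:26])
        for i in (2, 9):
            sub[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sub[i]]
        kept, removed = ngd.filter_contaminants(
            [ngd.TrimmedRead("r", "".join(sub), "", "", "kept")], self.CONTAMINANT
        )
        assert len(removed) == 1  # 2/21 < 10%... (0.095)


def brute_force_align(read, sequences, max_mismatch_frac=0.1):
    """Independent all-positions oracle for ungapped placement."""
    best, best_key = [], None
    for tid, ref in sequences.items():
        for pos in range(len(ref) - MIN_INSERT + 1):
            k = min(len(read), len(ref) - pos)
            overhang = read[k:]
            if overhang and set(overhang) != {"A"}:
                continue
            t = k
            while t > 0 and read[t - 1] != ref[pos + t - 1]:
                t -= 1
            tail = read[t:k]
            if (tail or overhang) and t >= MIN_INSERT and set(tail) <= {"A"}:
                templated, untA = t, (k - t) + len(overhang)
            else:
                if overhang:
                    continue
                templated, untA = k, 0
            mism = sum(a != b for a, b in zip(read[:templated], ref[pos : pos + templated]))
            if templated < MIN_INSERT or mism > max_mismatch_frac * templated:
                continue
            key = (mism, -templated)
            if best_key is None or key < best_key:
                best_key, best = key, [(tid, pos, templated, untA, mism)]
            elif key == best_key:
                best.append((tid, pos, templated, untA, mism))
    return best_key, best


class TestAlignFootprint:
    def test_exact_substring(self, index, reporter):
        read = reporter.transcript_seq[200:225]
        fp = ngd.align_footprint("r", read, index)
        assert fp.transcript_id == reporter.name
        assert (fp.start, fp.end, fp.untemplated_A, fp.mismatches) == (200, 225, 0, 0)

    def test_untemplated_A_tail(self, index, rfp):
        j = next(x for x in ngd.valid_polyA_junctions(rfp, 3) if x > 100)
        read = rfp.transcript_seq[j - 18 : j] + "AAA"
        fp = ngd.align_footprint("r", read, index)
        assert (fp.untemplated_A, fp.length, fp.end) == (3, 18, j)

    def test_nonA_trailing_bases_count_as_mismatches(self, index, reporter):
        seq = reporter.transcript_seq
        pos = 300
        read = seq[pos : pos + 20]
        last = "G" if seq[pos + 19] != "G" else "C"
        read = read[:-1] + last
        fp = ngd.align_footprint("r", read, index)
        assert fp.untemplated_A == 0 and fp.mismatches >= 1

    def test_duplicated_substring_multimaps(self):
        ref = {"t": "ACGGATTTACGGCGGCATTACGTTT" * 2 + "GATTACACGGATCTTCCGG"}
        idx = TranscriptomeIndex(ref)
        read = ref["t"][:20]  # present at offsets 0 and 25
        fp = ngd.align_footprint("r", read, idx)
        assert fp.multimapped

    def test_agrees_with_brute_force_oracle(self, index, rng):
        """1000 random reads (clean, mutated, tailed) match the oracle."""
        seqs = index.sequences
        names = list(seqs)
        checked = 0
        for _ in range(1000):
            tid = names[rng.integers(len(names))]
            ref = seqs[tid]
            L = int(rng.integers(15, 33))
            pos = int(rng.integers(0, len(ref) - L))
            read = ref[pos : pos + L]
            style = rng.integers(3)
            if style == 1:  # one internal mutation
                i = int(rng.integers(L))
                read = read[:i] + "ACGT"[rng.integers(4)] + read[i + 1 :]
            elif style == 2:  # untemplated tail
                read = read + "A" * int(rng.integers(1, 4))
            fp = ngd.align_footprint("r", read, index)
            key, placements = brute_force_align(read, seqs)
            if fp is None:
                assert key is None
                continue
            if fp.multimapped:
                assert len(placements) > 1
                continue
            assert len(placements) == 1
            tid_o, pos_o, templated, untA, mism = placements[0]
            assert (fp.transcript_id, fp.start, fp.length, fp.untemplated_A, fp.mismatches) == (
                tid_o, pos_o, templated, untA, mism
            )
            checked += 1
        assert checked > 800


class TestReadAccounting:
    def test_every_read_in_exactly_one_category(self, aligned_library, ngd_library):
        _, _, acc = aligned_library
        assert acc.total == len(ngd_library.reads)
        assert acc.conserved()


class TestSamRoundTrip:
    def test_roundtrip_500_random_alignments(self, tmp_path, index, rng):
        seqs = index.sequences
        names = list(seqs)
        fps = []
        for i in range(500):
            tid = names[rng.integers(len(names))]
            L = int(rng.integers(15, 33))
            pos = int(rng.integers(0, len(seqs[tid]) - L))
            untA = int(rng.integers(0, 4))
            fps.append(ngd.AlignedFootprint(f"r{i}", tid, pos, pos + L, untA, 0))
        path = tmp_path / "rt.sam"
        ngd.write_sam(fps, seqs, path)
        back, skipped = ngd.read_sam(path)
        assert skipped == 0
        assert sorted(back, key=lambda f: f.read_id) == sorted(fps, key=lambda f: f.read_id)

    def test_non_A_softclip_not_untemplated(self, tmp_path, index):
        # hand-written SAM record with 3' soft-clip AAG
        path = tmp_path / "clip.sam"
        tid = list(index.sequences)[0]
        seq = index.sequences[tid][100:120] + "AAG"
        path.write_text(
            f"@HD\tVN:1.6\n@SQ\tSN:{tid}\tLN:{len(index.sequences[tid])}\n"
            f"r1\t0\t{tid}\t101\t255\t20M3S\t*\t0\t0\t{seq}\t*\tNM:i:0\n"
        )
        back, _ = ngd.read_sam(path)
        assert back[0].untemplated_A == 0

    def test_indel_records_skipped(self, tmp_path, index):
        path = tmp_path / "indel.sam"
        tid = list(index.sequences)[0]
        seq = index.sequences[tid][100:121]
        path.write_text(
            f"@HD\tVN:1.6\n@SQ\tSN:{tid}\tLN:{len(index.sequences[tid])}\n"
            f"r1\t0\t{tid}\t101\t255\t10M1D11M\t*\t0\t0\t{seq}\t*\n"
        )
        back, skipped = ngd.read_sam(path)
        assert back == [] and skipped == 1

    def test_empty_set_header_only(self, tmp_path, index):
        path = tmp_path / "empty.sam"
        ngd.write_sam([], index.sequences, path)
        back, _ = ngd.read_sam(path)
        assert back == []
        assert all(l.startswith("@") for l in path.read_text().splitlines())


class TestDedupUmis:
    def test_collapses_identical_coordinates_and_umis(self, index):
        tid = list(index.sequences)[0]
        fps = [ngd.AlignedFootprint(f"r{i}", tid, 100, 121) for i in range(3)]
        trimmed = {
            "r0": ngd.TrimmedRead("r0", "x", "ACGT", "AACCGG", "kept"),
            "r1": ngd.TrimmedRead("r1", "x", "ACGT", "AACCGG", "kept"),  # dup of r0
            "r2": ngd.TrimmedRead("r2", "x", "TTTT", "AACCGG", "kept"),
        }
        out = ngd.reads.dedup_umis(fps, trimmed)
        assert [f.read_id for f in out] == ["r0", "r2"]
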