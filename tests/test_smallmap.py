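"""Alignment vs an exhaustive-offset oracle, fractional counting vs a
per-read assignment oracle, coverage vs a naive pileup, length medians."""

import numpy as np
import pandas as pd
import pytest

from tsrnapipe import refmodel, smallmap
from tsrnapipe.refmodel import FIVE_PRIME, THREE_PRIME, HalfFeature
from tsrnapipe.smallmap import (
    AlignmentHit,
    LengthDistribution,
    align_reads,
    compute_coverage,
    count_features,
    length_stats,
    rpm_normalize,
)


def brute_force_align(seq, refset, max_mismatch=1):
    """Oracle: scan every offset of every reference, keep best tier."""
    placements = []
    for ref_id, ref in refset.sequences.items():
        for start in range(len(ref.sequence) - len(seq) + 1):
            mism = sum(
                1
                for a, b in zip(seq, ref.sequence[start:])
                if a != b or a == "N"
            )
            if mism <= max_mismatch:
                placements.append((ref_id, start, mism))
    if not placements:
        return []
    best = min(m for *_, m in placements)
    return sorted(p for p in placements if p[2] == best)


class TestAlignment:
    def test_exact_prefix_read_single_hit(self, tiny_refset):
        seq = tiny_refset.sequences["tA"].sequence[:20]
        hits, unaligned = align_reads([("r1", seq)], tiny_refset)
        assert unaligned == 0
        [hit] = hits
        assert (hit.ref_id, hit.start, hit.mismatches, hit.n_hits) == ("tA", 0, 0, 1)

    def test_one_mismatch_threshold(self, tiny_refset):
        seq = list(tiny_refset.sequences["tA"].sequence[:20])
        seq[9] = {"A": "C"}.get(seq[9], "A")
        seq = "".join(seq)
        hits, _ = align_reads([("r1", seq)], tiny_refset, max_mismatch=1)
        assert hits and hits[0].mismatches == 1
        hits0, unaligned0 = align_reads([("r1", seq)], tiny_refset, max_mismatch=0)
        assert not hits0 and unaligned0 == 1

    def test_non_acgtn_read_rejected(self, tiny_refset):
        with pytest.raises(ValueError, match="non-ACGTN"):
            align_reads([("r1", "ACGTX" + "A" * 15)], tiny_refset)

    def test_matches_exhaustive_offset_oracle(self, tiny_refset):
        # 500 random 20-nt reads: some pure random, some mutated fragments
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        refs = list(tiny_refset.sequences.values())
        reads = []
        for i in range(500):
            if i % 2:
                reads.append(("".join(rng.choice(bases, size=20)), f"rand{i}"))
            else:
                ref = refs[rng.integers(len(refs))]
                start = int(rng.integers(0, len(ref.sequence) - 20 + 1))
                frag = list(ref.sequence[start : start + 20])
                for _ in range(int(rng.integers(0, 3))):  # 0-2 mutations
                    j = int(rng.integers(20))
                    frag[j] = str(rng.choice(bases))
                reads.append(("".join(frag), f"frag{i}"))
        for seq, rid in reads:
            hits, _ = align_reads([(rid, seq)], tiny_refset)
            got = sorted((h.ref_id, h.start, h.mismatches) for h in hits)
            assert got == brute_force_align(seq, tiny_refset), seq

    def test_multimapping_n_hits_equal_across_hits(self):
        # identical duplicated reference -> every read has 2 placements
        rs = refmodel.ReferenceSet()
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(np.array(list("ACGT")), size=60))
        rs.add_sequence(refmodel.ReferenceSequence("a", "rRNA", seq))
        rs.add_sequence(refmodel.ReferenceSequence("b", "rRNA", seq))
        hits, _ = align_reads([("r", seq[5:25])], rs)
        assert len(hits) == 2
        assert all(h.n_hits == 2 for h in hits)

    def test_sam_output_readable_by_pysam(self, tiny_refset, tmp_path):
        pysam = pytest.importorskip("pysam")
        seq = tiny_refset.sequences["tA"].sequence[:20]
        hits, _ = align_reads([("r1", seq)], tiny_refset)
        sam = tmp_path / "out.sam"
        smallmap.write_sam(hits, tiny_refset, sam, sequences={"r1": seq})
        with pysam.AlignmentFile(str(sam), "r") as fh:
            recs = list(fh)
        assert len(recs) == 1
        assert recs[0].reference_name == "tA"
        assert recs[0].reference_start == 0
        assert recs[0].query_sequence == seq


def oracle_counts(hits, features, min_overlap_frac=0.5):
    """Per-read assignment oracle, written independently of count_features."""
    out = {f.feature_id: 0.0 for f in features}
    for h in hits:
        read_len = h.end - h.start
        halves, others = [], []
        for f in features:
            if f.parent_ref_id != h.ref_id:
                continue
            ov = max(0, min(h.end, f.end) - max(h.start, f.start))
            (halves if f.kind in (FIVE_PRIME, THREE_PRIME) else others).append((f, ov))
        for f, ov in others:
            if ov / read_len >= min_overlap_frac:
                out[f.feature_id] += 1.0 / h.n_hits
        if halves:
            best_ov = max(ov for _, ov in halves)
            winners = [f for f, ov in halves if ov == best_ov]
            winner = next(
                (f for f in winners if f.kind == FIVE_PRIME), winners[0]
            )
            if best_ov / read_len >= min_overlap_frac:
                out[winner.feature_id] += 1.0 / h.n_hits
    return out


class TestCounting:
    def test_two_placements_split_half_and_half(self, tiny_refset):
        feats = tiny_refset.features_of_kind("full")
        hits = [
            AlignmentHit("r", "tA", 0, 20, 0, 2),
            AlignmentHit("r", "tB", 0, 20, 0, 2),
        ]
        counts = count_features(hits, feats)
        assert counts["tA"] == pytest.approx(0.5)
        assert counts["tB"] == pytest.approx(0.5)

    def test_unique_read_inside_five_prime_half(self, tiny_refset):
        feats = tiny_refset.features_of_kind(FIVE_PRIME, THREE_PRIME)
        counts = count_features([AlignmentHit("r", "tA", 0, 24, 0, 1)], feats)
        assert counts["tA.5p"] == pytest.approx(1.0)
        assert counts["tA.3p"] == 0.0

    def test_boundary_tie_goes_to_five_prime(self, tiny_refset):
        # tA halves split at 35; a read [25, 45) overlaps both by 10
        feats = tiny_refset.features_of_kind(FIVE_PRIME, THREE_PRIME)
        counts = count_features([AlignmentHit("r", "tA", 25, 45, 0, 1)], feats)
        assert counts["tA.5p"] == pytest.approx(1.0)
        assert counts["tA.3p"] == 0.0

    def test_conservation_and_oracle_on_random_hits(self, tiny_refset):
        rng = np.random.default_rng(23)
        feats = list(tiny_refset.features.values())
        half_feats = tiny_refset.features_of_kind(FIVE_PRIME, THREE_PRIME)
        refs = list(tiny_refset.sequences)
        hits = []
        for i in range(1000):
            ref = refs[rng.integers(len(refs))]
            L = len(tiny_refset.sequences[ref])
            rl = int(rng.integers(15, 31))
            start = int(rng.integers(0, L - rl + 1))
            hits.append(AlignmentHit(f"r{i}", ref, start, start + rl, 0, 1))
        counts = count_features(hits, half_feats)
        oracle = oracle_counts(hits, half_feats)
        for fid in oracle:
            assert counts[fid] == pytest.approx(oracle[fid])
        # conservation over full-length features: every read assigned once
        full = tiny_refset.features_of_kind("full")
        assert count_features(hits, full).sum() == pytest.approx(len(hits))

    def test_five_three_partition_of_trna_reads(self, tiny_refset):
        # halves partition: 5p + 3p count equals tRNA-assigned reads when
        # every read meets the overlap rule
        hits = [
            AlignmentHit(f"r{i}", "tA", s, s + 20, 0, 1)
            for i, s in enumerate([0, 5, 10, 40, 50, 52])
        ]
        feats = tiny_refset.features_of_kind(FIVE_PRIME, THREE_PRIME)
        counts = count_features(hits, feats)
        assert counts["tA.5p"] + counts["tA.3p"] == pytest.approx(len(hits))


class TestRpm:
    def _meta(self):
        return pd.Series({"f1": "tRNA", "f2": "rRNA", "f3": "miscRNA"})

    def test_basic_arithmetic(self):
        counts = pd.DataFrame({"s": [2.0, 2e6 - 2, 50.0]}, index=["f1", "f2", "f3"])
        rpm = rpm_normalize(counts, self._meta())
        assert rpm.loc["f1", "s"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s": [10.0, 90.0, 5.0]}, index=["f1", "f2", "f3"])
        r1 = rpm_normalize(counts, self._meta())
        r2 = rpm_normalize(counts * 3, self._meta())
        pd.testing.assert_frame_equal(r1, r2)

    def test_misc_rna_excluded_from_denominator(self):
        counts = pd.DataFrame({"s": [25.0, 75.0, 900.0]}, index=["f1", "f2", "f3"])
        rpm = rpm_normalize(counts, self._meta())
        assert rpm.loc["f1", "s"] == pytest.approx(25.0 / 100.0 * 1e6)

    def test_zero_denominator_errors(self):
        counts = pd.DataFrame({"s": [0.0, 0.0, 10.0]}, index=["f1", "f2", "f3"])
        with pytest.raises(ZeroDivisionError):
            rpm_normalize(counts, self._meta())


class TestCoverage:
    def test_three_stacked_reads(self):
        hits = [AlignmentHit(f"r{i}", "x", 0, 5, 0, 1) for i in range(3)]
        cov = compute_coverage(hits, "x", 8)
        assert cov.tolist() == [3, 3, 3, 3, 3, 0, 0, 0]

    def test_mass_identity_and_pileup_oracle(self, tiny_refset):
        rng = np.random.default_rng(5)
        refs = list(tiny_refset.sequences)
        hits = []
        for i in range(500):
            ref = refs[rng.integers(len(refs))]
            L = len(tiny_refset.sequences[ref])
            rl = int(rng.integers(15, 31))
            start = int(rng.integers(0, L - rl + 1))
            hits.append(AlignmentHit(f"r{i}", ref, start, start + rl, 0, int(rng.integers(1, 4))))
        for ref in refs:
            L = len(tiny_refset.sequences[ref])
            cov = compute_coverage(hits, ref, L)
            pile = np.zeros(L)
            for h in hits:  # naive per-base loop
                if h.ref_id == ref:
                    for pos in range(h.start, h.end):
                        pile[pos] += 1.0 / h.n_hits
            np.testing.assert_allclose(cov, pile)
        total_mass = sum(
            compute_coverage(hits, r, len(tiny_refset.sequences[r])).sum()
            for r in refs
        )
        expected = sum((h.end - h.start) / h.n_hits for h in hits)
        assert total_mass == pytest.approx(expected)

    def test_rpm_scaling(self):
        hits = [AlignmentHit("r", "x", 0, 4, 0, 1)]
        cov = compute_coverage(hits, "x", 4, normalize="rpm", category_total=2e6)
        assert cov.tolist() == [0.5, 0.5, 0.5, 0.5]


class TestLengthStats:
    def test_simple_median(self):
        dist = LengthDistribution(pd.Series({20: 1.0, 24: 1.0, 30: 1.0}))
        assert dist.median == 24

    def test_even_mass_tie_resolves_to_lower_length(self):
        dist = LengthDistribution(pd.Series({20: 1.0, 30: 1.0}))
        assert dist.median == 20

    def test_weighted_by_inverse_hits(self, tiny_refset):
        hits = [
            AlignmentHit("r1", "tA", 0, 20, 0, 2),
            AlignmentHit("r1", "tB", 0, 20, 0, 2),
            AlignmentHit("r2", "tA", 0, 30, 0, 1),
        ]
        dist = length_stats(hits, tiny_refset, "tRNA")
        assert dist.counts[20] == pytest.approx(1.0)
        assert dist.counts[30] == pytest.approx(1.0)
        assert dist.median == 20

    def test_empty_class_errors(self, tiny_refset):
        with pytest.raises(ValueError, match="no reads"):
            length_stats([], tiny_refset, "miRNA")

    def test_configured_median_recovered_from_simulation(self, refset):
        from tsrnapipe.preprocess import ReadRecord, preprocess_reads
        from tsrnapipe.simdata import LibrarySimConfig, simulate_library

        cfg = LibrarySimConfig(
            n_reads=6000, condition="control", seed=11,
            five_prime_length_model={"control": (24.0, 2.0), "treated": (29.0, 2.0)},
        )
        reads, _ = simulate_library(refset, cfg)
        records = [ReadRecord(r, s, "I" * len(s)) for r, s in reads]
        clean, _ = preprocess_reads(records, "sncrna", cfg.adapter3)
        hits, _ = align_reads([(r.read_id, r.sequence) for r in clean], refset)
        median = length_stats(hits, refset, "tRNA").median
        assert abs(median - 24) <= 1
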