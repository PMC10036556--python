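"""Ungapped alignment to the sncRNA reference, fractional feature counting,
RPM normalization, per-base coverage, and read-length distributions.

Alignment model: sense-strand, ungapped, full-read placements with at most
``max_mismatch`` mismatches (default 1); all placements at the minimum
observed mismatch count are reported (0 preferred over 1), and a read with
n such placements contributes 1/n to each ("fractional multimapping").  The
search uses a k-mer seed index with two non-overlapping seeds per read:
with at most one mismatch, at least one seed is exact (pigeonhole), so the
candidate set is complete for reads of length >= 2k.  ``N`` never matches
anything and counts as a mismatch.

Counting: a placement contributes to a feature when at least
``min_overlap_frac`` of the read lies inside it (default 50%); a read
spanning the 5'/3' half boundary of a tRNA goes to the half containing the
majority of its bases, ties to the 5' half.

RPM values are reads per million assigned to functional sncRNA categories
(miRNA/tRNA/snRNA/snoRNA/rRNA incl. mitochondrial), not per million raw
reads.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .refmodel import (
    FIVE_PRIME,
    FULL,
    FUNCTIONAL_CLASSES,
    THREE_PRIME,
    HalfFeature,
    ReferenceSet,
)

SEED_K = 7  # two seeds of 7 nt cover every >= 15 nt read under <= 1 mismatch


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    ref_id: str
    start: int
    end: int  # half-open; end - start == read length
    mismatches: int
    n_hits: int
    weight: float = 1.0  # multiplicity of identical reads collapsed upstream


class RefIndex:
    """Exact k-mer index over the reference sequences."""

    def __init__(self, refset: ReferenceSet, k: int = SEED_K):
        self.k = k
        self.seqs = {r: s.sequence for r, s in refset.sequences.items()}
        index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for ref_id, seq in self.seqs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    index[kmer].append((ref_id, i))
        self.index = dict(index)


def _count_mismatches(read: str, ref: str, start: int, limit: int) -> int:
    mism = 0
    segment = ref[start : start + len(read)]
    if segment == read:
        return 0
    for a, b in zip(read, segment):
        if a != b or a == "N":
            mism += 1
            if mism > limit:
                return mism
    return mism


def _align_sequence(
    seq: str, index: RefIndex, max_mismatch: int
) -> list[tuple[str, int, int]]:
    """All best-tier placements of one sequence: (ref_id, start, mismatches)."""
    k = index.k
    if len(seq) < 2 * k:
        raise ValueError(f"read of {len(seq)} nt shorter than {2 * k} nt minimum")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"read contains non-ACGTN characters {sorted(bad)}")
    candidates: set[tuple[str, int]] = set()
    for offset in (0, k):
        for ref_id, pos in index.index.get(seq[offset : offset + k], ()):
            start = pos - offset
            if start >= 0 and start + len(seq) <= len(index.seqs[ref_id]):
                candidates.add((ref_id, start))
    placements: list[tuple[str, int, int]] = []
    best = max_mismatch
    for ref_id, start in candidates:
        mism = _count_mismatches(seq, index.seqs[ref_id], start, best)
        if mism <= best:
            placements.append((ref_id, start, mism))
    if not placements:
        return []
    best = min(m for _, _, m in placements)
    return sorted(
        [(r, s, m) for r, s, m in placements if m == best]
    )


def align_reads(
    reads: Iterable[tuple[str, str]],
    refset: ReferenceSet,
    max_mismatch: int = 1,
    index: RefIndex | None = None,
) -> tuple[list[AlignmentHit], int]:
    """Align (read_id, sequence) pairs; returns (hits, n_unaligned).

    Placements are memoized per distinct sequence, which makes highly
    duplicated small-RNA libraries cheap to align.
    """
    if index is None:
        index = RefIndex(refset)
    cache: dict[str, list[tuple[str, int, int]]] = {}
    hits: list[AlignmentHit] = []
    n_unaligned = 0
    for read_id, seq in reads:
        placements = cache.get(seq)
        if placements is None:
            placements = _align_sequence(seq, index, max_mismatch)
            cache[seq] = placements
        if not placements:
            n_unaligned += 1
            continue
        n = len(placements)
        for ref_id, start, mism in placements:
            hits.append(
                AlignmentHit(read_id, ref_id, start, start + len(seq), mism, n)
            )
    return hits, n_unaligned


def write_sam(
    hits: Sequence[AlignmentHit],
    refset: ReferenceSet,
    path: str | Path,
    sequences: dict[str, str] | None = None,
) -> None:
    """Minimal SAM output (mapped records only, '*' sequence unless given)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref_id, seq in refset.sequences.items():
            fh.write(f"@SQ\tSN:{ref_id}\tLN:{len(seq)}\n")
        fh.write("@PG\tID:tsrnapipe\tPN:tsrnapipe\n")
        for h in hits:
            seq = sequences.get(h.read_id, "*") if sequences else "*"
            length = h.end - h.start
            fh.write(
                "\t".join(
                    [
                        h.read_id,
                        "0",
                        h.ref_id,
                        str(h.start + 1),
                        "255" if h.n_hits == 1 else "0",
                        f"{length}M",
                        "*",
                        "0",
                        "0",
                        seq,
                        "*",
                        f"NM:i:{h.mismatches}",
                        f"NH:i:{h.n_hits}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Counting


def count_features(
    hits: Iterable[AlignmentHit],
    features: Sequence[HalfFeature],
    min_overlap_frac: float = 0.5,
    boundary_tie: str = FIVE_PRIME,
) -> pd.Series:
    """Fractional feature counts for one sample.

    Each placement contributes ``weight / n_hits`` to every feature it
    overlaps by at least ``min_overlap_frac`` of the read length, except
    that the 5'/3' half pair of one tRNA is mutually exclusive: the half
    with the larger overlap wins (ties to ``boundary_tie``).
    """
    by_parent: dict[str, list[HalfFeature]] = defaultdict(list)
    for f in features:
        by_parent[f.parent_ref_id].append(f)
    counts: dict[str, float] = {f.feature_id: 0.0 for f in features}
    known_refs = set(by_parent)
    for h in hits:
        # hits on references without features in this set (e.g. rRNA hits
        # against a halves-only feature set) are simply not counted
        if h.ref_id not in known_refs:
            continue
        read_len = h.end - h.start
        frac = h.weight / h.n_hits
        feats = by_parent[h.ref_id]
        halves = [f for f in feats if f.kind in (FIVE_PRIME, THREE_PRIME)]
        others = [f for f in feats if f.kind not in (FIVE_PRIME, THREE_PRIME)]
        for f in others:
            ov = min(h.end, f.end) - max(h.start, f.start)
            if ov / read_len >= min_overlap_frac:
                counts[f.feature_id] += frac
        if halves:
            best = None
            best_ov = -1
            for f in halves:
                ov = min(h.end, f.end) - max(h.start, f.start)
                if ov > best_ov or (ov == best_ov and f.kind == boundary_tie):
                    best, best_ov = f, ov
            if best is not None and best_ov / read_len >= min_overlap_frac:
                counts[best.feature_id] += frac
    return pd.Series(counts, name="count")


def validate_hits(hits: Iterable[AlignmentHit], refset: ReferenceSet) -> None:
    for h in hits:
        if h.ref_id not in refset.sequences:
            raise KeyError(f"hit references unknown ref_id {h.ref_id!r}")


def build_count_table(per_sample: dict[str, pd.Series]) -> pd.DataFrame:
    """Assemble per-sample count Series into a feature x sample table."""
    table = pd.DataFrame(per_sample).fillna(0.0)
    table.index.name = "feature_id"
    return table


def rpm_normalize(
    counts: pd.DataFrame | pd.Series,
    feature_class: pd.Series,
    functional_classes: frozenset = FUNCTIONAL_CLASSES,
) -> pd.DataFrame | pd.Series:
    """Reads-per-million over the functional sncRNA categories.

    ``feature_class`` maps feature_id -> rna_class; the per-sample
    denominator is the total count assigned to features of the functional
    classes.  RPM_fs = counts_fs / category_total_s * 1e6.
    """
    df = counts.to_frame() if isinstance(counts, pd.Series) else counts
    functional = df.index.map(
        lambda f: feature_class.get(f) in functional_classes
    ).values.astype(bool)
    denom = df.loc[functional].sum(axis=0)
    if (denom <= 0).any():
        bad = denom.index[denom <= 0].tolist()
        raise ZeroDivisionError(
            f"no reads assigned to functional categories in samples {bad}"
        )
    rpm = df.div(denom, axis=1) * 1e6
    return rpm.iloc[:, 0] if isinstance(counts, pd.Series) else rpm


# ---------------------------------------------------------------------------
# Coverage and length distributions


def compute_coverage(
    hits: Iterable[AlignmentHit],
    ref_id: str,
    ref_length: int,
    normalize: str = "raw",
    category_total: float | None = None,
) -> np.ndarray:
    """Per-base fractional coverage of one reference (bin size 1).

    Each placement adds weight/n_hits over its span.  ``normalize='rpm'``
    scales by 1e6 / category_total.
    """
    if ref_length <= 0:
        raise KeyError(f"unknown ref_id {ref_id!r} (non-positive length)")
    cov = np.zeros(ref_length, dtype=float)
    for h in hits:
        if h.ref_id != ref_id:
            continue
        cov[h.start : h.end] += h.weight / h.n_hits
    if normalize == "rpm":
        if not category_total or category_total <= 0:
            raise ZeroDivisionError("rpm normalization needs category_total > 0")
        cov *= 1e6 / category_total
    elif normalize != "raw":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    return cov


def write_bedgraph(cov: np.ndarray, ref_id: str, path: str | Path) -> None:
    """bedGraph (0-based half-open), merging runs of equal value."""
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(cov) + 1):
            if i == len(cov) or cov[i] != cov[start]:
                if cov[start] != 0:
                    fh.write(f"{ref_id}\t{start}\t{i}\t{cov[start]:.6g}\n")
                start = i


@dataclass
class LengthDistribution:
    """Fractional read counts per length with a weighted median."""

    counts: pd.Series  # index: length (nt), values: fractional counts

    @property
    def median(self) -> int:
        """Weighted median: the lowest length whose cumulative fractional
        mass reaches half of the total (even-mass ties resolve downward)."""
        c = self.counts.sort_index()
        total = c.sum()
        if total <= 0:
            raise ValueError("empty length distribution")
        cum = c.cumsum()
        return int(c.index[np.searchsorted(cum.values, total / 2.0)])


def length_stats(
    hits: Iterable[AlignmentHit],
    refset: ReferenceSet,
    rna_class: str | tuple[str, ...],
) -> LengthDistribution:
    """Length distribution of reads mapped to references of a class.

    Each placement contributes weight/n_hits at the read's length, so a
    read multimapping within the class still counts once in total.
    """
    classes = (rna_class,) if isinstance(rna_class, str) else tuple(rna_class)
    acc: dict[int, float] = defaultdict(float)
    for h in hits:
        if refset.class_of(h.ref_id) in classes:
            acc[h.end - h.start] += h.weight / h.n_hits
    if not acc:
        raise ValueError(f"no reads mapped to class {classes}")
    return LengthDistribution(pd.Series(acc).sort_index())
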