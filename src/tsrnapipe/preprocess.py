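"""Raw-read trimming and filtering for sperm small RNA-seq libraries.

Library structure: each sequenced read is

    [4 random nt] [biological insert] [6 random nt] [3' sequencing adapter...]

The random nucleotides flank the insert as ligation spacers and are
discarded, not used for deduplication.  Two filter chains are provided:

* ``sncrna`` mode (class-level counting): 3' adapter removal (discard when
  the adapter cannot be identified, or when the remainder is < 15 nt), then
  removal of the 4 + 6 random nucleotides, then discard of reads < 19 nt.
* ``halves`` mode (5'/3' tRNA-half counting): the sncrna steps, then an
  additional 3 nt removed from the 3' end of every read, then discard of
  reads < 15 nt.

Every input read is accounted for exactly once in the :class:`TrimReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

MIN_LEN_AFTER_ADAPTER = 15
MIN_LEN_SNCRNA = 19
MIN_LEN_HALVES = 15
EXTRA_3P_TRIM = 3


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class TrimReport:
    """Per-stage read accounting; reads_in == reads_out + all discards."""

    reads_in: int = 0
    discarded_no_adapter: int = 0
    discarded_short_after_adapter: int = 0
    discarded_short_after_random_nt: int = 0
    discarded_length_filter: int = 0
    reads_out: int = 0
    params: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        return self.reads_in == (
            self.reads_out
            + self.discarded_no_adapter
            + self.discarded_short_after_adapter
            + self.discarded_short_after_random_nt
            + self.discarded_length_filter
        )

    def to_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "discarded_no_adapter": self.discarded_no_adapter,
            "discarded_short_after_adapter": self.discarded_short_after_adapter,
            "discarded_short_after_random_nt": self.discarded_short_after_random_nt,
            "discarded_length_filter": self.discarded_length_filter,
            "reads_out": self.reads_out,
            "params": self.params,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def write_tsv(self, path: str | Path) -> None:
        d = self.to_dict()
        d.pop("params")
        with open(path, "w") as fh:
            fh.write("counter\tvalue\n")
            for k, v in d.items():
                fh.write(f"{k}\t{v}\n")


def find_adapter(sequence: str, adapter3: str, min_overlap: int = 5,
                 max_error_rate: float = 0.1) -> int | None:
    """Return the start index of the 3' adapter in ``sequence``, or None.

    Semantics of 3'-adapter trimming: at candidate position i the adapter
    prefix of length min(len(adapter3), len(sequence) - i) must match the
    read through its end with at most ``max_error_rate`` mismatches over the
    matched span, and the span must be >= ``min_overlap`` (a full internal
    adapter occurrence always qualifies).  The leftmost acceptable position
    wins; positions admitting a full-length adapter match are scanned first
    by construction since they lie leftmost.
    """
    if len(adapter3) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    n, la = len(sequence), len(adapter3)
    # fast path: exact full adapter occurrence
    pos = sequence.find(adapter3)
    if pos != -1:
        return pos
    for i in range(n):
        span = min(la, n - i)
        if span < min_overlap:
            break
        allowed = int(max_error_rate * span)
        mism = 0
        for a, b in zip(sequence[i : i + span], adapter3[:span]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return i
    return None


def trim_adapter(read: ReadRecord, adapter3: str, min_overlap: int = 5,
                 max_error_rate: float = 0.1,
                 min_len: int = MIN_LEN_AFTER_ADAPTER) -> tuple[ReadRecord | None, str]:
    """Trim the 3' adapter; return (read, "ok") or (None, discard reason)."""
    if len(read.sequence) == 0:
        return None, "no_adapter"
    pos = find_adapter(read.sequence, adapter3, min_overlap, max_error_rate)
    if pos is None:
        return None, "no_adapter"
    if pos < min_len:
        return None, "short_after_adapter"
    return ReadRecord(read.read_id, read.sequence[:pos], read.quality[:pos]), "ok"


def trim_random_nt(read: ReadRecord, n5: int = 4, n3: int = 6) -> ReadRecord | None:
    """Remove the n5 leading and n3 trailing random nucleotides.

    Returns None (discard) when nothing would remain.
    """
    if len(read.sequence) <= n5 + n3:
        return None
    end = len(read.sequence) - n3
    return ReadRecord(read.read_id, read.sequence[n5:end], read.quality[n5:end])


def _iter_fastq(path: str | Path) -> Iterator[ReadRecord]:
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield ReadRecord(title.split()[0], seq.upper(), qual)


def preprocess_reads(
    reads: Iterable[ReadRecord],
    mode: str,
    adapter3: str,
    n_random5: int = 4,
    n_random3: int = 6,
    min_overlap: int = 5,
    max_error_rate: float = 0.1,
    min_len_sncrna: int = MIN_LEN_SNCRNA,
    min_len_halves: int = MIN_LEN_HALVES,
    extra_3p_trim: int = EXTRA_3P_TRIM,
) -> tuple[list[ReadRecord], TrimReport]:
    """Run the full trimming chain for one mode over an iterable of reads."""
    if mode not in ("sncrna", "halves"):
        raise ValueError(f"unknown mode {mode!r}")
    report = TrimReport(
        params={
            "mode": mode,
            "adapter3": adapter3,
            "n_random5": n_random5,
            "n_random3": n_random3,
            "min_overlap": min_overlap,
            "max_error_rate": max_error_rate,
            "min_len_sncrna": min_len_sncrna,
            "min_len_halves": min_len_halves,
            "extra_3p_trim": extra_3p_trim,
        }
    )
    out: list[ReadRecord] = []
    for read in reads:
        report.reads_in += 1
        trimmed, status = trim_adapter(
            read, adapter3, min_overlap, max_error_rate
        )
        if trimmed is None:
            if status == "no_adapter":
                report.discarded_no_adapter += 1
            else:
                report.discarded_short_after_adapter += 1
            continue
        trimmed = trim_random_nt(trimmed, n_random5, n_random3)
        if trimmed is None:
            report.discarded_short_after_random_nt += 1
            continue
        if mode == "sncrna":
            if len(trimmed.sequence) < min_len_sncrna:
                report.discarded_length_filter += 1
                continue
        else:  # halves: sncrna steps minus its floor, then -3 nt, then >=15
            keep = len(trimmed.sequence) - extra_3p_trim
            if keep < min_len_halves:
                report.discarded_length_filter += 1
                continue
            trimmed = ReadRecord(
                trimmed.read_id, trimmed.sequence[:keep], trimmed.quality[:keep]
            )
        report.reads_out += 1
        out.append(trimmed)
    assert report.reconciles()
    return out, report


def run_preprocess(
    fastq_in: str | Path,
    fastq_out: str | Path,
    mode: str,
    adapter3: str,
    **params,
) -> TrimReport:
    """File-to-file variant of :func:`preprocess_reads`."""
    try:
        reads = list(_iter_fastq(fastq_in))
    except ValueError as exc:
        raise ValueError(f"unreadable FASTQ {fastq_in}: {exc}") from exc
    out, report = preprocess_reads(reads, mode, adapter3, **params)
    write_fastq(out, fastq_out)
    return report


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    return list(_iter_fastq(path))
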