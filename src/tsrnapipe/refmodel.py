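"""Reference model for a transcript-level small non-coding RNA reference.

The analysis aligns sequenced fragments against a custom set of mature
sncRNA sequences (rRNAs, tRNAs, miRNAs, snRNAs, snoRNAs, ...), not a whole
genome.  Each tRNA is additionally annotated with its isoacceptor identity
(amino acid + anticodon, e.g. ``Asp-GUC``) and, when known, the 0-based
position of the first anticodon nucleotide.  From these annotations the
module derives 5'/3' tRNA-half interval features: the canonical
stress-induced cleavage falls in the anticodon loop, so by default a tRNA
of length L with anticodon starting at position a is split after the middle
anticodon nucleotide, i.e. at s = a + 2, giving a 5' half [0, s) and a
3' half [s, L).  When the anticodon position is unknown the split falls at
floor(L / 2).

Coordinate conventions
----------------------
Internally every interval is 0-based half-open.  The GTF writer/reader uses
1-based inclusive coordinates; the BED writer/reader uses 0-based half-open
coordinates.  Both round-trip exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_CLASSES = frozenset(
    {"tRNA", "rRNA", "mt_rRNA", "miRNA", "snRNA", "snoRNA", "miscRNA"}
)

#: classes whose assigned reads define the RPM denominator ("functional"
#: sncRNA categories); miscellaneous RNA is excluded.
FUNCTIONAL_CLASSES = frozenset(
    {"tRNA", "rRNA", "mt_rRNA", "miRNA", "snRNA", "snoRNA"}
)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
FULL = "full"

_VALID_KINDS = (FIVE_PRIME, THREE_PRIME, FULL)


class ReferenceError(ValueError):
    """Raised for malformed or inconsistent reference inputs."""


@dataclass(frozen=True)
class ReferenceSequence:
    ref_id: str
    rna_class: str
    sequence: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ReferenceError(
                f"{self.ref_id}: unknown rna_class {self.rna_class!r}"
            )
        if len(self.sequence) < 1:
            raise ReferenceError(f"{self.ref_id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ReferenceError(
                f"{self.ref_id}: invalid characters {sorted(bad)} "
                "(sequences must be normalized to uppercase A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TRNAAnnotation:
    """Isoacceptor identity of one tRNA reference entry.

    ``anticodon_start`` is the 0-based index of the first anticodon
    nucleotide on the mature sequence, or ``None`` when unknown.
    """

    ref_id: str
    isoacceptor: str
    length: int
    anticodon_start: int | None = None

    def __post_init__(self) -> None:
        if self.anticodon_start is not None:
            if not (0 <= self.anticodon_start and self.anticodon_start + 3 <= self.length):
                raise ReferenceError(
                    f"{self.ref_id}: anticodon [{self.anticodon_start}, "
                    f"{self.anticodon_start + 3}) outside sequence of length {self.length}"
                )


@dataclass(frozen=True)
class HalfFeature:
    """A counting interval on a reference sequence (0-based half-open)."""

    feature_id: str
    parent_ref_id: str
    kind: str  # five_prime | three_prime | full
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ReferenceError(f"{self.feature_id}: bad kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ReferenceError(
                f"{self.feature_id}: bad interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceSet:
    """Sequences + tRNA annotations + interval features, kept consistent."""

    sequences: dict[str, ReferenceSequence] = field(default_factory=dict)
    trna_annotations: dict[str, TRNAAnnotation] = field(default_factory=dict)
    features: dict[str, HalfFeature] = field(default_factory=dict)

    def add_sequence(self, seq: ReferenceSequence) -> None:
        if seq.ref_id in self.sequences:
            raise ReferenceError(f"duplicate ref_id {seq.ref_id!r}")
        self.sequences[seq.ref_id] = seq

    def add_annotation(self, ann: TRNAAnnotation) -> None:
        seq = self.sequences.get(ann.ref_id)
        if seq is None:
            raise ReferenceError(f"annotation for unknown ref_id {ann.ref_id!r}")
        if seq.rna_class != "tRNA":
            raise ReferenceError(f"{ann.ref_id}: tRNA annotation on {seq.rna_class}")
        if ann.length != len(seq):
            raise ReferenceError(
                f"{ann.ref_id}: annotation length {ann.length} != sequence {len(seq)}"
            )
        self.trna_annotations[ann.ref_id] = ann

    def add_feature(self, feat: HalfFeature) -> None:
        seq = self.sequences.get(feat.parent_ref_id)
        if seq is None:
            raise ReferenceError(
                f"feature {feat.feature_id!r} references unknown "
                f"ref_id {feat.parent_ref_id!r}"
            )
        if feat.end > len(seq):
            raise ReferenceError(
                f"{feat.feature_id}: end {feat.end} beyond sequence length {len(seq)}"
            )
        if feat.feature_id in self.features:
            raise ReferenceError(f"duplicate feature_id {feat.feature_id!r}")
        self.features[feat.feature_id] = feat

    def class_of(self, ref_id: str) -> str:
        return self.sequences[ref_id].rna_class

    def features_of_kind(self, *kinds: str) -> list[HalfFeature]:
        return [f for f in self.features.values() if f.kind in kinds]

    def half_pairs(self) -> dict[str, tuple[HalfFeature, HalfFeature]]:
        """Map parent ref_id -> (5' half, 3' half) for tRNAs with both."""
        fives = {f.parent_ref_id: f for f in self.features.values() if f.kind == FIVE_PRIME}
        threes = {f.parent_ref_id: f for f in self.features.values() if f.kind == THREE_PRIME}
        return {r: (fives[r], threes[r]) for r in fives if r in threes}


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert U -> T (RNA input stored as DNA alphabet)."""
    return raw.upper().replace("U", "T")


def load_reference(fasta_path: str | Path, class_table_path: str | Path) -> ReferenceSet:
    """Load a reference FASTA plus its class table into a ReferenceSet.

    The class table is a TSV with header columns ``ref_id``, ``rna_class``
    and, for tRNAs, ``isoacceptor`` and optionally ``anticodon_start``.
    Every FASTA entry must be classed and every classed id must exist in
    the FASTA; anything else is a hard error (no silent default class).
    """
    table: dict[str, dict[str, str]] = {}
    with open(class_table_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"ref_id", "rna_class"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ReferenceError(
                f"{class_table_path}: class table needs columns {sorted(required)}"
            )
        for row in reader:
            table[row["ref_id"]] = row

    refset = ReferenceSet()
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = table.get(rec.id)
        if row is None:
            raise ReferenceError(
                f"FASTA id {rec.id!r} missing from class table {class_table_path}"
            )
        seen.add(rec.id)
        seq = ReferenceSequence(
            ref_id=rec.id,
            rna_class=row["rna_class"],
            sequence=normalize_sequence(str(rec.seq)),
        )
        refset.add_sequence(seq)
        if seq.rna_class == "tRNA":
            iso = (row.get("isoacceptor") or "").strip()
            if not iso:
                raise ReferenceError(f"{rec.id}: tRNA without isoacceptor in class table")
            ac_raw = (row.get("anticodon_start") or "").strip()
            ac = int(ac_raw) if ac_raw else None
            refset.add_annotation(
                TRNAAnnotation(
                    ref_id=rec.id,
                    isoacceptor=iso,
                    length=len(seq),
                    anticodon_start=ac,
                )
            )
    unknown = set(table) - seen
    if unknown:
        raise ReferenceError(
            f"class table ids not present in FASTA: {sorted(unknown)}"
        )
    return refset


def write_reference_fasta(refset: ReferenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.ref_id, description="")
        for s in refset.sequences.values()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_class_table(refset: ReferenceSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["ref_id", "rna_class", "isoacceptor", "anticodon_start"])
        for s in refset.sequences.values():
            ann = refset.trna_annotations.get(s.ref_id)
            w.writerow(
                [
                    s.ref_id,
                    s.rna_class,
                    ann.isoacceptor if ann else "",
                    "" if ann is None or ann.anticodon_start is None else ann.anticodon_start,
                ]
            )


def build_half_annotations(
    refset: ReferenceSet, split_rule: str = "anticodon_mid"
) -> ReferenceSet:
    """Add one 5' and one 3' half feature for every annotated tRNA.

    ``anticodon_mid`` (default): split point s = anticodon_start + 2, so the
    5' half runs through the middle anticodon nucleotide; when the anticodon
    position is absent, s = floor(length / 2).  ``midpoint``: always
    s = floor(length / 2).  The two halves always partition [0, length).
    """
    if split_rule not in ("anticodon_mid", "midpoint"):
        raise ReferenceError(f"unknown split_rule {split_rule!r}")
    for ref_id, seq in refset.sequences.items():
        if seq.rna_class != "tRNA":
            continue
        ann = refset.trna_annotations.get(ref_id)
        if ann is None:
            raise ReferenceError(f"{ref_id}: tRNA lacks a TRNAAnnotation")
        length = len(seq)
        if length < 6:
            raise ReferenceError(f"{ref_id}: tRNA of {length} nt too short to split")
        if split_rule == "anticodon_mid" and ann.anticodon_start is not None:
            s = ann.anticodon_start + 2
        else:
            s = length // 2
        s = max(1, min(s, length - 1))  # both halves non-empty
        refset.add_feature(
            HalfFeature(f"{ref_id}.5p", ref_id, FIVE_PRIME, 0, s)
        )
        refset.add_feature(
            HalfFeature(f"{ref_id}.3p", ref_id, THREE_PRIME, s, length)
        )
    return refset


def build_full_length_features(refset: ReferenceSet) -> ReferenceSet:
    """Add a full-span feature per reference (class-level counting)."""
    for ref_id, seq in refset.sequences.items():
        refset.add_feature(HalfFeature(ref_id, ref_id, FULL, 0, len(seq)))
    return refset


# ---------------------------------------------------------------------------
# GTF / BED round-trip (custom transcript-coordinate dialects)

def write_features_gtf(features: Iterable[HalfFeature], path: str | Path) -> None:
    """Write features as GTF: 1-based inclusive coordinates, strand '+'."""
    feats = list(features)
    ids = [f.feature_id for f in feats]
    if len(ids) != len(set(ids)):
        raise ReferenceError("duplicate feature_ids in GTF export")
    with open(path, "w") as fh:
        for f in feats:
            attrs = (
                f'feature_id "{f.feature_id}"; parent "{f.parent_ref_id}"; '
                f'kind "{f.kind}";'
            )
            fh.write(
                "\t".join(
                    [
                        f.parent_ref_id,
                        "tsrnapipe",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_features_gtf(path: str | Path) -> list[HalfFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ReferenceError(
                    f"{path}:{lineno}: expected 9 tab-separated GTF columns, "
                    f"got {len(cols)}"
                )
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ReferenceError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = _parse_gtf_attributes(cols[8], path, lineno)
            feats.append(
                HalfFeature(
                    feature_id=attrs["feature_id"],
                    parent_ref_id=attrs.get("parent", cols[0]),
                    kind=attrs.get("kind", cols[2]),
                    start=start1 - 1,
                    end=end1,
                )
            )
    return feats


def _parse_gtf_attributes(text: str, path, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError as exc:
            raise ReferenceError(f"{path}:{lineno}: bad attribute {chunk!r}") from exc
        attrs[key] = value.strip().strip('"')
    if "feature_id" not in attrs:
        raise ReferenceError(f"{path}:{lineno}: attributes lack feature_id")
    return attrs


def write_features_bed(features: Iterable[HalfFeature], path: str | Path) -> None:
    """BED dialect: 0-based half-open; name = feature_id; column 7 = kind."""
    feats = list(features)
    ids = [f.feature_id for f in feats]
    if len(ids) != len(set(ids)):
        raise ReferenceError("duplicate feature_ids in BED export")
    with open(path, "w") as fh:
        for f in feats:
            fh.write(
                "\t".join(
                    [f.parent_ref_id, str(f.start), str(f.end), f.feature_id, "0", "+", f.kind]
                )
                + "\n"
            )


def read_features_bed(path: str | Path) -> list[HalfFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise ReferenceError(
                    f"{path}:{lineno}: expected >= 7 BED columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ReferenceError(f"{path}:{lineno}: bad coordinates") from exc
            feats.append(
                HalfFeature(
                    feature_id=cols[3],
                    parent_ref_id=cols[0],
                    kind=cols[6],
                    start=start,
                    end=end,
                )
            )
    return feats
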