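"""Synthetic data generator for the full analysis pipeline.

Emulates the statistical structure of a sperm small RNA-seq library from a
paternal methotrexate (MTX) exposure experiment, plus the morphometric and
categorical phenotype readouts of the offspring:

* libraries dominated by rRNA- and tRNA-derived fragments;
* condition-dependent enrichment of specific 5' tRNA halves (by default
  Asp-GUC, Glu-CUC, Lys-CUU, Gly-GCC) with no matching 3'-half increase;
* a shift of the tRNA-fragment length distribution between conditions
  (control fragments centred at 24 nt, treated at 29 nt);
* the raw read structure implied by the library protocol: 4 random
  nucleotides 5' of the insert, 6 random nucleotides 3' of it, then the 3'
  sequencing adapter.

All randomness flows through one ``numpy`` generator seeded from the
config, so identical (config, seed) pairs produce byte-identical FASTQ.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refmodel import (
    FIVE_PRIME,
    THREE_PRIME,
    ReferenceSet,
    ReferenceSequence,
    TRNAAnnotation,
    ReferenceSet as _RefSet,
    build_half_annotations,
)

_BASES = np.array(list("ACGT"))

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"  # standard small-RNA 3' adapter

DEFAULT_CLASS_WEIGHTS = {
    "rRNA": 0.39,
    "mt_rRNA": 0.06,
    "tRNA": 0.37,
    "miRNA": 0.08,
    "snRNA": 0.04,
    "snoRNA": 0.03,
    "miscRNA": 0.03,
}

DEFAULT_ISOACCEPTORS = [
    "Asp-GUC", "Glu-CUC", "Glu-UUC", "Lys-CUU", "Gly-GCC",
    "Gly-UCC", "Pro-UGG", "Arg-UCU", "Ser-GCU", "His-GUG",
]

#: relative abundance of the 3' half per isoacceptor (5' half weight is 1);
#: Glu-CUC / Glu-UUC / Gly-UCC 3' halves are nearly absent, Ser-GCU is
#: 3'-dominant, matching the qualitative half balance seen in sperm.
DEFAULT_THREE_PRIME_WEIGHT = {
    "Asp-GUC": 0.25, "Glu-CUC": 0.02, "Glu-UUC": 0.02, "Lys-CUU": 0.25,
    "Gly-GCC": 0.25, "Gly-UCC": 0.02, "Pro-UGG": 0.25, "Arg-UCU": 0.25,
    "Ser-GCU": 1.5, "His-GUG": 0.25,
}

#: fold change applied to the 5' half in the treated condition
DEFAULT_CONDITION_EFFECTS = {
    "Asp-GUC": 4.0, "Glu-CUC": 3.0, "Lys-CUU": 2.5, "Gly-GCC": 2.0,
}


@dataclass
class LibrarySimConfig:
    """Parameters of one simulated small RNA-seq library.

    ``five_prime_length_model`` maps condition -> (mean, sd) of the 5'
    tRNA-half fragment length, measured from the tRNA 5' end; the defaults
    (24 +/- 2 control, 29 +/- 2 treated) reproduce the observed 24 -> 29 nt
    median shift of tRNA-mapped reads.  3' halves are anchored at the tRNA
    3' end and keep the control length model in both conditions, so the
    treatment affects 5' halves only.
    """

    n_reads: int = 50_000
    condition: str = "control"  # control | treated
    class_weights: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    isoacceptor_abundance: dict = field(
        default_factory=lambda: {iso: 1.0 for iso in DEFAULT_ISOACCEPTORS}
    )
    condition_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_EFFECTS)
    )
    three_prime_weight: dict = field(
        default_factory=lambda: dict(DEFAULT_THREE_PRIME_WEIGHT)
    )
    five_prime_length_model: dict = field(
        default_factory=lambda: {"control": (24.0, 2.0), "treated": (29.0, 2.0)}
    )
    other_length_model: tuple = (22.0, 3.0)  # rRNA/snRNA/snoRNA/misc windows
    rrna_length_model: dict = field(
        default_factory=lambda: {"control": (22.0, 3.0), "treated": (24.0, 3.0)}
    )
    min_insert: int = 15
    max_insert: int = 35
    seq_error_rate: float = 0.001
    read_length: int = 50
    adapter3: str = DEFAULT_ADAPTER3
    n_random5: int = 4
    n_random3: int = 6
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_weights sum to {total}, expected 1")
        if any(w < 0 for w in self.class_weights.values()):
            raise ValueError("negative class weight")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if any(f <= 0 for f in self.condition_effects.values()):
            raise ValueError("condition fold changes must be > 0")
        if self.condition not in ("control", "treated"):
            raise ValueError(f"unknown condition {self.condition!r}")


def example_reference(seed: int = 2023) -> ReferenceSet:
    """Build a synthetic transcript-level sncRNA reference.

    Sequences are random (seeded) stand-ins with realistic lengths: six
    rRNA species (cytoplasmic 28S/18S/5.8S/5S surrogates at desk scale plus
    mitochondrial 16S/12S), ten tRNA isoacceptors of 72-76 nt with the
    anticodon starting at position 33, five 22-nt miRNAs, three snRNAs, two
    snoRNAs and two miscellaneous RNAs.
    """
    rng = np.random.default_rng(seed)

    def rand_seq(length: int) -> str:
        return "".join(rng.choice(_BASES, size=length))

    refset = _RefSet()
    rrnas = [
        ("rRNA_28S", "rRNA", 600), ("rRNA_18S", "rRNA", 450),
        ("rRNA_5.8S", "rRNA", 153), ("rRNA_5S", "rRNA", 119),
        ("mt_rRNA_16S", "mt_rRNA", 300), ("mt_rRNA_12S", "mt_rRNA", 250),
    ]
    for ref_id, cls, length in rrnas:
        refset.add_sequence(ReferenceSequence(ref_id, cls, rand_seq(length)))
    for i, iso in enumerate(DEFAULT_ISOACCEPTORS):
        length = 72 + (i % 3) * 2  # 72/74/76 nt
        ref_id = f"tRNA-{iso}"
        refset.add_sequence(ReferenceSequence(ref_id, "tRNA", rand_seq(length)))
        refset.add_annotation(
            TRNAAnnotation(ref_id, iso, length, anticodon_start=33)
        )
    for i in range(5):
        refset.add_sequence(ReferenceSequence(f"miR-{i + 1}", "miRNA", rand_seq(22)))
    for ref_id, length in [("snRNA_U1", 164), ("snRNA_U2", 191), ("snRNA_U6", 107)]:
        refset.add_sequence(ReferenceSequence(ref_id, "snRNA", rand_seq(length)))
    for i, length in enumerate([134, 127]):
        refset.add_sequence(ReferenceSequence(f"snoRNA_{i + 1}", "snoRNA", rand_seq(length)))
    for i, length in enumerate([210, 180]):
        refset.add_sequence(ReferenceSequence(f"miscRNA_{i + 1}", "miscRNA", rand_seq(length)))
    return refset


@dataclass(frozen=True)
class _Species:
    """One fragment-generating unit with a sampling weight."""

    feature_id: str
    ref_id: str
    rna_class: str
    kind: str  # five_prime | three_prime | full
    isoacceptor: str | None
    weight: float


def _species_table(refset: ReferenceSet, config: LibrarySimConfig) -> list[_Species]:
    config.validate()
    by_class: dict[str, list[str]] = {}
    for s in refset.sequences.values():
        by_class.setdefault(s.rna_class, []).append(s.ref_id)
    species: list[_Species] = []
    treated = config.condition == "treated"
    for cls, cw in config.class_weights.items():
        refs = by_class.get(cls, [])
        if not refs or cw == 0:
            continue
        if cls == "tRNA":
            iso_of = {r: refset.trna_annotations[r].isoacceptor for r in refs}
            iso_w = {
                r: config.isoacceptor_abundance.get(iso_of[r], 0.0) for r in refs
            }
            tot = sum(
                iso_w[r] * (1.0 + config.three_prime_weight.get(iso_of[r], 0.25))
                for r in refs
            )
            for r in refs:
                iso = iso_of[r]
                w5 = iso_w[r]
                w3 = iso_w[r] * config.three_prime_weight.get(iso, 0.25)
                if treated:
                    w5 *= config.condition_effects.get(iso, 1.0)
                species.append(_Species(f"{r}.5p", r, cls, FIVE_PRIME, iso, cw * w5 / tot))
                species.append(_Species(f"{r}.3p", r, cls, THREE_PRIME, iso, cw * w3 / tot))
        else:
            for r in refs:
                species.append(_Species(r, r, cls, "full", None, cw / len(refs)))
    return species


def ground_truth(refset: ReferenceSet, config: LibrarySimConfig) -> pd.DataFrame:
    """Expected fractional abundances and true per-feature log2 fold changes.

    ``true_log2fc`` is the fold change after compositional normalization,
    i.e. log2 of the applied 5'-half condition effect (0 for every other
    feature), which is what a median-of-ratios normalized DE analysis
    estimates.
    """
    ctrl = dataclasses.replace(config, condition="control")
    trt = dataclasses.replace(config, condition="treated")
    rows = {}
    for cond, cfg in (("control", ctrl), ("treated", trt)):
        sp = _species_table(refset, cfg)
        tot = sum(s.weight for s in sp)
        for s in sp:
            rec = rows.setdefault(
                s.feature_id,
                {
                    "feature_id": s.feature_id,
                    "ref_id": s.ref_id,
                    "rna_class": s.rna_class,
                    "kind": s.kind,
                    "isoacceptor": s.isoacceptor,
                },
            )
            rec[f"abundance_{cond}"] = s.weight / tot
    df = pd.DataFrame(rows.values()).set_index("feature_id")
    effect = np.zeros(len(df))
    for i, (fid, row) in enumerate(df.iterrows()):
        if row["kind"] == FIVE_PRIME and row["isoacceptor"] in config.condition_effects:
            effect[i] = np.log2(config.condition_effects[row["isoacceptor"]])
    df["true_log2fc"] = effect
    # per-isoacceptor true 5' percentage per condition
    return df


def true_five_prime_percent(refset: ReferenceSet, config: LibrarySimConfig) -> pd.DataFrame:
    gt = ground_truth(refset, config)
    halves = gt[gt["kind"].isin([FIVE_PRIME, THREE_PRIME])]
    out = []
    for iso, grp in halves.groupby("isoacceptor"):
        rec = {"isoacceptor": iso}
        for cond in ("control", "treated"):
            a = grp.set_index("kind")[f"abundance_{cond}"]
            rec[f"percent5_{cond}"] = 100.0 * a[FIVE_PRIME] / (a[FIVE_PRIME] + a[THREE_PRIME])
        out.append(rec)
    return pd.DataFrame(out).set_index("isoacceptor")


def simulate_library(
    refset: ReferenceSet,
    config: LibrarySimConfig,
    fastq_path: str | Path | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate one library; returns (reads, ground truth table).

    ``reads`` is a list of (read_id, sequence); when ``fastq_path`` is given
    the reads are also written as FASTQ with constant quality ('I').
    Identical (config, seed) pairs produce byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = _species_table(refset, config)
    weights = np.array([s.weight for s in species], dtype=float)
    probs = weights / weights.sum()

    length_model = dict(config.five_prime_length_model)
    mu5, sd5 = length_model[config.condition]
    mu5_ctrl, sd5_ctrl = length_model["control"]
    mu_r, sd_r = config.rrna_length_model[config.condition]
    mu_o, sd_o = config.other_length_model

    n = config.n_reads
    idx = rng.choice(len(species), size=n, p=probs)
    normals = rng.standard_normal(n)

    seqs = {r: s.sequence for r, s in refset.sequences.items()}
    reads: list[tuple[str, str]] = []
    la = config.adapter3
    n5, n3 = config.n_random5, config.n_random3
    # pre-draw the random flanks in one block for speed and determinism
    flanks = rng.integers(0, 4, size=(n, n5 + n3))
    err_draws = rng.random(size=(n, config.read_length))
    err_bases = rng.integers(1, 4, size=(n, config.read_length))

    base_order = "ACGT"
    base_index = {b: i for i, b in enumerate(base_order)}

    for i in range(n):
        sp = species[idx[i]]
        ref_seq = seqs[sp.ref_id]
        L = len(ref_seq)
        if sp.kind == FIVE_PRIME:
            mu, sd = (mu5, sd5)
        elif sp.kind == THREE_PRIME:
            mu, sd = (mu5_ctrl, sd5_ctrl)  # 3' halves unaffected by treatment
        elif sp.rna_class in ("rRNA", "mt_rRNA"):
            mu, sd = (mu_r, sd_r)
        elif sp.rna_class == "miRNA":
            mu, sd = (float(L), 0.0)
        else:
            mu, sd = (mu_o, sd_o)
        frag_len = int(round(mu + sd * normals[i]))
        frag_len = max(config.min_insert, min(frag_len, config.max_insert, L))
        if sp.kind == FIVE_PRIME:
            start = 0
        elif sp.kind == THREE_PRIME:
            start = L - frag_len
        elif L == frag_len:
            start = 0
        else:
            start = int(rng.integers(0, L - frag_len + 1))  # uniform window
        insert = ref_seq[start : start + frag_len]
        flank = flanks[i]
        raw = (
            "".join(base_order[b] for b in flank[:n5])
            + insert
            + "".join(base_order[b] for b in flank[n5:])
            + la
        )
        raw = raw[: config.read_length]
        if config.seq_error_rate > 0:
            chars = list(raw)
            hits = np.nonzero(err_draws[i, : len(raw)] < config.seq_error_rate)[0]
            for j in hits:
                b = chars[j]
                if b in base_index:
                    chars[j] = base_order[(base_index[b] + err_bases[i, j]) % 4]
            raw = "".join(chars)
        reads.append((f"sim_{config.condition}_{config.seed}_{i:07d}", raw))

    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return reads, ground_truth(refset, config)


# ---------------------------------------------------------------------------
# Phenotype simulators


@dataclass
class PhenoSimConfig:
    """Group-level parameters for morphometric / categorical phenotypes.

    ``groups`` maps group name -> dict with keys ``n`` (embryos), ``mean``
    and ``sd`` (trait units, e.g. micrometres) for continuous traits, or
    ``p_affected`` for categorical ones.
    """

    groups: dict
    trait: str = "trait"
    seed: int = 0

    def validate_morphometry(self) -> None:
        for g, spec in self.groups.items():
            if spec["n"] < 2:
                raise ValueError(f"group {g}: n must be >= 2")
            if spec["sd"] < 0:
                raise ValueError(f"group {g}: sd must be >= 0")

    def validate_counts(self) -> None:
        for g, spec in self.groups.items():
            if not (0.0 <= spec["p_affected"] <= 1.0):
                raise ValueError(f"group {g}: p_affected outside [0, 1]")


def simulate_morphometry(config: PhenoSimConfig) -> pd.DataFrame:
    """Draw per-embryo trait values ~ Normal(mean, sd) for each group."""
    config.validate_morphometry()
    rng = np.random.default_rng(config.seed)
    rows = []
    for group, spec in config.groups.items():
        values = spec["mean"] + spec["sd"] * rng.standard_normal(spec["n"])
        for i, v in enumerate(values):
            rows.append(
                {
                    "embryo_id": f"{group}_{i + 1:03d}",
                    "group": group,
                    "trait": config.trait,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


def simulate_phenotype_counts(config: PhenoSimConfig) -> pd.DataFrame:
    """Affected counts ~ Binomial(n, p) per group; returns a 2-column table."""
    config.validate_counts()
    rng = np.random.default_rng(config.seed)
    rows = []
    for group, spec in config.groups.items():
        affected = int(rng.binomial(spec["n"], spec["p_affected"]))
        rows.append(
            {
                "group": group,
                "affected": affected,
                "normal": spec["n"] - affected,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def simulated_refset_with_halves(seed: int = 2023) -> ReferenceSet:
    """Example reference with 5'/3' half features already built."""
    return build_half_annotations(example_reference(seed))
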