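"""End-to-end orchestration: simulate -> preprocess -> align -> count ->
differential expression -> half-ratio statistics -> report.

Everything is deterministic given (config, seed): simulation is the only
randomized stage and each library derives its seed from the global seed and
its sample index.  Stages are plain functions over in-memory objects so the
CLI subcommands and the tests can run them individually; ``run_pipeline``
wires them together and writes TSV/JSON artifacts.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

from . import refmodel, rnastats, simdata, smallmap
from .preprocess import ReadRecord, preprocess_reads
from .refmodel import FIVE_PRIME, FULL, THREE_PRIME, ReferenceSet
from .simdata import LibrarySimConfig

DEFAULT_N_REPLICATES = 3


def sample_seed(global_seed: int, index: int) -> int:
    """Per-library seed derived from the run seed (stays below 2^31)."""
    return (global_seed * 1_000 + index) % (2**31 - 1)


def simulate_study(
    refset: ReferenceSet,
    seed: int,
    n_replicates: int = DEFAULT_N_REPLICATES,
    n_reads: int = 50_000,
    **config_overrides,
) -> dict[str, tuple[list[tuple[str, str]], str]]:
    """Simulate a control-vs-treated study; returns sample -> (reads, cond)."""
    samples: dict[str, tuple[list[tuple[str, str]], str]] = {}
    i = 0
    for condition, prefix in (("control", "ctrl"), ("treated", "mtx")):
        for rep in range(1, n_replicates + 1):
            cfg = LibrarySimConfig(
                n_reads=n_reads,
                condition=condition,
                seed=sample_seed(seed, i),
                **config_overrides,
            )
            reads, _ = simdata.simulate_library(refset, cfg)
            samples[f"{prefix}{rep}"] = (reads, condition)
            i += 1
    return samples


def feature_metadata(refset: ReferenceSet) -> pd.DataFrame:
    """feature_id -> (parent, kind, rna_class, isoacceptor) table."""
    rows = []
    for f in refset.features.values():
        ann = refset.trna_annotations.get(f.parent_ref_id)
        rows.append(
            {
                "feature_id": f.feature_id,
                "parent_ref_id": f.parent_ref_id,
                "kind": f.kind,
                "rna_class": refset.class_of(f.parent_ref_id),
                "isoacceptor": ann.isoacceptor if ann else None,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def analyze_samples(
    samples: dict[str, tuple[list[tuple[str, str]], str]],
    refset: ReferenceSet,
    adapter3: str = simdata.DEFAULT_ADAPTER3,
    max_mismatch: int = 1,
    min_overlap_frac: float = 0.5,
) -> dict:
    """Run both trimming modes, align, count, and compute the statistics.

    Returns a dict of intermediate and final tables keyed by stage name.
    """
    if not refset.half_pairs():
        refmodel.build_half_annotations(refset)
    full_feats = [f for f in refset.features.values() if f.kind == FULL]
    if not full_feats:
        refmodel.build_full_length_features(refset)
        full_feats = [f for f in refset.features.values() if f.kind == FULL]
    half_feats = refset.features_of_kind(FIVE_PRIME, THREE_PRIME)
    index = smallmap.RefIndex(refset)

    condition = {name: cond for name, (_, cond) in samples.items()}
    trim_reports: dict[str, dict] = {}
    counts_classes: dict[str, pd.Series] = {}
    counts_halves: dict[str, pd.Series] = {}
    hits_by_condition: dict[str, list[smallmap.AlignmentHit]] = {
        "control": [],
        "treated": [],
    }
    align_totals: dict[str, dict] = {}

    for name, (reads, cond) in samples.items():
        # constant quality; the pipeline never uses base qualities
        records = [ReadRecord(rid, seq, "I" * len(seq)) for rid, seq in reads]
        snc_reads, rep_snc = preprocess_reads(records, "sncrna", adapter3)
        half_reads, rep_half = preprocess_reads(records, "halves", adapter3)
        trim_reports[name] = {
            "sncrna": rep_snc.to_dict(),
            "halves": rep_half.to_dict(),
        }
        snc_hits, snc_unal = smallmap.align_reads(
            [(r.read_id, r.sequence) for r in snc_reads],
            refset,
            max_mismatch,
            index=index,
        )
        half_hits, half_unal = smallmap.align_reads(
            [(r.read_id, r.sequence) for r in half_reads],
            refset,
            max_mismatch,
            index=index,
        )
        align_totals[name] = {
            "sncrna_aligned_reads": rep_snc.reads_out - snc_unal,
            "sncrna_unaligned": snc_unal,
            "halves_aligned_reads": rep_half.reads_out - half_unal,
            "halves_unaligned": half_unal,
        }
        counts_classes[name] = smallmap.count_features(
            snc_hits, full_feats, min_overlap_frac
        )
        counts_halves[name] = smallmap.count_features(
            half_hits, half_feats, min_overlap_frac
        )
        hits_by_condition[cond].extend(snc_hits)

    table_classes = smallmap.build_count_table(counts_classes)
    table_halves = smallmap.build_count_table(counts_halves)
    meta = feature_metadata(refset)
    feature_class = meta["rna_class"]
    rpm = smallmap.rpm_normalize(table_classes, feature_class)

    de_classes = rnastats.nb_wald_test(table_classes, condition)
    de_halves = rnastats.nb_wald_test(table_halves, condition)

    percents = rnastats.half_percentages_from_counts(table_halves, meta, condition)
    half_tests = rnastats.half_ratio_test(percents)

    length_dists = {}
    medians = {}
    for cond, hits in hits_by_condition.items():
        if hits:
            dist = smallmap.length_stats(hits, refset, "tRNA")
            length_dists[cond] = dist
            medians[cond] = dist.median

    return {
        "condition": condition,
        "hits_by_condition": hits_by_condition,
        "trim_reports": trim_reports,
        "align_totals": align_totals,
        "counts_classes": table_classes,
        "counts_halves": table_halves,
        "rpm_classes": rpm,
        "de_classes": de_classes,
        "de_halves": de_halves,
        "half_percents": percents,
        "half_tests": half_tests,
        "length_dists": length_dists,
        "trna_length_medians": medians,
        "feature_meta": meta,
    }


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the configured study end to end, writing artifacts to ``outdir``.

    Config keys (all optional except ``seed``): ``seed``; ``simulate``
    (n_replicates, n_reads, plus any LibrarySimConfig override);
    ``reference`` (fasta + class_table paths; defaults to the bundled
    synthetic reference); ``samples`` (list of {name, condition, fastq})
    as an alternative to simulation; ``adapter3``; ``align.max_mismatch``;
    ``count.min_overlap_frac``; ``coverage_refs``.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    ref_cfg = config.get("reference") or {}
    if ref_cfg.get("fasta"):
        fasta, table = Path(ref_cfg["fasta"]), Path(ref_cfg["class_table"])
        for p in (fasta, table):
            if not p.exists():
                raise FileNotFoundError(f"reference input missing: {p}")
        refset = refmodel.load_reference(fasta, table)
    else:
        refset = simdata.example_reference(seed=int(ref_cfg.get("seed", 2023)))
    refmodel.build_half_annotations(refset)
    refmodel.build_full_length_features(refset)
    refmodel.write_reference_fasta(refset, outdir / "reference.fasta")
    refmodel.write_class_table(refset, outdir / "reference_classes.tsv")
    refmodel.write_features_gtf(
        refset.features_of_kind(FIVE_PRIME, THREE_PRIME), outdir / "trna_halves.gtf"
    )
    refmodel.write_features_gtf(
        refset.features_of_kind(FULL), outdir / "full_length.gtf"
    )

    adapter3 = config.get("adapter3", simdata.DEFAULT_ADAPTER3)
    if config.get("samples"):
        from .preprocess import read_fastq

        samples = {}
        for s in config["samples"]:
            path = Path(s["fastq"])
            if not path.exists():
                raise FileNotFoundError(f"sample FASTQ missing: {path}")
            reads = [(r.read_id, r.sequence) for r in read_fastq(path)]
            samples[s["name"]] = (reads, s["condition"])
    else:
        sim_cfg = dict(config.get("simulate") or {})
        n_replicates = int(sim_cfg.pop("n_replicates", DEFAULT_N_REPLICATES))
        n_reads = int(sim_cfg.pop("n_reads", 50_000))
        samples = simulate_study(
            refset, seed, n_replicates, n_reads, adapter3=adapter3, **sim_cfg
        )
        for name, (reads, _) in samples.items():
            with open(outdir / f"{name}.raw.fastq", "w") as fh:
                for rid, seq in reads:
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    align_cfg = config.get("align") or {}
    count_cfg = config.get("count") or {}
    results = analyze_samples(
        samples,
        refset,
        adapter3=adapter3,
        max_mismatch=int(align_cfg.get("max_mismatch", 1)),
        min_overlap_frac=float(count_cfg.get("min_overlap_frac", 0.5)),
    )

    header = f"# tsrnapipe run seed={seed}\n"

    def _write(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index)

    _write(results["counts_classes"], "counts_classes.tsv")
    _write(results["counts_halves"], "counts_halves.tsv")
    _write(results["rpm_classes"], "rpm_classes.tsv")
    _write(results["de_classes"], "de_classes.tsv")
    _write(results["de_halves"], "de_halves.tsv")
    _write(results["half_percents"], "half_percents.tsv", index=False)
    _write(results["half_tests"], "half_ratio_tests.tsv")
    for cond, dist in results["length_dists"].items():
        _write(
            dist.counts.rename("fractional_count").to_frame(),
            f"trna_lengths_{cond}.tsv",
        )

    for ref_id in config.get("coverage_refs") or []:
        ref_len = len(refset.sequences[ref_id])
        for cond, hits in results["hits_by_condition"].items():
            cov = smallmap.compute_coverage(hits, ref_id, ref_len)
            smallmap.write_bedgraph(
                cov, ref_id, outdir / f"coverage_{ref_id}_{cond}.bedgraph"
            )

    report = {
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "samples"},
        "samples": {name: cond for name, (_, cond) in samples.items()},
        "trim_reports": results["trim_reports"],
        "align_totals": results["align_totals"],
        "trna_length_medians": results["trna_length_medians"],
        "n_features": {
            "classes": int(len(results["counts_classes"])),
            "halves": int(len(results["counts_halves"])),
        },
        "de_calls": {
            "classes": results["de_classes"]["call"].value_counts().to_dict(),
            "halves": results["de_halves"]["call"].value_counts().to_dict(),
        },
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
        fh.write("\n")
    results["report"] = report
    return results
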