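"""End-to-end orchestration: simulate -> annotate -> count -> diffexp -> oxbs -> enrich.

Stages exchange flat TSV/BED/SAM/FASTQ files inside one output directory, so
any stage can be rerun or inspected independently, and a ``manifest.json``
records the seed, per-stage row counts, input checksums and timings. Rerun
with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import counting, diffexp, enrichment, oxbs, repeats, simulate

__all__ = ["ConfigError", "DataError", "load_config", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger("retrosilence")

ALL_STAGES = ("simulate", "annotate", "count", "diffexp", "oxbs", "enrich")

DEFAULT_THRESHOLDS = {
    "merge_gap": 100,  # bp bridged when merging same-strand fragments
    "detection_rpm": 0.25,  # copy detectability threshold
    "copy_fold": 10.0,  # per-copy activation fold
    "pseudocount_rpm": 0.1,
    "de_lfc": 1.0,  # log2 of the "more than twofold" rule
    "de_alpha": 0.05,
    "min_coverage": 100,  # BS/oxBS reads per CpG per treatment
    "n_shuffles": 1000,
}


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or malformed stage inputs (CLI exit code 3)."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    cfg = dict(cfg)
    cfg.setdefault("seed", 0)
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    for key, val in thresholds.items():
        if not isinstance(val, (int, float)) or val <= 0:
            raise ConfigError(f"threshold {key!r} must be a positive number, got {val!r}")
    cfg["thresholds"] = thresholds
    cfg.setdefault("simulation", {})
    cfg.setdefault("merge_names", ["IAPEz"])
    try:
        cfg["_sim_config"] = simulate.SimulationConfig(
            seed=cfg["seed"], **cfg["simulation"]
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulation settings: {exc}") from exc
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    cfg: dict,
    outdir: str | Path,
    stages: tuple[str, ...] | None = None,
) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    Later stages read the files earlier stages wrote, so a stage subset on a
    directory with precomputed inputs only touches its own outputs; a
    missing upstream file raises :class:`DataError` naming the stage.
    """
    cfg = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages) if stages else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in ALL_STAGES if s in stages)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "seed": cfg["seed"],
        "thresholds": cfg["thresholds"],
        "stages": {},
    }
    simdir = outdir / "sim"
    th = cfg["thresholds"]
    sim_config = cfg["_sim_config"]

    try:
        for stage in stages:
            t0 = time.perf_counter()
            logger.info("stage %s starting (seed %d)", stage, cfg["seed"])
            info = _STAGE_FUNCS[stage](cfg, sim_config, th, outdir, simdir)
            info["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][stage] = info
            logger.info("stage %s done in %.2fs", stage, info["seconds"])
    finally:
        logger.removeHandler(handler)
        handler.close()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DataError(f"stage {stage!r}: missing upstream output {path}")
    return path


def _stage_simulate(cfg, sim_config, th, outdir, simdir) -> dict:
    paths = simulate.simulate_all(sim_config, simdir)
    return {
        "outputs": {k: str(v) for k, v in paths.items()},
        "checksums": {k: _sha256(v) for k, v in paths.items()},
        "n_samples": len(sim_config.library_sizes),
    }


def _stage_annotate(cfg, sim_config, th, outdir, simdir) -> dict:
    rm_path = _require(simdir / "repeats.out", "annotate")
    fragments = repeats.parse_repeatmasker(rm_path)
    merged = repeats.merge_fragments(
        fragments, gap=int(th["merge_gap"]), name_scope=set(cfg["merge_names"])
    )
    all_merged = repeats.merge_fragments(fragments, gap=int(th["merge_gap"]))
    repeats.write_bed(merged, outdir / "elements_iap.bed")
    repeats.write_bed(all_merged, outdir / "elements_all.bed")
    return {
        "n_fragments": len(fragments),
        "n_elements_iap_scope": len(merged),
        "n_elements_all": len(all_merged),
        "n_full_length": sum(e.full_length for e in all_merged),
        "checksums": {"repeatmasker": _sha256(rm_path)},
    }


def _stage_count(cfg, sim_config, th, outdir, simdir) -> dict:
    elements = repeats.read_bed(_require(outdir / "elements_all.bed", "count"))
    samples = list(sim_config.library_sizes)
    class_per_sample: dict = {}
    copy_per_sample: dict = {}
    lib_sizes: dict[str, int] = {}
    for sample in samples:
        sam = _require(simdir / f"{sample}.sam", "count")
        alignments = counting.read_sam_alignments(sam)
        lib_sizes[sample] = len(alignments)
        class_per_sample[sample] = counting.count_by_class_inclusive(alignments, elements)
        copy_per_sample[sample] = counting.count_by_copy_unique(alignments, elements)
    class_table = counting.build_class_table(class_per_sample, lib_sizes)
    copy_table = counting.build_copy_table(copy_per_sample, lib_sizes, elements)
    class_table.counts.to_csv(outdir / "class_counts.tsv", sep="\t", index_label="repeat_class")
    copy_table.counts.to_csv(outdir / "copy_counts.tsv", sep="\t", index_label="copy")
    copy_table.rpm().to_csv(outdir / "copy_rpm.tsv", sep="\t", index_label="copy")
    pd.DataFrame(
        {
            "library_size": pd.Series(lib_sizes),
            "unassigned": class_table.unassigned,
            "condition": pd.Series(sim_config.sample_conditions),
        }
    ).to_csv(outdir / "samples.tsv", sep="\t", index_label="sample")

    # per-copy tenfold classification on unique-regime RPM
    rpm = counting.filter_detectable(copy_table.rpm(), threshold=th["detection_rpm"])
    cond = pd.Series(sim_config.sample_conditions)
    ctrl_cols = [s for s in samples if cond[s] == "A"]
    depl_cols = [s for s in samples if cond[s] == "B"]
    calls = counting.classify_fold_change(
        rpm[ctrl_cols], rpm[depl_cols],
        fold=th["copy_fold"], pseudocount=th["pseudocount_rpm"],
    )
    calls.rename("upregulated").to_csv(outdir / "copy_classification.tsv", sep="\t", index_label="copy")
    summary = counting.summarize_classification(calls)
    with open(outdir / "classification_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {
        "library_sizes": lib_sizes,
        "n_classes": int(len(class_table.counts)),
        "n_copies": int(len(copy_table.counts)),
        "classification": summary,
    }


def _stage_diffexp(cfg, sim_config, th, outdir, simdir) -> dict:
    counts = pd.read_csv(
        _require(outdir / "class_counts.tsv", "diffexp"), sep="\t", index_col=0
    )
    samples = pd.read_csv(
        _require(outdir / "samples.tsv", "diffexp"), sep="\t", index_col=0
    )
    res = diffexp.run_diffexp(
        counts,
        samples["condition"],
        lfc_threshold=th["de_lfc"],
        alpha_level=th["de_alpha"],
    )
    res.table.to_csv(outdir / "diffexp.tsv", sep="\t", index_label="repeat_class")
    return {
        "n_tested": int(res.table["pvalue"].notna().sum()),
        "n_called": int(res.table["call"].sum()),
        "called": sorted(res.called),
    }


def _stage_oxbs(cfg, sim_config, th, outdir, simdir) -> dict:
    amplicons = oxbs.load_amplicons(_require(simdir / "amplicons.fa", "oxbs"))
    replicate_calls = []
    for rep in range(1, sim_config.bs_replicates + 1):
        bs_reads: list[str] = []
        ox_reads: list[str] = []
        for amp in amplicons:
            bs_reads.extend(
                oxbs.read_fastq_sequences(
                    _require(simdir / f"{amp.name}_BS_rep{rep}.fastq", "oxbs")
                )
            )
            ox_reads.extend(
                oxbs.read_fastq_sequences(
                    _require(simdir / f"{amp.name}_oxBS_rep{rep}.fastq", "oxbs")
                )
            )
        replicate_calls.append(
            oxbs.run_oxbs(amplicons, bs_reads, ox_reads, min_coverage=int(th["min_coverage"]))
        )
    per_rep = pd.concat(
        [oxbs.calls_to_frame(calls).assign(replicate=i + 1) for i, calls in enumerate(replicate_calls)]
    )
    per_rep.to_csv(outdir / "methylation_per_replicate.tsv", sep="\t", index=False)
    agg = oxbs.aggregate_amplicon(replicate_calls)
    agg.to_csv(outdir / "methylation.tsv", sep="\t")
    return {
        "n_cpgs_called": int(len(agg)),
        "n_amplicons": len(amplicons),
    }


def _stage_enrich(cfg, sim_config, th, outdir, simdir) -> dict:
    peaks = enrichment.read_bed_intervals(_require(simdir / "peaks.bed", "enrich"))
    mappable = enrichment.read_bed_intervals(_require(simdir / "mappable.bed", "enrich"))
    elements = repeats.read_bed(_require(outdir / "elements_all.bed", "enrich"))
    result = enrichment.enrichment_test(
        sorted(peaks), elements, mappable,
        n_shuffles=int(th["n_shuffles"]), seed=cfg["seed"],
    )
    result.to_tsv(outdir / "enrichment.tsv")
    return {
        "n_peaks": len(peaks),
        "n_shuffles": result.n_shuffles,
        "min_pvalue": float(result.table["pvalue"].min()),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "annotate": _stage_annotate,
    "count": _stage_count,
    "diffexp": _stage_diffexp,
    "oxbs": _stage_oxbs,
    "enrich": _stage_enrich,
}
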