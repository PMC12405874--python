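"""End-to-end orchestration: count -> normalize -> FD -> profiles.

A run is described by one YAML config (see :class:`RunConfig`); the
pipeline quantifies every sample's FASTQ(s), scores each treatment
condition against its matched controls, and writes counts, FD tables,
a coinhibition matrix and a machine-readable run report.  Reruns with
the same config reproduce outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._fastq import read_fastq
from .catalog import load_catalog
from .fitness import (
    SampleSheet,
    combine_tags,
    fd_scores,
    normalize,
    select_best_tag,
    write_fd_table,
)
from .layouts import preset_layout
from .matching import MatchParams, build_index, counts_frame, quantify_sample
from .profiles import coinhibition_matrix

log = logging.getLogger("barseqkit")


@dataclass
class RunConfig:
    catalog: Path
    sample_sheet: Path
    samples: dict[str, list[dict]]  # sample_id -> [{fastq, layout}, ...]
    match: MatchParams = field(default_factory=MatchParams)
    pseudocount: float = 1.0
    combination_mode: str = "best_tag"
    output_dir: Path = Path("barseq_results")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        match = MatchParams(**raw.get("match", {}))
        samples = {}
        for sid, entries in raw["samples"].items():
            if isinstance(entries, dict):
                entries = [entries]
            samples[sid] = entries
        return cls(
            catalog=Path(raw["catalog"]),
            sample_sheet=Path(raw["sample_sheet"]),
            samples=samples,
            match=match,
            pseudocount=float(raw.get("pseudocount", 1.0)),
            combination_mode=raw.get("combination_mode", "best_tag"),
            output_dir=Path(raw.get("output_dir", "barseq_results")),
        )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns a summary dict (the report)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = load_catalog(cfg.catalog)
    sheet = SampleSheet.from_tsv(cfg.sample_sheet)
    missing = set(sheet.table["sample_id"]) - set(cfg.samples)
    if missing:
        raise ValueError(f"sheet samples without FASTQs in config: {sorted(missing)}")
    index = build_index(catalog)

    columns: dict[str, pd.Series] = {}
    sample_stats: dict[str, dict] = {}
    for sample_id in sheet.table["sample_id"]:
        total: pd.Series | None = None
        agg: dict[str, int] = {}
        for entry in cfg.samples[sample_id]:
            layout = preset_layout(entry["layout"])
            params = cfg.match
            if layout.error_model == "with_indels" and params.metric == "hamming":
                params = MatchParams(
                    max_dist=max(params.max_dist, 3),
                    min_margin=params.min_margin,
                    metric="levenshtein",
                )
            log.info("counting sample=%s fastq=%s layout=%s",
                     sample_id, entry["fastq"], entry["layout"])
            col, stats = quantify_sample(
                read_fastq(entry["fastq"]), layout, index, params
            )
            total = col if total is None else (
                total.add(col, fill_value=0).astype("int64")
            )
            for k, v in stats.items():
                agg[k] = agg.get(k, 0) + v
        columns[sample_id] = total
        sample_stats[sample_id] = agg
        log.info("sample=%s reads=%d assigned=%d", sample_id,
                 agg.get("n_reads", 0), agg.get("assigned", 0))
    counts = counts_frame(columns, catalog)
    counts.to_csv(out / "counts.tsv", sep="\t")
    stats_frame = pd.DataFrame(sample_stats).T
    stats_frame.index.name = "sample_id"
    stats_frame.to_csv(out / "stats.tsv", sep="\t")

    norm = normalize(counts, cfg.pseudocount)
    profiles = {}
    for condition in sheet.treatment_conditions():
        assay = sheet.assay_of_condition(condition)
        profile = fd_scores(norm, sheet, condition)
        best = None
        if cfg.combination_mode == "best_tag":
            best = select_best_tag(norm, sheet, assay=assay)
        profile = combine_tags(
            profile,
            mode=cfg.combination_mode,
            best=best,
            counts=counts,
            sheet=sheet,
            pseudocount=cfg.pseudocount,
        )
        write_fd_table(profile, out / f"fd_{condition}.tsv", best=best)
        profiles[condition] = profile
    if len(profiles) >= 2:
        coinh = coinhibition_matrix(
            {c: p.combined for c, p in profiles.items()}
        )
        coinh.to_csv(out / "coinhibition.tsv", sep="\t", float_format="%.6g")

    report = {
        "barseqkit_version": __version__,
        "parameters": {
            "match": {
                "max_dist": cfg.match.max_dist,
                "min_margin": cfg.match.min_margin,
                "metric": cfg.match.metric,
            },
            "pseudocount": cfg.pseudocount,
            "combination_mode": cfg.combination_mode,
        },
        "n_strains": len(catalog),
        "samples": sample_stats,
        "conditions": list(profiles),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
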