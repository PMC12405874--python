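"""Ground-truth simulator for pooled Bar-seq screens.

Models the study design end to end: a barcoded pool grows for g
generations under treatment, where a strain with fitness coefficient s
grows as 2^{g(1-s)} relative to a neutral strain (so its planted
fitness defect is ~g*s log2 units after renormalization); tag-specific
PCR amplification bias is multiplicative lognormal, drawn per tag
independently ("trans", as when the two tags are amplified in separate
reactions) or shared per strain ("cis", as when one long read spans
both tags); sequencing depth is multinomial; and reads are rendered
through any platform layout with substitution and (for long-read
layouts) indel errors.

Everything is driven by one integer seed and is bit-for-bit
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._fastq import write_fastq
from .catalog import BarcodeCatalog, BarcodeRecord, write_catalog
from .fitness import SampleSheet
from .layouts import (
    NANOPORE_INDEX_LEN,
    PLATFORMS,
    ReadLayout,
    preset_layout,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated screen.

    Defaults model a homozygous-pool (HOP) screen: ~5 generations of
    growth, a small affected cohort, modest lognormal variation in
    starting abundance and tag efficiency, and short-read error rates
    around 1% substitutions.  ``depth_per_sample`` is the total read
    depth of one sample, split evenly between the two tag PCRs.
    """

    n_strains: int = 1000
    assay: str = "HOP"
    generations: float | None = None  # default 20 for HIP, 5 for HOP
    fraction_affected: float = 0.05
    fitness_coefficients: tuple[float, ...] | None = None
    affected_s_range: tuple[float, float] = (0.1, 0.8)
    initial_abundance_sigma: float = 0.5
    tag_efficiency_sigma: float = 0.3
    tag_linkage: str = "trans"  # "cis" for long-read, "trans" for short-read
    replicate_efficiency_sigma: tuple[float, float] = (0.0, 0.0)  # (uptag, downtag)
    depth_per_sample: int = 200_000
    error_rate_substitution: float = 0.01
    error_rates_indel: tuple[float, float] = (0.005, 0.005)  # (insertion, deletion)
    fraction_uptag_only: float = 0.03
    stuffer_len: int = 1400  # unsequenced cassette interior in long reads
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.depth_per_sample < 1:
            raise ValueError("n_strains and depth_per_sample must be positive")
        for p in (
            self.fraction_affected,
            self.error_rate_substitution,
            *self.error_rates_indel,
            self.fraction_uptag_only,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.tag_linkage not in {"cis", "trans"}:
            raise ValueError("tag_linkage must be 'cis' or 'trans'")
        if self.assay not in {"HIP", "HOP"}:
            raise ValueError("assay must be 'HIP' or 'HOP'")

    @property
    def g(self) -> float:
        if self.generations is not None:
            return self.generations
        return 20.0 if self.assay == "HIP" else 5.0


@dataclass
class SimTruth:
    """Ground truth of one simulated pool."""

    strain_ids: list[str]
    s: np.ndarray
    true_fd: np.ndarray  # log2(a_ctrl / a_trt), exactly as realized
    abundance_initial: np.ndarray
    abundance_control: np.ndarray
    abundance_treated: np.ndarray
    uptag_efficiency: np.ndarray
    downtag_efficiency: np.ndarray
    uptag_only: np.ndarray  # boolean mask

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain_id": self.strain_ids,
                "s": self.s,
                "true_fd": self.true_fd,
                "abundance_initial": self.abundance_initial,
                "abundance_control": self.abundance_control,
                "abundance_treated": self.abundance_treated,
                "uptag_efficiency": self.uptag_efficiency,
                "downtag_efficiency": self.downtag_efficiency,
                "uptag_only": self.uptag_only,
            }
        ).set_index("strain_id")


def _random_tags(rng: np.random.Generator, n: int, existing: list[str],
                 min_hamming: int) -> list[str]:
    """Random 20-mers with all-pairs Hamming distance >= min_hamming."""
    accepted: list[np.ndarray] = [
        np.frombuffer(t.encode(), dtype=np.uint8) for t in existing
    ]
    out: list[str] = []
    mat = np.array(accepted) if accepted else np.empty((0, 20), dtype=np.uint8)
    while len(out) < n:
        cand = _BASES[rng.integers(0, 4, size=20)]
        if mat.shape[0]:
            if int((mat != cand).sum(axis=1).min()) < min_hamming:
                continue
        mat = np.vstack([mat, cand])
        out.append(cand.tobytes().decode())
    return out


def make_catalog(
    cfg: SimConfig, rng: np.random.Generator, min_hamming: int = 5
) -> BarcodeCatalog:
    """Random catalog matching the pool: two 20-bp tags per strain, a
    ``fraction_uptag_only`` subset lacking the downtag, and a guaranteed
    minimum within-class pairwise Hamming distance."""
    n = cfg.n_strains
    uptags = _random_tags(rng, n, [], min_hamming)
    downtags = _random_tags(rng, n, [], min_hamming)
    n_up_only = int(round(cfg.fraction_uptag_only * n))
    up_only = np.zeros(n, dtype=bool)
    if n_up_only:
        up_only[rng.choice(n, size=n_up_only, replace=False)] = True
    records = [
        BarcodeRecord(
            strain_id=f"STR{i:05d}",
            uptag=uptags[i],
            downtag=None if up_only[i] else downtags[i],
        )
        for i in range(n)
    ]
    return BarcodeCatalog(records)


def simulate_abundances(cfg: SimConfig) -> SimTruth:
    """Draw the pool's growth outcome and per-tag efficiencies.

    Initial abundances are lognormal; treated abundance scales as
    2^{-g*s} relative to control before renormalization.  ``true_fd``
    records log2(control/treated) exactly as realized (equal to g*s
    plus a common renormalization constant shared by all strains).
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n_strains
    if cfg.fitness_coefficients is not None:
        s = np.asarray(cfg.fitness_coefficients, dtype=float)
        if s.shape != (n,):
            raise ValueError("fitness_coefficients length != n_strains")
    else:
        s = np.zeros(n)
        n_aff = int(round(cfg.fraction_affected * n))
        if n_aff:
            idx = rng.choice(n, size=n_aff, replace=False)
            s[idx] = rng.uniform(*cfg.affected_s_range, size=n_aff)
    if (s > 1).any():
        raise ValueError("fitness coefficients s > 1 are undefined here")

    a0 = rng.lognormal(0.0, cfg.initial_abundance_sigma, n)
    a0 = a0 / a0.sum()
    w = a0 * np.exp2(-cfg.g * s)
    a_trt = w / w.sum()
    a_ctrl = a0
    true_fd = np.log2(a_ctrl / a_trt)

    e_up = rng.lognormal(0.0, cfg.tag_efficiency_sigma, n)
    if cfg.tag_linkage == "cis":
        e_dn = e_up.copy()
    else:
        e_dn = rng.lognormal(0.0, cfg.tag_efficiency_sigma, n)
    n_up_only = int(round(cfg.fraction_uptag_only * n))
    up_only = np.zeros(n, dtype=bool)
    if n_up_only:
        up_only[rng.choice(n, size=n_up_only, replace=False)] = True

    return SimTruth(
        strain_ids=[f"STR{i:05d}" for i in range(n)],
        s=s,
        true_fd=true_fd,
        abundance_initial=a0,
        abundance_control=a_ctrl,
        abundance_treated=a_trt,
        uptag_efficiency=e_up,
        downtag_efficiency=e_dn,
        uptag_only=up_only,
    )


def expected_shares(
    truth: SimTruth, role: str, tag_class: str, jitter: np.ndarray | None = None
) -> np.ndarray:
    """Expected within-class read shares for one sample.

    Share of strain i ∝ abundance(role) × tag efficiency; strains
    without the tag get share zero.  ``jitter`` optionally multiplies in
    per-replicate amplification noise.
    """
    a = truth.abundance_treated if role == "treatment" else truth.abundance_control
    e = (
        truth.uptag_efficiency
        if tag_class == "uptag"
        else truth.downtag_efficiency
    )
    w = a * e
    if jitter is not None:
        w = w * jitter
    if tag_class == "downtag":
        w = np.where(truth.uptag_only, 0.0, w)
    return w / w.sum()


def simulate_counts(
    truth: SimTruth,
    cfg: SimConfig,
    samples: list[tuple[str, str]],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Multinomial tag counts for each (sample_id, role) pair.

    The per-sample depth is split evenly between the uptag and downtag
    reactions (they are pooled equally after PCR); each half is one
    multinomial draw over that class's expected shares.  Column sums
    equal ``depth_per_sample`` exactly.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1])
    n = cfg.n_strains
    rows_up = [(sid, "uptag") for sid in truth.strain_ids]
    rows_dn = [
        (sid, "downtag")
        for sid, only in zip(truth.strain_ids, truth.uptag_only)
        if not only
    ]
    index = pd.MultiIndex.from_tuples(
        rows_up + rows_dn, names=["strain_id", "tag_class"]
    )
    depth_up = cfg.depth_per_sample // 2
    depth_dn = cfg.depth_per_sample - depth_up
    cols = {}
    sig_up, sig_dn = cfg.replicate_efficiency_sigma
    for sample_id, role in samples:
        jit_up = rng.lognormal(0.0, sig_up, n) if sig_up > 0 else None
        jit_dn = rng.lognormal(0.0, sig_dn, n) if sig_dn > 0 else None
        p_up = expected_shares(truth, role, "uptag", jit_up)
        p_dn = expected_shares(truth, role, "downtag", jit_dn)
        c_up = rng.multinomial(depth_up, p_up)
        c_dn = rng.multinomial(depth_dn, p_dn)
        cols[sample_id] = np.concatenate(
            [c_up, c_dn[~truth.uptag_only]]
        )
    return pd.DataFrame(cols, index=index).sort_index()


def _mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    lut = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
    for p in pos:
        arr[p] = lut.get(arr[p], b"ACG")[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _mutate_indels(
    seq: str, ins_rate: float, del_rate: float, rng: np.random.Generator
) -> str:
    if ins_rate <= 0 and del_rate <= 0:
        return seq
    n_del = rng.binomial(len(seq), del_rate) if del_rate > 0 else 0
    if n_del:
        keep = np.ones(len(seq), dtype=bool)
        keep[rng.choice(len(seq), size=n_del, replace=False)] = False
        seq = "".join(c for c, k in zip(seq, keep) if k)
    n_ins = rng.binomial(len(seq) + 1, ins_rate) if ins_rate > 0 else 0
    if n_ins and seq:
        positions = sorted(rng.integers(0, len(seq) + 1, size=n_ins), reverse=True)
        for p in positions:
            base = "ACGT"[rng.integers(0, 4)]
            seq = seq[:p] + base + seq[p:]
    return seq


def make_index_table(
    n: int, rng: np.random.Generator, min_hamming: int = 3
) -> list[tuple[str, str]]:
    """n distinct 10-mer sample indexes with pairwise Hamming >= 3."""
    seqs: list[str] = []
    mat = np.empty((0, NANOPORE_INDEX_LEN), dtype=np.uint8)
    while len(seqs) < n:
        cand = _BASES[rng.integers(0, 4, size=NANOPORE_INDEX_LEN)]
        if mat.shape[0] and int((mat != cand).sum(axis=1).min()) < min_hamming:
            continue
        mat = np.vstack([mat, cand])
        seqs.append(cand.tobytes().decode())
    return [(seq, f"S{i + 1}") for i, seq in enumerate(seqs)]


def _render_read(
    layout: ReadLayout,
    rec: BarcodeRecord,
    cfg: SimConfig,
    rng: np.random.Generator,
    stuffer: str,
    sample_index_seq: str | None,
) -> str:
    parts: list[str] = []
    for seg in layout.segments:
        if seg.kind == "fixed":
            parts.append(seg.sequence)
        elif seg.kind == "stagger":
            variants = seg.variants or ("", "A", "GC", "TTG")
            parts.append(variants[rng.integers(0, len(variants))])
        elif seg.kind == "skip":
            if seg.max_len < 0:
                parts.append(stuffer)
            elif seg.max_len > 0:
                parts.append(
                    _BASES[rng.integers(0, 4, size=seg.max_len)].tobytes().decode()
                )
        elif seg.kind == "sample_index":
            if sample_index_seq is None:
                raise ValueError("layout has a sample index but none was given")
            parts.append(sample_index_seq)
        elif seg.kind == "tag":
            tag = rec.tag(seg.tag_class)
            if tag is None:
                # uptag-only strain: the cassette still has a (foreign)
                # downtag region; emit a random 20-mer
                tag = _BASES[rng.integers(0, 4, size=20)].tobytes().decode()
            parts.append(tag)
    seq = "".join(parts)
    if layout.error_model == "with_indels":
        seq = _mutate_indels(seq, *cfg.error_rates_indel, rng)
    seq = _mutate_substitutions(seq, cfg.error_rate_substitution, rng)
    if layout.scan_both_orientations and rng.integers(0, 2):
        seq = revcomp(seq)
    return seq


def synth_reads(
    counts_col: pd.Series,
    catalog: BarcodeCatalog,
    layout: ReadLayout,
    cfg: SimConfig,
    rng: np.random.Generator,
    sample_index_seq: str | None = None,
    read_prefix: str = "r",
):
    """Yield (read_id, sequence, strain_id) for one sample column.

    ``counts_col`` is indexed by (strain_id, tag_class).  Single-tag
    layouts render the rows of their tag class; the long-read layout
    renders one read per molecule using the uptag rows (each read spans
    both tags).  Read ids embed the source strain after the last ':'.
    """
    by_strain = {rec.strain_id: rec for rec in catalog}
    classes = layout.tag_classes
    if len(classes) == 1:
        rows = counts_col.xs(classes[0], level="tag_class")
    else:
        rows = counts_col.xs("uptag", level="tag_class")
    stuffer = ""
    if any(seg.kind == "skip" and seg.max_len < 0 for seg in layout.segments):
        stuffer = _BASES[rng.integers(0, 4, size=cfg.stuffer_len)].tobytes().decode()
    i = 0
    for strain_id, count in rows.items():
        rec = by_strain[strain_id]
        for _ in range(int(count)):
            seq = _render_read(layout, rec, cfg, rng, stuffer, sample_index_seq)
            yield f"{read_prefix}:{i:07d}:{strain_id}", seq, strain_id
            i += 1


SCENARIOS = ("hop_basic", "hip_3pct", "dose_series", "platform_panel")


def _write_truth(truth: SimTruth, path: Path) -> None:
    truth.frame().to_csv(path, sep="\t", float_format="%.10g")


def _sheet_frame(samples: list[tuple[str, str, str, int]], assay: str,
                 generations: float) -> SampleSheet:
    rows = [
        {
            "sample_id": sid,
            "condition": cond,
            "role": role,
            "replicate": rep,
            "assay": assay,
            "generations": generations,
        }
        for sid, cond, role, rep in samples
    ]
    return SampleSheet(pd.DataFrame(rows))


def _emit_sample_fastqs(
    out: Path,
    counts: pd.DataFrame,
    catalog: BarcodeCatalog,
    cfg: SimConfig,
    rng: np.random.Generator,
    layout_up: str = "illumina_uptag",
    layout_dn: str = "illumina_downtag",
) -> dict[str, list[dict]]:
    fastq_dir = out / "fastq"
    fastq_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[dict]] = {}
    for sample_id in counts.columns:
        entries = []
        for layout_name in (layout_up, layout_dn):
            layout = preset_layout(layout_name)
            path = fastq_dir / f"{sample_id}_{layout.tag_classes[0]}.fastq.gz"
            reads = (
                (rid, seq)
                for rid, seq, _ in synth_reads(
                    counts[sample_id], catalog, layout, cfg, rng,
                    read_prefix=sample_id,
                )
            )
            write_fastq(path, reads)
            entries.append({"fastq": str(path), "layout": layout_name})
        manifest[sample_id] = entries
    return manifest


def make_fixture(scenario: str, seed: int, out_dir: str | Path) -> dict:
    """Write a complete, self-contained test scenario to disk.

    hop_basic: 1,000-strain homozygous pool, 5 generations, 5% of
    strains affected; three replicates per arm with Illumina-layout
    FASTQs.  hip_3pct: 200-strain heterozygous pool, 20 generations,
    a 40-strain cohort planted at s=0.03 (FD 0.6), 500 reads/tag depth.
    dose_series: four dose-scaled conditions sharing one affected set
    plus one unrelated condition, written as count matrices.
    platform_panel: one count vector rendered through every layout
    preset at zero error rate.

    Returns a dict of the paths written.  Identical (scenario, seed)
    inputs reproduce every file byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    builder = {
        "hop_basic": _fixture_hop_basic,
        "hip_3pct": _fixture_hip_3pct,
        "dose_series": _fixture_dose_series,
        "platform_panel": _fixture_platform_panel,
    }[scenario]
    return builder(seed, out)


def _write_run_config(out: Path, manifest: dict, mode: str = "best_tag") -> Path:
    config = {
        "catalog": str(out / "catalog.tsv"),
        "sample_sheet": str(out / "sheet.tsv"),
        "samples": manifest,
        "match": {"max_dist": 2, "min_margin": 1, "metric": "hamming"},
        "pseudocount": 1.0,
        "combination_mode": mode,
        "output_dir": str(out / "results"),
    }
    path = out / "run.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path


def _fixture_hop_basic(seed: int, out: Path) -> dict:
    cfg = SimConfig(
        n_strains=1000,
        assay="HOP",
        fraction_affected=0.05,
        depth_per_sample=100_000,
        seed=seed,
    )
    rng_cat = np.random.default_rng([seed, 10])
    catalog = make_catalog(cfg, rng_cat)
    truth = simulate_abundances(cfg)
    # align the catalog's uptag-only set with the truth's
    truth.uptag_only = np.array(
        [rec.downtag is None for rec in catalog], dtype=bool
    )
    samples = [(f"T{i}", "drug", "treatment", i) for i in (1, 2, 3)] + [
        (f"C{i}", "control", "control", i) for i in (1, 2, 3)
    ]
    counts = simulate_counts(truth, cfg, [(s[0], s[2]) for s in samples])
    sheet = _sheet_frame(samples, "HOP", cfg.g)
    write_catalog(catalog, out / "catalog.tsv")
    sheet.to_tsv(out / "sheet.tsv")
    _write_truth(truth, out / "truth.tsv")
    counts.to_csv(out / "counts_true.tsv", sep="\t")
    rng_reads = np.random.default_rng([seed, 11])
    manifest = _emit_sample_fastqs(out, counts, catalog, cfg, rng_reads)
    config = _write_run_config(out, manifest)
    return {
        "catalog": out / "catalog.tsv",
        "sheet": out / "sheet.tsv",
        "truth": out / "truth.tsv",
        "counts_true": out / "counts_true.tsv",
        "config": config,
        "cfg": cfg,
    }


def _fixture_hip_3pct(seed: int, out: Path) -> dict:
    n = 200
    cohort = 40
    rng_pick = np.random.default_rng([seed, 20])
    s = np.zeros(n)
    s[rng_pick.choice(n, size=cohort, replace=False)] = 0.03
    cfg = SimConfig(
        n_strains=n,
        assay="HIP",
        fitness_coefficients=tuple(s),
        depth_per_sample=n * 2 * 500,  # 500 reads per tag per strain
        seed=seed,
    )
    catalog = make_catalog(cfg, np.random.default_rng([seed, 21]))
    truth = simulate_abundances(cfg)
    truth.uptag_only = np.array(
        [rec.downtag is None for rec in catalog], dtype=bool
    )
    samples = [(f"T{i}", "drug", "treatment", i) for i in (1, 2, 3)] + [
        (f"C{i}", "control", "control", i) for i in (1, 2, 3)
    ]
    counts = simulate_counts(truth, cfg, [(sid, role) for sid, _, role, _ in samples])
    sheet = _sheet_frame(samples, "HIP", cfg.g)
    write_catalog(catalog, out / "catalog.tsv")
    sheet.to_tsv(out / "sheet.tsv")
    _write_truth(truth, out / "truth.tsv")
    counts.to_csv(out / "counts_true.tsv", sep="\t")
    rng_reads = np.random.default_rng([seed, 22])
    manifest = _emit_sample_fastqs(out, counts, catalog, cfg, rng_reads)
    config = _write_run_config(out, manifest)
    return {
        "catalog": out / "catalog.tsv",
        "sheet": out / "sheet.tsv",
        "truth": out / "truth.tsv",
        "counts_true": out / "counts_true.tsv",
        "config": config,
        "cfg": cfg,
    }


DOSE_SCALES = {"dox_ic10": 0.4, "dox_ic20": 0.6, "dox_ic30": 0.8, "dox_ic40": 1.0}


def _fixture_dose_series(seed: int, out: Path) -> dict:
    """Four dose-scaled profiles sharing one affected cohort, plus one
    unrelated compound; emitted at the count level."""
    n = 300
    base_cfg = SimConfig(
        n_strains=n,
        assay="HOP",
        fraction_affected=0.25,
        affected_s_range=(0.2, 0.8),
        depth_per_sample=n * 2 * 500,
        seed=seed,
    )
    rng_pick = np.random.default_rng([seed, 30])
    affected = rng_pick.choice(n, size=int(0.25 * n), replace=False)
    base_s = np.zeros(n)
    base_s[affected] = rng_pick.uniform(0.2, 0.8, size=affected.size)
    other_s = np.zeros(n)
    other_affected = rng_pick.choice(n, size=int(0.25 * n), replace=False)
    other_s[other_affected] = rng_pick.uniform(0.2, 0.8, size=other_affected.size)

    catalog = make_catalog(base_cfg, np.random.default_rng([seed, 31]))
    up_only = np.array([rec.downtag is None for rec in catalog], dtype=bool)

    frames = []
    truths = {}
    sample_rows = []
    rng_counts = np.random.default_rng([seed, 32])
    conditions = {**{c: ("dox", f) for c, f in DOSE_SCALES.items()},
                  "tigecycline": ("other", 1.0)}
    for ci, (cond, (kind, factor)) in enumerate(conditions.items()):
        s_vec = (base_s if kind == "dox" else other_s) * factor
        cfg = replace(
            base_cfg, fitness_coefficients=tuple(s_vec), seed=seed + 100 + ci
        )
        truth = simulate_abundances(cfg)
        truth.uptag_only = up_only
        truths[cond] = truth
        sample_ids = [(f"{cond}_r{i}", "treatment") for i in (1, 2)]
        frames.append(
            simulate_counts(truth, cfg, sample_ids, rng=rng_counts)
        )
        sample_rows += [
            (sid, cond, "treatment", i + 1) for i, (sid, _) in enumerate(sample_ids)
        ]
    # shared controls drawn from the neutral pool
    ctrl_cfg = replace(base_cfg, fitness_coefficients=tuple(np.zeros(n)))
    ctrl_truth = simulate_abundances(ctrl_cfg)
    ctrl_truth.uptag_only = up_only
    ctrl_samples = [(f"C{i}", "control") for i in (1, 2, 3)]
    frames.append(simulate_counts(ctrl_truth, ctrl_cfg, ctrl_samples, rng=rng_counts))
    sample_rows += [(sid, "control", "control", i + 1)
                    for i, (sid, _) in enumerate(ctrl_samples)]

    counts = pd.concat(frames, axis=1).fillna(0).astype(np.int64)
    sheet = _sheet_frame(sample_rows, "HOP", base_cfg.g)
    write_catalog(catalog, out / "catalog.tsv")
    sheet.to_tsv(out / "sheet.tsv")
    counts.to_csv(out / "counts.tsv", sep="\t")
    truth_frame = pd.DataFrame(
        {f"true_fd_{cond}": t.true_fd for cond, t in truths.items()},
        index=truths[next(iter(truths))].strain_ids,
    )
    truth_frame.index.name = "strain_id"
    truth_frame.to_csv(out / "truth.tsv", sep="\t", float_format="%.10g")
    return {
        "catalog": out / "catalog.tsv",
        "sheet": out / "sheet.tsv",
        "counts": out / "counts.tsv",
        "truth": out / "truth.tsv",
        "series_conditions": list(DOSE_SCALES),
        "other_condition": "tigecycline",
    }


def _fixture_platform_panel(seed: int, out: Path) -> dict:
    """One per-strain count vector rendered through every layout preset
    with zero error rates; quantifying any of them must agree."""
    n = 50
    cfg = SimConfig(
        n_strains=n,
        assay="HOP",
        fraction_affected=0.0,
        depth_per_sample=4000,
        error_rate_substitution=0.0,
        error_rates_indel=(0.0, 0.0),
        fraction_uptag_only=0.0,
        tag_linkage="cis",
        stuffer_len=300,
        seed=seed,
    )
    catalog = make_catalog(cfg, np.random.default_rng([seed, 40]))
    truth = simulate_abundances(cfg)
    rng = np.random.default_rng([seed, 41])
    per_strain = rng.multinomial(cfg.depth_per_sample // 2,
                                 expected_shares(truth, "control", "uptag"))
    index = pd.MultiIndex.from_tuples(
        [(sid, cls) for cls in ("uptag", "downtag") for sid in truth.strain_ids],
        names=["strain_id", "tag_class"],
    )
    counts = pd.Series(
        np.concatenate([per_strain, per_strain]), index=index, name="S1"
    ).sort_index()
    write_catalog(catalog, out / "catalog.tsv")
    counts.to_frame().to_csv(out / "counts_true.tsv", sep="\t")
    index_table = make_index_table(1, np.random.default_rng([seed, 42]))
    fastq_dir = out / "fastq"
    fastq_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    rng_reads = np.random.default_rng([seed, 43])
    for platform in PLATFORMS:
        layout = preset_layout(platform)
        sample_index = index_table[0][0] if platform == "nanopore_long" else None
        path = fastq_dir / f"{platform}.fastq.gz"
        reads = (
            (rid, seq)
            for rid, seq, _ in synth_reads(
                counts, catalog, layout, cfg, rng_reads,
                sample_index_seq=sample_index, read_prefix=platform,
            )
        )
        write_fastq(path, reads)
        paths[platform] = path
    return {
        "catalog": out / "catalog.tsv",
        "counts_true": out / "counts_true.tsv",
        "fastqs": paths,
        "index_table": index_table,
        "cfg": cfg,
    }
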