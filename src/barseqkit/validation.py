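"""Self-validation drivers: seeded end-to-end checks of the toolkit.

Each function simulates a screen under stated study conditions, runs
the relevant part of the pipeline, and measures how well the known
truth is recovered.  They are used by the test suite and by the
repository's acceptance script; all randomness flows from the given
seed.

The matcher check compares the production assigner (exact lookup,
vectorized Hamming scan, pigeonhole-seeded Levenshtein search) against
an independent exhaustive oracle that computes the full query-by-tag
distance matrix directly and applies the assignment rule by hand.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as scistats

import edlib

from .catalog import BarcodeCatalog, BarcodeRecord
from .fitness import (
    SampleSheet,
    combine_tags,
    fd_scores,
    normalize,
    select_best_tag,
)
from .layouts import PLATFORMS, extract_tags, preset_layout
from .matching import Assignment, MatchParams, assign_tag, build_index
from .profiles import coinhibition_matrix, tag_value_table, updn_correlation
from .simulate import (
    SimConfig,
    make_catalog,
    make_fixture,
    simulate_abundances,
    simulate_counts,
    synth_reads,
)

_BASES = "ACGT"

DEFAULT_PARAM_GRID = [
    MatchParams(max_dist=d, min_margin=m, metric=metric)
    for metric in ("hamming", "levenshtein")
    for d in (0, 1, 2, 3)
    for m in (1, 2)
]


def _random_tag(rng: np.random.Generator, length: int = 20) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(seq: str, rng: np.random.Generator, n_sub=0, n_ins=0, n_del=0) -> str:
    s = list(seq)
    for _ in range(n_del):
        if s:
            s.pop(rng.integers(0, len(s)))
    for _ in range(n_ins):
        s.insert(rng.integers(0, len(s) + 1), _BASES[rng.integers(0, 4)])
    for _ in range(n_sub):
        if s:
            p = rng.integers(0, len(s))
            s[p] = _BASES[(_BASES.index(s[p]) + 1 + rng.integers(0, 3)) % 4]
    return "".join(s)


def _query_catalog(rng: np.random.Generator, size: int) -> list[str]:
    """Random tag set where ~25% of tags are near-duplicates of earlier
    ones (1-2 substitutions), so margin and ambiguity rules are hit."""
    tags: list[str] = []
    seen: set[str] = set()
    while len(tags) < size:
        if tags and rng.random() < 0.25:
            cand = _mutate(tags[rng.integers(0, len(tags))], rng,
                           n_sub=int(rng.integers(1, 3)))
        else:
            cand = _random_tag(rng)
        if cand not in seen:
            seen.add(cand)
            tags.append(cand)
    return tags


def _make_queries(tags: list[str], rng: np.random.Generator, n: int) -> list[str]:
    queries = []
    for _ in range(n):
        kind = rng.random()
        base = tags[rng.integers(0, len(tags))]
        if kind < 0.10:
            queries.append(base)  # exact
        elif kind < 0.55:
            queries.append(_mutate(base, rng, n_sub=int(rng.integers(1, 5))))
        elif kind < 0.70:
            queries.append(
                _mutate(base, rng, n_sub=int(rng.integers(0, 2)),
                        n_ins=int(rng.integers(0, 2)),
                        n_del=int(rng.integers(0, 2)))
            )
        else:
            queries.append(_random_tag(rng))
    return queries


def _oracle_distance_table(queries: list[str], tags: list[str], metric: str):
    """Full (query x tag) distance matrix, computed directly.

    Hamming uses a broadcast byte comparison (length-mismatched queries
    get infinite distance); Levenshtein calls edlib per pair with a
    cap of 5 (beyond which no parameter combination in the default grid
    can be affected).
    """
    big = 99
    n_q, n_t = len(queries), len(tags)
    D = np.full((n_q, n_t), big, dtype=np.int64)
    tag_mat = np.frombuffer("".join(tags).encode(), dtype=np.uint8).reshape(n_t, 20)
    if metric == "hamming":
        ok = [i for i, q in enumerate(queries) if len(q) == 20]
        if ok:
            q_mat = np.frombuffer(
                "".join(queries[i] for i in ok).encode(), dtype=np.uint8
            ).reshape(len(ok), 20)
            D[ok, :] = (q_mat[:, None, :] != tag_mat[None, :, :]).sum(axis=2)
    else:
        for qi, q in enumerate(queries):
            row = D[qi]
            for ti, t in enumerate(tags):
                d = edlib.align(q, t, task="distance", k=5)["editDistance"]
                if d >= 0:
                    row[ti] = d
    return D


def _oracle_assignments(
    queries: list[str], tags: list[str], strains: list[str],
    D: np.ndarray, params: MatchParams,
) -> list[Assignment]:
    """Apply the exact/within/no-hit/ambiguous rule to a distance table."""
    out = []
    exact_map = {t: s for t, s in zip(tags, strains)}
    for qi, q in enumerate(queries):
        hit = exact_map.get(q)
        if hit is not None:
            out.append(Assignment(hit, "uptag", 0, "exact"))
            continue
        row = D[qi]
        i1 = int(row.argmin())
        d1 = int(row[i1])
        rest = np.delete(row, i1)
        d2 = int(rest.min()) if rest.size else None
        if d1 > params.max_dist or d1 >= 99:
            out.append(Assignment(None, "uptag", None, "no_hit"))
        elif d2 is not None and d2 - d1 < params.min_margin:
            out.append(Assignment(None, "uptag", d1, "ambiguous"))
        else:
            out.append(Assignment(strains[i1], "uptag", d1, "within_dist"))
    return out


def matcher_agreement(
    seed: int,
    n_catalogs: int = 20,
    n_queries: int = 10_000,
    catalog_sizes: tuple[int, ...] = (100, 200, 300, 400, 500),
    param_grid: list[MatchParams] | None = None,
) -> dict:
    """Compare assign_tag with the exhaustive oracle over random catalogs.

    Returns the number of (catalog, query, params) comparisons made and
    how many disagreed (an agreeing matcher reports 0).
    """
    if param_grid is None:
        param_grid = DEFAULT_PARAM_GRID
    rng = np.random.default_rng([seed, 101])
    compared = disagreed = 0
    for ci in range(n_catalogs):
        size = catalog_sizes[ci % len(catalog_sizes)]
        tags = _query_catalog(rng, size)
        strains = [f"S{i:05d}" for i in range(size)]
        catalog = BarcodeCatalog(
            [BarcodeRecord(s, uptag=t) for s, t in zip(strains, tags)]
        )
        index = build_index(catalog)
        queries = _make_queries(tags, rng, n_queries)
        for metric in ("hamming", "levenshtein"):
            D = _oracle_distance_table(queries, tags, metric)
            for params in [p for p in param_grid if p.metric == metric]:
                expected = _oracle_assignments(queries, tags, strains, D, params)
                for q, exp in zip(queries, expected):
                    got = assign_tag(q, "uptag", index, params)
                    compared += 1
                    if (got.reason, got.strain_id, got.distance) != (
                        exp.reason, exp.strain_id, exp.distance
                    ):
                        disagreed += 1
    return {
        "n_compared": compared,
        "n_disagreements": disagreed,
        "agreement": 1.0 - disagreed / compared,
    }


def _default_sheet(assay: str, generations: float) -> SampleSheet:
    rows = [
        {"sample_id": s, "condition": c, "role": r, "replicate": i,
         "assay": assay, "generations": generations}
        for s, c, r, i in [
            ("T1", "drug", "treatment", 1), ("T2", "drug", "treatment", 2),
            ("T3", "drug", "treatment", 3), ("C1", "ctrl", "control", 1),
            ("C2", "ctrl", "control", 2), ("C3", "ctrl", "control", 3),
        ]
    ]
    return SampleSheet(pd.DataFrame(rows))


_SIX_SAMPLES = [("T1", "treatment"), ("T2", "treatment"), ("T3", "treatment"),
                ("C1", "control"), ("C2", "control"), ("C3", "control")]


def roundtrip_accuracy(
    seed: int,
    n_strains: int = 1000,
    reads_per_preset: int = 2000,
    noisy_reads: int = 10_000,
    nanopore_reads: int = 2000,
) -> dict:
    """Extraction + assignment accuracy per layout preset.

    Zero-error reads must recover every planted tag; with 1%
    substitutions short reads are matched at Hamming <= 2, and with
    0.5%/0.5% indels long Nanopore reads at edit distance <= 3, on a
    catalog with minimum within-class pairwise Hamming distance 5.
    """
    base = SimConfig(
        n_strains=n_strains, depth_per_sample=max(reads_per_preset, 2),
        error_rate_substitution=0.0, error_rates_indel=(0.0, 0.0),
        fraction_uptag_only=0.0, tag_linkage="cis", stuffer_len=300, seed=seed,
    )
    rng = np.random.default_rng([seed, 201])
    catalog = make_catalog(base, rng, min_hamming=5)
    index = build_index(catalog)
    truth = simulate_abundances(base)

    def _run(cfg, layout_name, n_reads, params):
        layout = preset_layout(layout_name)
        counts = simulate_counts(
            truth, cfg, [("S", "control")],
            rng=np.random.default_rng([seed, 202]),
        )["S"]
        # rescale the sample to the requested number of reads
        cls = layout.tag_classes[0]
        sub = counts.xs(cls, level="tag_class")
        shares = sub / sub.sum()
        draw = np.random.default_rng([seed, 203]).multinomial(n_reads, shares)
        col = pd.Series(
            draw,
            index=pd.MultiIndex.from_product(
                [shares.index, [cls]], names=["strain_id", "tag_class"]
            ),
        )
        correct = total = 0
        reads_rng = np.random.default_rng([seed, 204])
        for rid, seq, strain in synth_reads(
            col, catalog, layout, cfg, reads_rng,
            sample_index_seq="ACGTACGTAC" if layout_name == "nanopore_long" else None,
        ):
            total += 1
            observations = extract_tags((rid, seq), layout)
            good = bool(observations)
            for obs in observations:
                a = assign_tag(obs.observed_seq, obs.tag_class, index, params)
                if not (a.assigned and a.strain_id == strain):
                    good = False
            if good:
                correct += 1
        return correct / total

    out = {}
    short_params = MatchParams(max_dist=2, min_margin=1, metric="hamming")
    long_params = MatchParams(max_dist=3, min_margin=1, metric="levenshtein")
    for platform in PLATFORMS:
        layout = preset_layout(platform)
        params = long_params if layout.error_model == "with_indels" else short_params
        out[f"zero_error_{platform}"] = _run(base, platform, reads_per_preset, params)
    # 1% substitutions on the short-read presets
    noisy_cfg = replace(base, error_rate_substitution=0.01)
    sub_acc = [
        _run(noisy_cfg, p, noisy_reads // 6, short_params)
        for p in PLATFORMS
        if preset_layout(p).error_model == "substitution_only"
    ]
    out["substitution_1pct_accuracy"] = float(np.mean(sub_acc))
    # 0.5%/0.5% indels on the long Nanopore preset
    indel_cfg = replace(base, error_rates_indel=(0.005, 0.005))
    out["nanopore_indel_accuracy"] = _run(
        indel_cfg, "nanopore_long", nanopore_reads, long_params
    )
    return out


def fd_recovery(seed: int, n_strains: int = 1000, reads_per_tag: int = 500) -> dict:
    """Parameter recovery on a homozygous-pool screen.

    1,000 strains, 5 generations, 5% affected, three replicates per
    arm at 500 reads/tag/sample; best-tag combined FD vs planted FD.
    """
    cfg = SimConfig(
        n_strains=n_strains, assay="HOP", fraction_affected=0.05,
        depth_per_sample=n_strains * 2 * reads_per_tag, seed=seed,
    )
    truth = simulate_abundances(cfg)
    counts = simulate_counts(truth, cfg, _SIX_SAMPLES)
    sheet = _default_sheet("HOP", cfg.g)
    norm = normalize(counts, 1.0)
    best = select_best_tag(norm, sheet, assay="HOP")
    profile = combine_tags(
        fd_scores(norm, sheet, "drug"), mode="best_tag", best=best
    )
    true_fd = pd.Series(truth.true_fd, index=truth.strain_ids)
    joined = pd.concat([true_fd, profile.combined], axis=1).dropna()
    r = scistats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic
    slope = scistats.linregress(joined.iloc[:, 0], joined.iloc[:, 1]).slope
    return {"pearson_r": float(r), "slope": float(slope), "n": len(joined)}


def hip_detectability(seed: int, n_strains: int = 200, cohort: int = 40) -> dict:
    """Detecting a 3% fitness defect after 20 generations (planted FD 0.6).

    Returns the affected cohort's mean estimated FD and its separation
    from the neutral cohort in robust z-units (median/MAD based).
    """
    rng = np.random.default_rng([seed, 301])
    s = np.zeros(n_strains)
    s[rng.choice(n_strains, size=cohort, replace=False)] = 0.03
    cfg = SimConfig(
        n_strains=n_strains, assay="HIP", fitness_coefficients=tuple(s),
        depth_per_sample=n_strains * 2 * 500, seed=seed,
    )
    truth = simulate_abundances(cfg)
    counts = simulate_counts(truth, cfg, _SIX_SAMPLES)
    sheet = _default_sheet("HIP", cfg.g)
    norm = normalize(counts, 1.0)
    best = select_best_tag(norm, sheet, assay="HIP")
    profile = combine_tags(
        fd_scores(norm, sheet, "drug"), mode="best_tag", best=best
    )
    est = profile.combined
    affected = pd.Series(truth.s, index=truth.strain_ids) > 0
    neutral = est[~affected].dropna()
    mad = 1.4826 * float(np.median(np.abs(neutral - neutral.median())))
    z = (est[affected].mean() - neutral.median()) / mad
    return {
        "cohort_mean_fd": float(est[affected].mean()),
        "neutral_median_fd": float(neutral.median()),
        "robust_z": float(z),
    }


def cis_trans_concordance(seed: int, n_seeds: int = 20, n_strains: int = 500) -> dict:
    """Uptag-downtag concordance: cis linkage vs trans, matched seeds.

    With tag efficiency sigma 0.3, the cis (long-read, both tags on one
    molecule) correlation should exceed the trans (separate PCRs)
    correlation in nearly every replicate.
    """
    wins = 0
    pairs = []
    for i in range(n_seeds):
        rep_seed = seed * 1000 + i
        r = {}
        for linkage in ("cis", "trans"):
            cfg = SimConfig(
                n_strains=n_strains, tag_efficiency_sigma=0.3,
                tag_linkage=linkage, depth_per_sample=200_000,
                seed=rep_seed,
            )
            truth = simulate_abundances(cfg)
            counts = simulate_counts(
                truth, cfg, [("C1", "control"), ("C2", "control")]
            )
            norm = normalize(counts, 1.0)
            table = tag_value_table(norm.values, ["C1", "C2"])
            r[linkage] = updn_correlation(table)
        wins += r["cis"] > r["trans"]
        pairs.append(r)
    return {
        "cis_wins": wins,
        "n_seeds": n_seeds,
        "median_cis_r": float(np.median([p["cis"] for p in pairs])),
        "median_trans_r": float(np.median([p["trans"] for p in pairs])),
    }


def dose_series_margins(seed: int, workdir) -> dict:
    """Coinhibition structure of the dose-series scenario.

    Every within-series correlation (dose pairs of the same compound)
    should exceed every cross-series correlation (any dose vs the
    unrelated compound).
    """
    fixture = make_fixture("dose_series", seed, workdir)
    counts = pd.read_csv(fixture["counts"], sep="\t", index_col=[0, 1])
    sheet = SampleSheet.from_tsv(fixture["sheet"])
    norm = normalize(counts, 1.0)
    best = select_best_tag(norm, sheet, assay="HOP")
    profiles = {
        cond: combine_tags(
            fd_scores(norm, sheet, cond), mode="best_tag", best=best
        ).combined
        for cond in sheet.treatment_conditions()
    }
    matrix = coinhibition_matrix(profiles)
    series = fixture["series_conditions"]
    other = fixture["other_condition"]
    within = [
        matrix.loc[a, b] for i, a in enumerate(series) for b in series[i + 1:]
    ]
    cross = [matrix.loc[a, other] for a in series]
    return {
        "within_min": float(min(within)),
        "within_max": float(max(within)),
        "cross_max": float(max(cross)),
        "ordered": bool(min(within) > max(cross)),
    }
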