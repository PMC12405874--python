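"""Profile-level analyses: cross-profile and tag-concordance correlations.

A chemogenomic profile is the vector of per-strain FD scores for one
condition.  Profiles from replicate platforms or related doses of the
same compound correlate strongly; unrelated compounds do not.  The
"coinhibition" of two profiles is summarized here as the Pearson
correlation of their FD vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitness import FitnessProfile


def _as_series(profile) -> pd.Series:
    if isinstance(profile, FitnessProfile):
        return profile.combined
    return pd.Series(profile)


@dataclass
class ProfileSet:
    """Labelled FD profiles over a shared strain universe."""

    profiles: dict[str, pd.Series]

    @classmethod
    def from_profiles(cls, profiles: dict) -> "ProfileSet":
        return cls({label: _as_series(p) for label, p in profiles.items()})


def profile_correlation(a, b) -> tuple[float, int]:
    """Pearson r between two FD profiles over shared defined strains.

    Returns (r, n_used).  Requires at least 3 strains defined in both.
    """
    sa, sb = _as_series(a), _as_series(b)
    joined = pd.concat([sa, sb], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"only {n} shared defined strains; need >= 3")
    r = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic
    return float(r), n


def topk_correlation(a, b, k: int = 50) -> tuple[float, list[str]]:
    """Pearson r over the k most sensitive plus k most resistant strains.

    Selection ranks the FIRST profile's FD; ties at the rank-k boundary
    are broken by strain id.  Returns (r, selected strain ids).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sa, sb = _as_series(a), _as_series(b)
    shared = pd.concat([sa, sb], axis=1, join="inner").dropna()
    if len(shared) < 2 * k:
        raise ValueError(
            f"{len(shared)} shared defined strains; need >= {2 * k} for k={k}"
        )
    ref = shared.iloc[:, 0]
    # deterministic tie-break on strain id: sort by id first, then stably by FD
    ordered = ref.sort_index().sort_values(ascending=False, kind="mergesort")
    top = list(ordered.index[:k])
    bottom = list(ordered.index[-k:])
    selected = top + bottom
    sub = shared.loc[selected]
    r = stats.pearsonr(sub.iloc[:, 0], sub.iloc[:, 1]).statistic
    return float(r), selected


def updn_correlation(per_tag: pd.DataFrame, level: str = "counts") -> float:
    """Concordance between a strain's two tags across the pool.

    ``per_tag`` is indexed by strain with columns ``uptag`` and
    ``downtag`` holding replicate-averaged values: normalized counts
    (``level='counts'``, log2-transformed here before correlating, so
    abundance outliers do not dominate) or FD scores (``level='fd'``,
    used as-is).  Strains lacking either tag are excluded.
    """
    if level not in {"counts", "fd"}:
        raise ValueError(f"unknown level {level!r}")
    both = per_tag[["uptag", "downtag"]].dropna()
    if len(both) < 3:
        raise ValueError("need >= 3 dual-tag strains")
    x, y = both["uptag"], both["downtag"]
    if level == "counts":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("count-level concordance needs positive values")
        x, y = np.log2(x), np.log2(y)
    return float(stats.pearsonr(x, y).statistic)


def tag_value_table(norm_values: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Replicate-averaged per-tag values, one row per strain.

    Averages the given sample columns of a normalized matrix (indexed by
    (strain_id, tag_class)) and pivots tag classes to columns, ready for
    :func:`updn_correlation`.
    """
    mean = norm_values[samples].mean(axis=1)
    wide = mean.unstack("tag_class")
    return wide.reindex(columns=["uptag", "downtag"])


def coinhibition_matrix(profile_set: ProfileSet | dict) -> pd.DataFrame:
    """All-pairs Pearson correlation of FD profiles.

    Symmetric with unit diagonal; pairs with fewer than 3 shared defined
    strains are left as NaN.
    """
    if isinstance(profile_set, dict):
        profile_set = ProfileSet.from_profiles(profile_set)
    labels = list(profile_set.profiles)
    if len(labels) < 2:
        raise ValueError("need at least 2 profiles")
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            try:
                r, _ = profile_correlation(
                    profile_set.profiles[la], profile_set.profiles[lb]
                )
            except ValueError:
                r = np.nan
            mat.loc[la, lb] = r
            mat.loc[lb, la] = r
    return mat


def plot_heatmap(matrix: pd.DataFrame, path) -> None:
    """Write a correlation heatmap (PNG/SVG chosen by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(matrix), 1 + 0.5 * len(matrix)))
    im = ax.imshow(matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_scatter(a, b, path, labels=("profile A", "profile B"), n_label: int = 5):
    """FD-vs-FD scatter of two profiles, labelling the top/bottom strains."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sa, sb = _as_series(a), _as_series(b)
    joined = pd.concat([sa, sb], axis=1, join="inner").dropna()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(joined.iloc[:, 0], joined.iloc[:, 1], s=8, alpha=0.5)
    ranked = joined.iloc[:, 0].sort_values()
    for sid in list(ranked.index[:n_label]) + list(ranked.index[-n_label:]):
        ax.annotate(str(sid), (joined.iloc[:, 0][sid], joined.iloc[:, 1][sid]),
                    fontsize=7)
    ax.set_xlabel(f"FD ({labels[0]})")
    ax.set_ylabel(f"FD ({labels[1]})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
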