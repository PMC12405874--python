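"""Fitness-defect (FD) scoring for pooled deletion-strain screens.

Raw tag counts are depth-normalized to reads-per-million within each
sample (plus a pseudocount), replicates are averaged, and the FD of a
strain's tag is the log2 ratio of its control mean to its treatment
mean: positive FD = depleted under treatment = drug-sensitive, negative
FD = resistant.  The two tags of a strain are combined by one of three
strategies: per-strain *best tag* (the tag with the lowest robust
coefficient of variation across control samples), the *mean* of the two
per-tag FDs, or FD recomputed from per-strain *summed* raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ASSAYS = ("HIP", "HOP")
DEFAULT_GENERATIONS = {"HIP": 20.0, "HOP": 5.0}

SHEET_COLUMNS = ["sample_id", "condition", "role", "replicate", "assay", "generations"]


@dataclass
class SampleSheet:
    """Sample annotations: condition, treatment/control role, replicate,
    assay (HIP: heterozygous essential pool, 20 generations; HOP:
    homozygous pool, 5 generations)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SHEET_COLUMNS[:5]) - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns {sorted(missing)}")
        if "generations" not in self.table.columns:
            self.table = self.table.assign(
                generations=self.table["assay"].map(DEFAULT_GENERATIONS)
            )
        bad_roles = set(self.table["role"]) - {"treatment", "control"}
        if bad_roles:
            raise ValueError(f"unknown roles {sorted(bad_roles)}")
        bad_assays = set(self.table["assay"]) - set(ASSAYS)
        if bad_assays:
            raise ValueError(f"unknown assays {sorted(bad_assays)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sheet")
        for cond, grp in self.table[self.table["role"] == "treatment"].groupby(
            "condition"
        ):
            assay = grp["assay"].iloc[0]
            ctrl = self.table[
                (self.table["role"] == "control") & (self.table["assay"] == assay)
            ]
            if ctrl.empty:
                raise ValueError(
                    f"treatment condition {cond!r} has no matched {assay} control"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        sep = "," if str(path).endswith(".csv") else "\t"
        return cls(pd.read_csv(path, sep=sep))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def samples(self, *, condition=None, role=None, assay=None) -> list[str]:
        t = self.table
        if condition is not None:
            t = t[t["condition"] == condition]
        if role is not None:
            t = t[t["role"] == role]
        if assay is not None:
            t = t[t["assay"] == assay]
        return list(t["sample_id"])

    def assay_of_condition(self, condition: str) -> str:
        rows = self.table[self.table["condition"] == condition]
        if rows.empty:
            raise KeyError(f"condition {condition!r} not in sample sheet")
        assays = set(rows["assay"])
        if len(assays) > 1:
            raise ValueError(f"condition {condition!r} spans assays {sorted(assays)}")
        return assays.pop()

    def controls_for(self, condition: str) -> list[str]:
        return self.samples(role="control", assay=self.assay_of_condition(condition))

    def treatment_conditions(self) -> list[str]:
        t = self.table[self.table["role"] == "treatment"]
        return list(dict.fromkeys(t["condition"]))


@dataclass
class NormalizedMatrix:
    """Reads-per-million scaled counts (same shape as the raw matrix)."""

    values: pd.DataFrame
    pseudocount: float


@dataclass
class FitnessProfile:
    """Per-strain FD scores for one condition."""

    condition: str
    fd: pd.DataFrame  # columns fd_uptag, fd_downtag and (later) fd_combined
    combination_mode: str | None = None
    n_replicates: int = 0

    @property
    def combined(self) -> pd.Series:
        if "fd_combined" not in self.fd.columns:
            raise ValueError("profile has no combined FD yet; run combine_tags")
        return self.fd["fd_combined"]


def normalize(counts: pd.DataFrame, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Scale each sample column to reads-per-million, then add a pseudocount.

    value = count / column_total * 1e6 + pseudocount.  The denominator is
    the column's assigned-read total (the sum of its counts).  Raises on
    zero-depth columns.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    totals = counts.sum(axis=0)
    dead = totals[totals <= 0]
    if not dead.empty:
        raise ValueError(f"zero-depth column(s): {list(dead.index)}")
    values = counts.div(totals, axis=1) * 1e6 + pseudocount
    return NormalizedMatrix(values=values, pseudocount=pseudocount)


def fd_scores(
    norm: NormalizedMatrix,
    sheet: SampleSheet,
    condition: str,
    replicate_mode: str = "mean_then_log",
) -> FitnessProfile:
    """Per-tag FD scores for one treatment condition vs matched controls.

    FD = log2(mean over control replicates) - log2(mean over treatment
    replicates), on the normalized scale (``mean_then_log``, the
    default: one log-ratio per condition).  ``log_then_mean`` instead
    averages per-replicate-pair log ratios, pairing each treatment
    column with the control mean.
    """
    trt = sheet.samples(condition=condition, role="treatment")
    if not trt:
        raise KeyError(f"condition {condition!r} has no treatment samples")
    ctrl = sheet.controls_for(condition)
    v = norm.values
    if replicate_mode == "mean_then_log":
        fd_tag = np.log2(v[ctrl].mean(axis=1)) - np.log2(v[trt].mean(axis=1))
    elif replicate_mode == "log_then_mean":
        ctrl_mean = np.log2(v[ctrl].mean(axis=1))
        fd_tag = pd.concat(
            [ctrl_mean - np.log2(v[t]) for t in trt], axis=1
        ).mean(axis=1)
    else:
        raise ValueError(f"unknown replicate_mode {replicate_mode!r}")
    wide = fd_tag.unstack("tag_class")
    fd = pd.DataFrame(index=wide.index)
    fd["fd_uptag"] = wide.get("uptag")
    fd["fd_downtag"] = wide.get("downtag")
    return FitnessProfile(condition=condition, fd=fd, n_replicates=len(trt))


def robust_cv(values) -> float:
    """Robust coefficient of variation: 1.4826 * MAD / median.

    The 1.4826 factor makes the median absolute deviation consistent
    with the standard deviation under normality.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("robust_cv needs at least 2 values")
    med = float(np.median(arr))
    if med <= 0:
        raise ValueError("robust_cv requires a positive median")
    mad = float(np.median(np.abs(arr - med)))
    return 1.4826 * mad / med


def select_best_tag(
    norm: NormalizedMatrix, sheet: SampleSheet, assay: str | None = None
) -> pd.DataFrame:
    """Choose each strain's steadier tag across control samples.

    For every strain and tag the robust CV is computed over the control
    columns (of the given assay when specified); the tag with the lower
    robust CV wins, ties go to the uptag, and single-tag strains keep
    their only tag.  Returns a frame indexed by strain with columns
    chosen_class, rcv_uptag, rcv_downtag.
    """
    ctrl = sheet.samples(role="control", assay=assay)
    if len(ctrl) < 2:
        raise ValueError("best-tag selection needs at least 2 control samples")
    v = norm.values[ctrl]

    def _rcv_or_nan(row) -> float:
        try:
            return robust_cv(row.to_numpy())
        except ValueError:  # all-zero control counts at pseudocount 0
            return np.nan

    rcv = v.apply(_rcv_or_nan, axis=1)
    wide = rcv.unstack("tag_class")
    out = pd.DataFrame(index=wide.index)
    out["rcv_uptag"] = wide.get("uptag")
    out["rcv_downtag"] = wide.get("downtag")

    def choose(row) -> str:
        up, dn = row["rcv_uptag"], row["rcv_downtag"]
        if pd.isna(dn):
            return "uptag"
        if pd.isna(up):
            return "downtag"
        return "uptag" if up <= dn else "downtag"  # tie-break: uptag

    out["chosen_class"] = out.apply(choose, axis=1)
    return out


def combine_tags(
    profile: FitnessProfile,
    mode: str = "best_tag",
    best: pd.DataFrame | None = None,
    counts: pd.DataFrame | None = None,
    sheet: SampleSheet | None = None,
    pseudocount: float = 1.0,
    replicate_mode: str = "mean_then_log",
) -> FitnessProfile:
    """Fill ``fd_combined`` using one of the three strategies.

    best_tag: copy the chosen tag's FD (requires ``best`` from
    :func:`select_best_tag`).  mean: average the per-tag FDs
    (single-tag strains pass through).  sum: collapse the raw uptag and
    downtag counts per strain first, then renormalize and rescore
    (requires ``counts`` and ``sheet``).
    """
    fd = profile.fd.copy()
    if mode == "best_tag":
        if best is None:
            raise ValueError("mode='best_tag' requires a best-tag table")
        chosen = best["chosen_class"].reindex(fd.index)
        combined = fd["fd_uptag"].where(chosen == "uptag", fd["fd_downtag"])
        # strains absent from the best table fall back to their only tag
        combined = combined.fillna(fd["fd_uptag"]).fillna(fd["fd_downtag"])
    elif mode == "mean":
        combined = fd[["fd_uptag", "fd_downtag"]].mean(axis=1)
    elif mode == "sum":
        if counts is None or sheet is None:
            raise ValueError("mode='sum' requires raw counts and the sample sheet")
        summed = counts.groupby(level="strain_id").sum()
        summed.index = pd.MultiIndex.from_product(
            [summed.index, ["uptag"]], names=["strain_id", "tag_class"]
        )
        norm_sum = normalize(summed, pseudocount)
        prof = fd_scores(norm_sum, sheet, profile.condition, replicate_mode)
        combined = prof.fd["fd_uptag"].reindex(fd.index)
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    fd["fd_combined"] = combined
    return FitnessProfile(
        condition=profile.condition,
        fd=fd,
        combination_mode=mode,
        n_replicates=profile.n_replicates,
    )


def write_fd_table(
    profile: FitnessProfile, path: str | Path, best: pd.DataFrame | None = None
) -> None:
    out = profile.fd.copy()
    if best is not None:
        out["chosen_tag"] = best["chosen_class"].reindex(out.index)
    out.to_csv(path, sep="\t", index_label="strain_id", float_format="%.6g")
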