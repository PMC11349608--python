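"""Group-level statistics: tumor-vs-normal comparisons, clinical
correlations, and J-family clustering of usage matrices.

Group differences use the two-sided Mann-Whitney U test: exact p by full
enumeration when the combined sample size is at most 12 and there are no
ties, otherwise the normal approximation with tie and continuity
corrections (the study's group sizes, 13 vs 9, fall in the approximation
regime).  Usage comparisons report one test per gene/family/pair over the
full reference space, with both raw p and Benjamini-Hochberg adjusted p:
the "significant set" mirrors the raw p < 0.05 convention of the study
design, and the output metadata flags that no multiplicity correction
backs it.  Clinical correlations use the Spearman rank test with the
t-approximation p-value, computed separately per tissue group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .annotate import Repertoire
from .germline import Reference, collapse_families, family_of
from .stats import diversity_profile, vj_usage

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "JClusterResult",
    "mann_whitney_u",
    "spearman",
    "compare_diversity",
    "compare_usage",
    "correlate_clinical",
    "cluster_j_families",
    "EXACT_MAX_N",
    "USAGE_LEVELS",
]

EXACT_MAX_N = 12
USAGE_LEVELS = ("v_family", "v_subfamily", "j", "vj_pair")

DIVERSITY_METRICS = (
    "shannon_entropy",
    "clonality",
    "simpson",
    "cf100",
    "d50",
    "n_clonotypes",
    "n_v_segments",
    "n_vj_pairs",
    "n_vdj_combos",
    "mean_cdr3_len",
)


@dataclass(frozen=True)
class GroupComparisonResult:
    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_statistic: float
    p_value: float
    p_adjusted: float | None = None
    method: str = ""

    def as_row(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def mann_whitney_u(x: Sequence[float], y: Sequence[float], metric: str = "") -> GroupComparisonResult:
    """Two-sided Mann-Whitney U with the exact/approximate switch described above."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if x.size + y.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        if np.ptp(combined) == 0:
            # all observations identical: U at its null mean, no evidence
            return GroupComparisonResult(
                metric, float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0,
                float(y.mean()), float(y.std(ddof=1)) if y.size > 1 else 0.0,
                x.size * y.size / 2.0, 1.0, None, "degenerate",
            )
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupComparisonResult(
        metric=metric,
        mean_a=float(x.mean()),
        sd_a=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        mean_b=float(y.mean()),
        sd_b=float(y.std(ddof=1)) if y.size > 1 else 0.0,
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (midranks) with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant input")
    res = sps.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def _group_split(cohort: Sequence[Repertoire]) -> tuple[list[Repertoire], list[Repertoire]]:
    tumor = [r for r in cohort if r.group == "tumor"]
    normal = [r for r in cohort if r.group == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("each group needs at least 2 samples")
    return tumor, normal


def compare_diversity(cohort: Sequence[Repertoire], metric: str) -> GroupComparisonResult:
    """Mann-Whitney comparison of one diversity metric, tumor vs normal."""
    if metric not in DIVERSITY_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {DIVERSITY_METRICS}")
    tumor, normal = _group_split(cohort)
    xs = [getattr(diversity_profile(r), metric) for r in tumor]
    ys = [getattr(diversity_profile(r), metric) for r in normal]
    return mann_whitney_u(xs, ys, metric=metric)


def _usage_features(rep: Repertoire, ref: Reference, level: str) -> pd.Series:
    usage = vj_usage(rep, ref)
    if level == "v_subfamily":
        return usage.v_usage
    if level == "v_family":
        return usage.v_family_usage
    if level == "j":
        return usage.j_usage
    if level == "vj_pair":
        long = usage.long_format()
        return pd.Series(
            long["frequency"].to_numpy(),
            index=long["v_call"] + "|" + long["j_call"],
        )
    raise ValueError(f"unknown level {level!r}; choose from {USAGE_LEVELS}")


def compare_usage(cohort: Sequence[Repertoire], ref: Reference, level: str) -> pd.DataFrame:
    """Per-feature Mann-Whitney tests of usage frequencies, tumor vs normal.

    Returns one row per gene/family/pair in the reference space with group
    means/SDs, U, raw p, BH-adjusted p, and a raw p < 0.05 significance
    flag.  The frame's ``attrs['note']`` records that the flag follows the
    uncorrected convention.
    """
    tumor, normal = _group_split(cohort)
    feats_t = pd.DataFrame([_usage_features(r, ref, level) for r in tumor])
    feats_n = pd.DataFrame([_usage_features(r, ref, level) for r in normal])
    rows = []
    for feature in feats_t.columns:
        res = mann_whitney_u(feats_t[feature].to_numpy(), feats_n[feature].to_numpy(), feature)
        rows.append(res.as_row())
    table = pd.DataFrame(rows).rename(columns={"metric": "feature"})
    table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["significant_raw"] = table["p_value"] < 0.05
    table.attrs["note"] = (
        "significant_raw uses uncorrected p < 0.05; "
        "p_adjusted is Benjamini-Hochberg across the feature family"
    )
    return table


def correlate_clinical(
    cohort: Sequence[Repertoire], metric: str, covariate: str
) -> dict[str, CorrelationResult]:
    """Spearman correlation of a per-sample diversity metric with a clinical
    covariate, computed separately per group."""
    if metric not in DIVERSITY_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    out = {}
    for group in ("tumor", "normal"):
        reps = [r for r in cohort if r.group == group]
        missing = [r.sample_id for r in reps if covariate not in r.clinical]
        if missing:
            raise ValueError(f"covariate {covariate!r} missing for samples: {missing}")
        if len(reps) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 samples with {covariate!r}")
        xs = [getattr(diversity_profile(r), metric) for r in reps]
        ys = [r.clinical[covariate] for r in reps]
        out[group] = spearman(xs, ys)
    return out


@dataclass
class JClusterResult:
    """Agglomerative clustering of the 14 J usage columns."""

    j_order: list[str]  # dendrogram leaf order
    linkage: np.ndarray  # scipy linkage matrix (merge list)
    clusters: dict[int, list[str]]  # the two top-level clusters
    newick: str


def cluster_j_families(mean_usage: pd.DataFrame) -> JClusterResult:
    """Cluster J columns of a group-mean V x J matrix.

    Euclidean distance on column vectors, average linkage; scipy's
    deterministic ordering (ties resolved by observation index) fixes the
    result.  The two top-level clusters come from cutting the last merge.
    """
    j_ids = list(mean_usage.columns)
    X = mean_usage.to_numpy().T  # one row per J column
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    leaves = hierarchy.leaves_list(Z)
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    clusters: dict[int, list[str]] = {}
    for j, lab in zip(j_ids, labels):
        clusters.setdefault(int(lab), []).append(j)
    tree = hierarchy.to_tree(Z)

    def _newick(node) -> str:
        if node.is_leaf():
            return j_ids[node.id]
        left, right = _newick(node.get_left()), _newick(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return JClusterResult([j_ids[i] for i in leaves], Z, clusters, _newick(tree) + ";")


def group_mean_usage(cohort: Sequence[Repertoire], ref: Reference, group: str) -> pd.DataFrame:
    """Mean V x J usage matrix over a group's samples."""
    reps = [r for r in cohort if r.group == group]
    if not reps:
        raise ValueError(f"no samples in group {group!r}")
    mats = [vj_usage(r, ref).freqs for r in reps]
    return sum(mats[1:], start=mats[0].copy()) / len(mats)
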