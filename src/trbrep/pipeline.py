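"""Per-sample and cohort orchestration: FASTQ -> QC -> annotation -> AIRR
TSV -> statistics -> group reports, with machine-readable stage logs.

``run_sample`` writes, per sample: the AIRR clonotype table, a QC report,
the diversity-profile row, V x J usage matrices (wide and long form), and
a JSON log of record counts at every stage.  ``run_cohort`` aggregates
per-sample outputs into the report-table set: diversity comparisons, usage
comparisons at family/subfamily/J/pair level, group-mean V-J matrices with
J clustering (Newick dendrogram), clinical correlations, and the
frequency-region comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import Repertoire, annotate_reads, build_repertoire
from .compare import (
    USAGE_LEVELS,
    cluster_j_families,
    compare_diversity,
    compare_usage,
    correlate_clinical,
    group_mean_usage,
    mann_whitney_u,
)
from .germline import Reference, load_bundled_reference, load_reference
from .io import QcParams, qc_filter, read_airr, read_fastq, write_airr
from .stats import (
    DEFAULT_REGION_EDGES,
    diversity_profile,
    frequency_regions,
    vj_usage,
)

__all__ = ["RunConfig", "run_sample", "run_cohort", "cohort_report", "repertoire_from_airr"]

REPORT_METRICS = (
    "shannon_entropy",
    "clonality",
    "simpson",
    "cf100",
    "d50",
    "n_clonotypes",
    "mean_cdr3_len",
)
CLINICAL_COVARIATES = ("LDH", "NLR", "ALC")


@dataclass
class RunConfig:
    reference_fasta: str | Path | None = None  # None -> bundled reference
    reference_anchors: str | Path | None = None
    qc: QcParams = field(default_factory=QcParams)
    min_score: int = 10
    region_edges: tuple[float, ...] = DEFAULT_REGION_EDGES
    length_weighting: str = "by_clonotype"
    alpha: float = 0.05
    adjust_method: str = "fdr_bh"
    out_dir: str | Path = "trbrep_out"
    seed: int = 0

    def load_reference(self) -> Reference:
        if self.reference_fasta is None:
            return load_bundled_reference()
        if self.reference_anchors is None:
            raise ValueError("reference_fasta given without reference_anchors")
        for p in (self.reference_fasta, self.reference_anchors):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return load_reference(self.reference_fasta, self.reference_anchors)


def run_sample(
    config: RunConfig,
    fastq: str | Path,
    sample_id: str,
    group: str | None = None,
    clinical: dict[str, float] | None = None,
) -> tuple[Repertoire, str]:
    """Run one sample end to end; returns (repertoire, status).

    Status is "ok", or "warning" when no productive clonotypes remain.
    Outputs land in ``config.out_dir / sample_id``.
    """
    ref = config.load_reference()
    out = Path(config.out_dir) / sample_id
    out.mkdir(parents=True, exist_ok=True)

    reads = list(read_fastq(fastq))
    kept, qc_report = qc_filter(reads, config.qc)
    annotations, n_no_call = annotate_reads(kept, ref, config.min_score)
    rep = build_repertoire(annotations, sample_id, group, clinical)

    table = pd.DataFrame(
        {
            "sequence_id": [f"{sample_id}_c{i:05d}" for i in range(rep.n_clonotypes)],
            "v_call": rep.clonotypes.get("v_call", pd.Series(dtype=str)),
            "d_call": rep.clonotypes.get("d_call", pd.Series(dtype=str)),
            "j_call": rep.clonotypes.get("j_call", pd.Series(dtype=str)),
            "junction": "",
            "junction_aa": rep.clonotypes.get("cdr3_aa", pd.Series(dtype=str)),
            "productive": True,
            "duplicate_count": rep.clonotypes.get("count", pd.Series(dtype=int)),
            "frequency": rep.clonotypes.get("frequency", pd.Series(dtype=float)),
        }
    )
    write_airr(table, out / "clonotypes.airr.tsv")

    log = {
        "sample_id": sample_id,
        "n_raw_reads": qc_report.n_raw,
        "n_qc_reads": qc_report.n_kept,
        "n_removed_ambiguous": qc_report.n_removed_ambiguous,
        "n_removed_quality": qc_report.n_removed_quality,
        "n_no_call": n_no_call,
        "n_annotated": len(annotations),
        "n_productive_reads": rep.total_productive_reads,
        "n_clonotypes": rep.n_clonotypes,
    }
    (out / "qc_report.json").write_text(json.dumps(log, indent=2) + "\n")

    status = "ok"
    if rep.n_clonotypes == 0:
        status = "warning"
        (out / "diversity_profile.tsv").write_text("")
        return rep, status

    profile = pd.DataFrame([diversity_profile(rep).as_row()])
    profile.to_csv(out / "diversity_profile.tsv", sep="\t", index=False)
    usage = vj_usage(rep, ref)
    usage.freqs.to_csv(out / "vj_usage.tsv", sep="\t")
    usage.long_format().to_csv(out / "vj_usage_long.tsv", sep="\t", index=False)
    return rep, status


def repertoire_from_airr(
    path: str | Path,
    sample_id: str,
    group: str | None = None,
    clinical: dict[str, float] | None = None,
) -> Repertoire:
    """Rebuild a Repertoire from a written AIRR clonotype TSV."""
    table = read_airr(path)
    clono = pd.DataFrame(
        {
            "cdr3_aa": table["junction_aa"],
            "v_call": table["v_call"],
            "d_call": table["d_call"].replace("", None),
            "j_call": table["j_call"],
            "count": table["duplicate_count"],
            "frequency": table["frequency"],
        }
    )
    total = int(clono["count"].sum()) if len(clono) else 0
    return Repertoire(sample_id, group, clono, total, clinical or {})


def cohort_report(
    repertoires: list[Repertoire],
    ref: Reference,
    out_dir: str | Path,
    region_edges: tuple[float, ...] = DEFAULT_REGION_EDGES,
) -> dict[str, Path]:
    """Write the full cohort report-table set; returns written paths by name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    profiles = pd.DataFrame(
        [
            {**diversity_profile(r).as_row(), "group": r.group}
            for r in repertoires
        ]
    )
    written["diversity_profiles"] = out / "diversity_profiles.tsv"
    profiles.to_csv(written["diversity_profiles"], sep="\t", index=False)

    rows = [compare_diversity(repertoires, m).as_row() for m in REPORT_METRICS]
    written["diversity_comparison"] = out / "diversity_comparison.tsv"
    pd.DataFrame(rows).to_csv(written["diversity_comparison"], sep="\t", index=False)

    for level in USAGE_LEVELS:
        table = compare_usage(repertoires, ref, level)
        written[f"usage_{level}"] = out / f"usage_{level}.tsv"
        table.to_csv(written[f"usage_{level}"], sep="\t", index=False)

    for group in ("tumor", "normal"):
        mean = group_mean_usage(repertoires, ref, group)
        written[f"vj_mean_{group}"] = out / f"vj_mean_{group}.tsv"
        mean.to_csv(written[f"vj_mean_{group}"], sep="\t")
        clusters = cluster_j_families(mean)
        written[f"j_clusters_{group}"] = out / f"j_clusters_{group}.newick"
        written[f"j_clusters_{group}"].write_text(clusters.newick + "\n")
        membership = out / f"j_clusters_{group}.tsv"
        pd.DataFrame(
            [(c, j) for c, js in sorted(clusters.clusters.items()) for j in js],
            columns=["cluster", "j_call"],
        ).to_csv(membership, sep="\t", index=False)

    # clinical correlations: needs the covariate on every sample and >= 3
    # samples per group (smaller groups are skipped, not an error)
    corr_rows = []
    n_tumor = sum(r.group == "tumor" for r in repertoires)
    n_normal = sum(r.group == "normal" for r in repertoires)
    for cov in CLINICAL_COVARIATES:
        if all(cov in r.clinical for r in repertoires) and min(n_tumor, n_normal) >= 3:
            results = correlate_clinical(repertoires, "shannon_entropy", cov)
            for group, res in results.items():
                corr_rows.append(
                    {
                        "covariate": cov,
                        "group": group,
                        "metric": "shannon_entropy",
                        "rho": res.rho,
                        "p_value": res.p_value,
                        "n": res.n,
                    }
                )
    written["clinical_correlations"] = out / "clinical_correlations.tsv"
    pd.DataFrame(corr_rows).to_csv(written["clinical_correlations"], sep="\t", index=False)

    # frequency-region comparison: clonotype counts per region, tumor vs normal
    region_rows = []
    regions = {
        r.sample_id: frequency_regions(r.cdr3_frequencies(), region_edges)
        for r in repertoires
        if r.n_clonotypes
    }
    labels = next(iter(regions.values())).labels if regions else []
    for i, label in enumerate(labels):
        xs = [regions[r.sample_id].counts[i] for r in repertoires if r.group == "tumor"]
        ys = [regions[r.sample_id].counts[i] for r in repertoires if r.group == "normal"]
        res = mann_whitney_u(xs, ys, metric=label)
        region_rows.append(res.as_row())
    written["frequency_regions"] = out / "frequency_regions_comparison.tsv"
    pd.DataFrame(region_rows).to_csv(written["frequency_regions"], sep="\t", index=False)
    return written


def run_cohort(config: RunConfig, metadata_tsv: str | Path) -> dict[str, Path]:
    """Cohort run from a metadata TSV (sample_id, group, covariates, fastq).

    Per-sample AIRR outputs are built when absent and reused when present;
    groups with fewer than 2 samples are an error.
    """
    meta = pd.read_csv(metadata_tsv, sep="\t")
    base = Path(metadata_tsv).parent
    if meta["group"].value_counts().reindex(["tumor", "normal"]).fillna(0).min() < 2:
        raise ValueError("each group needs at least 2 samples")
    repertoires = []
    for row in meta.itertuples():
        clinical = {
            c: float(getattr(row, c))
            for c in CLINICAL_COVARIATES
            if hasattr(row, c) and np.isfinite(getattr(row, c))
        }
        airr = Path(config.out_dir) / row.sample_id / "clonotypes.airr.tsv"
        if not airr.exists():
            fastq = Path(row.fastq)
            if not fastq.is_absolute():
                fastq = base / fastq
            rep, _ = run_sample(config, fastq, row.sample_id, row.group, clinical)
        else:
            rep = repertoire_from_airr(airr, row.sample_id, row.group, clinical)
        repertoires.append(rep)
    ref = config.load_reference()
    return cohort_report(
        repertoires, ref, Path(config.out_dir) / "cohort", config.region_edges
    )
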