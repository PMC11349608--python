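"""Ground-truthed synthetic TCR-beta repertoires, reads, and cohorts.

The generator emulates the statistical structure of a two-group
(13 tumor / 9 adjacent-normal) amplicon repertoire study:

* clone sizes: log-normal weights (sigma 1.5), normalized to frequencies;
* junction amino-acid lengths: round(Normal(14, 1.5)) clipped to [8, 24];
* junctions: C + uniform interior + F on the amino-acid scale, nucleotides
  by uniform synonymous-codon back-translation, with the anchor codons
  copied from the clone's germline V and J so reads are self-consistent;
  70% of clones embed a >= 6 nt D-segment substring to exercise D calling;
* V/J usage: Dirichlet-sampled base vectors (fixed internal seed) with
  per-sample Dirichlet resampling around the base; the default cohort
  template shifts TRBV16 and TRBV7-6 usage up by +0.05 in the tumor group;
* reads: V flank + junction + J flank on the forward strand, per-base
  substitution errors, Phred ~ Normal(38, 2), plus a junk fraction split
  between random-sequence reads, reads with 9 planted N bases, and
  low-quality reads (to exercise QC and no-calls);
* clinical covariates (LDH, NLR, ALC): coupled to each sample's diversity
  through a Gaussian copula on ranks, so Spearman targets are direct
  (default SE-LDH coupling -0.8 in tumor, -0.2 in normal).

Identical seed and parameters give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import Repertoire
from .germline import GENETIC_CODE, Reference, SegmentKind
from .io import PHRED_OFFSET, SequenceRead

__all__ = [
    "SimulationParams",
    "CohortEffects",
    "GroundTruth",
    "sample_clones",
    "emit_reads",
    "write_fastq",
    "make_cohort",
    "repertoire_from_truth",
    "DEFAULT_V_FLANK",
    "DEFAULT_J_FLANK",
]

DEFAULT_V_FLANK = 36  # germline nt retained upstream of the V anchor codon
DEFAULT_J_FLANK = 27  # germline nt retained downstream of the J anchor codon

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in GENETIC_CODE.items():
    if _aa != "*":
        _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()

# rectangular codon lookup for vectorized back-translation
_N_CODONS = np.array([len(_CODONS_BY_AA[a]) for a in _AA20])
_CODON_TABLE = np.zeros((20, int(_N_CODONS.max())), dtype="S3")
for _i, _a in enumerate(_AA20):
    for _j, _c in enumerate(_CODONS_BY_AA[_a]):
        _CODON_TABLE[_i, _j] = _c.encode()

_AA_BY_CODON = {k.encode(): v for k, v in GENETIC_CODE.items()}


@dataclass(frozen=True)
class SimulationParams:
    """Defaults are the study conditions the generator emulates."""

    n_clones: int = 8000
    clone_size_sigma: float = 1.5  # log-normal sigma over unnormalized weights
    v_usage: np.ndarray | None = None  # probability vector over reference V segments
    j_usage: np.ndarray | None = None
    cdr3_len_mean: float = 14.0
    cdr3_len_sd: float = 1.5
    cdr3_len_range: tuple[int, int] = (8, 24)
    read_depth: int = 50_000
    error_rate: float = 0.002
    mean_phred: float = 38.0
    phred_sd: float = 2.0
    frac_junk_reads: float = 0.01
    d_embed_prob: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "frac_junk_reads", "d_embed_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for vec in (self.v_usage, self.j_usage):
            if vec is not None and abs(float(np.sum(vec)) - 1.0) > 1e-9:
                raise ValueError("usage vectors must sum to 1")


@dataclass
class GroundTruth:
    """True clone table plus (after read emission) per-read provenance."""

    clones: pd.DataFrame  # cdr3_aa, cdr3_nt, v_id, d_id, j_id, true_frequency
    ref: Reference
    provenance: pd.DataFrame | None = None  # read_id -> clone index (-1 = junk)


def default_usage(ref: Reference, concentration: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet-sampled skewed base usage vectors (fixed internal seed)."""
    rng = np.random.default_rng(20240901)
    v = rng.dirichlet(np.full(len(ref.v_ids), concentration))
    j = rng.dirichlet(np.full(len(ref.j_ids), concentration))
    return v, j


def sample_clones(params: SimulationParams, ref: Reference) -> GroundTruth:
    """Draw the clone table: V/J identity, junction, frequency per clone."""
    rng = np.random.default_rng(params.seed)
    n = params.n_clones
    if n <= 0:
        raise ValueError("n_clones must be positive")
    v_usage, j_usage = params.v_usage, params.j_usage
    if v_usage is None or j_usage is None:
        dv, dj = default_usage(ref)
        v_usage = dv if v_usage is None else np.asarray(v_usage)
        j_usage = dj if j_usage is None else np.asarray(j_usage)
    v_usage = np.asarray(v_usage, dtype=float)
    j_usage = np.asarray(j_usage, dtype=float)
    if len(v_usage) != len(ref.v_ids) or len(j_usage) != len(ref.j_ids):
        raise ValueError("usage vector length does not match the reference")

    v_idx = rng.choice(len(v_usage), size=n, p=v_usage)
    j_idx = rng.choice(len(j_usage), size=n, p=j_usage)

    lo, hi = params.cdr3_len_range
    lengths = np.clip(
        np.rint(rng.normal(params.cdr3_len_mean, params.cdr3_len_sd, size=n)).astype(int), lo, hi
    )

    # interior amino acids, then uniform synonymous-codon back-translation
    interior_len = lengths - 2
    offsets = np.concatenate([[0], np.cumsum(interior_len)])
    total = int(offsets[-1])
    aa_idx = rng.integers(0, 20, size=total)
    codon_idx = (rng.random(total) * _N_CODONS[aa_idx]).astype(int)
    interior_nt = _CODON_TABLE[aa_idx, codon_idx].tobytes()

    v_segs, j_segs, d_segs = ref.v_segments, ref.j_segments, ref.d_segments
    v_anchor_codon = [s.seq_nt[s.anchor_nt : s.anchor_nt + 3].encode() for s in v_segs]
    j_anchor_codon = [s.seq_nt[s.anchor_nt : s.anchor_nt + 3].encode() for s in j_segs]

    embed = rng.random(n) < params.d_embed_prob
    d_choice = rng.integers(0, max(len(d_segs), 1), size=n)

    cdr3_nt: list[str] = []
    cdr3_aa: list[str] = []
    d_ids: list[str | None] = []
    for i in range(n):
        interior = interior_nt[3 * offsets[i] : 3 * offsets[i + 1]]
        d_id = None
        if embed.size and embed[i] and d_segs and len(interior) >= 6:
            seg = d_segs[int(d_choice[i])]
            dseq = seg.seq_nt.encode()
            for _ in range(20):
                dlen = int(rng.integers(6, min(len(dseq), 10) + 1))
                dstart = int(rng.integers(0, len(dseq) - dlen + 1))
                pos = int(rng.integers(0, len(interior) - dlen + 1))
                cand = interior[:pos] + dseq[dstart : dstart + dlen] + interior[pos + dlen :]
                full = v_anchor_codon[v_idx[i]] + cand + j_anchor_codon[j_idx[i]]
                aa = "".join(_AA_BY_CODON[full[k : k + 3]] for k in range(0, len(full), 3))
                if "*" not in aa:
                    interior, d_id = cand, seg.id
                    break
        nt = v_anchor_codon[v_idx[i]] + interior + j_anchor_codon[j_idx[i]]
        if d_id is None:
            aa = "".join(_AA_BY_CODON[nt[k : k + 3]] for k in range(0, len(nt), 3))
        cdr3_nt.append(nt.decode())
        cdr3_aa.append(aa)
        d_ids.append(d_id)

    weights = rng.lognormal(0.0, params.clone_size_sigma, size=n)
    freqs = weights / weights.sum()

    clones = pd.DataFrame(
        {
            "cdr3_aa": cdr3_aa,
            "cdr3_nt": cdr3_nt,
            "v_id": [v_segs[i].id for i in v_idx],
            "d_id": d_ids,
            "j_id": [j_segs[i].id for i in j_idx],
            "true_frequency": freqs,
        }
    )
    return GroundTruth(clones, ref)


def _clone_read_template(clone, ref: Reference, v_flank: int, j_flank: int) -> str:
    v = ref[clone.v_id]
    j = ref[clone.j_id]
    v_part = v.seq_nt[max(0, v.anchor_nt - v_flank) : v.anchor_nt]
    j_part = j.seq_nt[j.anchor_nt + 3 : j.anchor_nt + 3 + j_flank]
    return v_part + clone.cdr3_nt + j_part


def emit_reads(
    truth: GroundTruth,
    params: SimulationParams,
    v_flank: int = DEFAULT_V_FLANK,
    j_flank: int = DEFAULT_J_FLANK,
) -> tuple[list[SequenceRead], pd.DataFrame]:
    """Multinomial reads over clone frequencies, plus junk; fills provenance.

    Junk reads rotate through three kinds: random sequence (good quality,
    exercises V/J no-calls), 9 planted N bases (fails the ambiguous-base
    filter), and 20% of positions at Q20 (fails the low-quality filter).
    """
    rng = np.random.default_rng(params.seed + 1)
    ref = truth.ref
    depth = params.read_depth
    n_junk = int(rng.binomial(depth, params.frac_junk_reads))
    counts = rng.multinomial(depth - n_junk, truth.clones["true_frequency"].to_numpy())

    templates = [
        _clone_read_template(c, ref, v_flank, j_flank) for c in truth.clones.itertuples()
    ]
    bases = np.array(list("ACGT"))
    reads: list[SequenceRead] = []
    prov_clone: list[int] = []
    ridx = 0

    def _quals(n: int) -> np.ndarray:
        q = np.rint(rng.normal(params.mean_phred, params.phred_sd, size=n))
        return np.clip(q, 2, 40).astype(np.int16)

    for clone_i, c in enumerate(counts):
        template = templates[clone_i]
        for _ in range(int(c)):
            seq = template
            if params.error_rate > 0:
                n_err = rng.binomial(len(seq), params.error_rate)
                if n_err:
                    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
                    pos = rng.choice(len(seq), size=n_err, replace=False)
                    for p in pos:
                        arr[p] = bases[(("ACGT".index(arr[p])) + int(rng.integers(1, 4))) % 4]
                    seq = "".join(arr)
            reads.append(SequenceRead(f"r{ridx:06d}", seq, _quals(len(seq))))
            prov_clone.append(clone_i)
            ridx += 1

    junk_len = v_flank + 42 + j_flank  # typical read length at the mean junction
    for k in range(n_junk):
        seq = "".join(rng.choice(bases, size=junk_len))
        quals = _quals(junk_len)
        kind = k % 3
        if kind == 1:
            pos = rng.choice(junk_len, size=9, replace=False)
            arr = list(seq)
            for p in pos:
                arr[p] = "N"
            seq = "".join(arr)
        elif kind == 2:
            n_low = int(np.ceil(0.20 * junk_len))
            pos = rng.choice(junk_len, size=n_low, replace=False)
            quals = quals.copy()
            quals[pos] = 20
        reads.append(SequenceRead(f"r{ridx:06d}", seq, quals))
        prov_clone.append(-1)
        ridx += 1

    provenance = pd.DataFrame(
        {"read_id": [r.id for r in reads], "clone_index": prov_clone}
    )
    truth.provenance = provenance
    return reads, provenance


def write_fastq(reads: list[SequenceRead], path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qual = (r.quals + PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")
            fh.write(f"@{r.id}\n{r.seq_nt}\n+\n{qual}\n")


def repertoire_from_truth(
    truth: GroundTruth,
    params: SimulationParams,
    sample_id: str,
    group: str | None = None,
    clinical: dict[str, float] | None = None,
) -> Repertoire:
    """Table-mode sample: multinomial read counts over true frequencies,
    bypassing read emission and annotation (used for statistics-level
    simulations where the read layer is exercised elsewhere)."""
    rng = np.random.default_rng(params.seed + 1)
    counts = rng.multinomial(params.read_depth, truth.clones["true_frequency"].to_numpy())
    df = truth.clones.loc[counts > 0, ["cdr3_aa", "v_id", "d_id", "j_id"]].copy()
    df["count"] = counts[counts > 0]
    df = df.rename(columns={"v_id": "v_call", "d_id": "d_call", "j_id": "j_call"})
    grouped = (
        df.groupby(["cdr3_aa", "v_call", "j_call"], sort=True)
        .agg(count=("count", "sum"), d_call=("d_call", "first"))
        .reset_index()
    )
    total = int(grouped["count"].sum())
    grouped["frequency"] = grouped["count"] / total
    grouped = grouped[["cdr3_aa", "v_call", "d_call", "j_call", "count", "frequency"]]
    return Repertoire(sample_id, group, grouped, total, clinical or {})


# --- cohort generation ----------------------------------------------------


@dataclass(frozen=True)
class CohortEffects:
    """Group-level effect template for synthetic cohorts.

    ``usage_shifts``: additive usage increase per V id in the tumor group.
    ``covariate_rho``: target Spearman correlation between a sample's
    diversity driver and each clinical covariate, per group.
    ``sigma_range``: per-sample clone-size sigma spans this interval,
    mapped monotonically (decreasing) from the diversity driver.
    """

    usage_shifts: dict[str, float] = field(
        default_factory=lambda: {"TRBV16": 0.05, "TRBV7-6": 0.05}
    )
    covariate_rho: dict[str, tuple[float, float]] = field(  # (tumor, normal)
        default_factory=lambda: {"LDH": (-0.8, -0.2), "NLR": (0.7, 0.2), "ALC": (-0.5, 0.3)}
    )
    sigma_range: tuple[float, float] = (0.8, 2.2)
    usage_concentration: float = 300.0  # per-sample Dirichlet concentration

    def __post_init__(self) -> None:
        for cov, (rt, rn) in self.covariate_rho.items():
            if abs(rt) > 1 or abs(rn) > 1:
                raise ValueError(f"infeasible copula target for {cov}: |rho| > 1")


_COVARIATE_SCALE = {  # log-normal (log-median, log-sd) per clinical covariate
    "LDH": (np.log(220.0), 0.25),  # U/L
    "NLR": (np.log(2.5), 0.35),  # ratio
    "ALC": (np.log(1.2), 0.30),  # 10^9/L
}


def _shift_usage(base: np.ndarray, v_ids: list[str], shifts: dict[str, float]) -> np.ndarray:
    """Add the template deltas to named segments, rescaling the rest."""
    out = base.copy()
    idx = {v: i for i, v in enumerate(v_ids)}
    delta_total = 0.0
    target_mass = 0.0
    for v, d in shifts.items():
        if v not in idx:
            raise ValueError(f"usage shift names unknown segment {v}")
        target_mass += out[idx[v]]
        delta_total += d
    scale = (1.0 - target_mass - delta_total) / (1.0 - target_mass)
    if scale <= 0:
        raise ValueError("usage shifts exceed available probability mass")
    out *= scale
    for v, d in shifts.items():
        out[idx[v]] = base[idx[v]] + d
    return out / out.sum()


def make_cohort(
    ref: Reference,
    n_tumor: int = 13,
    n_normal: int = 9,
    effects: CohortEffects | None = None,
    params: SimulationParams | None = None,
    seed: int = 0,
    mode: str = "tables",
    out_dir: str | Path | None = None,
):
    """Generate a two-group cohort with built-in usage and covariate effects.

    ``mode="tables"`` returns (repertoires, truths, manifest) with
    table-mode samples; ``mode="reads"`` additionally writes per-sample
    FASTQ, ground-truth clone tables, a metadata TSV and a params YAML to
    ``out_dir`` and returns the manifest.
    """
    if mode not in ("tables", "reads"):
        raise ValueError("mode must be 'tables' or 'reads'")
    if mode == "reads" and out_dir is None:
        raise ValueError("reads mode requires out_dir")
    effects = effects or CohortEffects()
    base_params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    base_v, base_j = default_usage(ref)
    tumor_v = _shift_usage(base_v, ref.v_ids, effects.usage_shifts)

    from scipy.stats import norm

    samples = [("tumor", f"T{i + 1:02d}") for i in range(n_tumor)] + [
        ("normal", f"N{i + 1:02d}") for i in range(n_normal)
    ]
    repertoires, truths, rows = [], [], []
    for group, sample_id in samples:
        z0 = rng.standard_normal()
        u1 = norm.cdf(z0)
        lo, hi = effects.sigma_range
        sigma = lo + (hi - lo) * (1.0 - u1)  # high driver -> even repertoire -> high SE
        clinical = {}
        for cov, (rho_t, rho_n) in effects.covariate_rho.items():
            rho_s = rho_t if group == "tumor" else rho_n
            rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)  # Spearman -> Gaussian copula rho
            z = rho_p * z0 + np.sqrt(1.0 - rho_p**2) * rng.standard_normal()
            mu, sd = _COVARIATE_SCALE[cov]
            clinical[cov] = float(np.exp(mu + sd * z))
        group_v = tumor_v if group == "tumor" else base_v
        conc = effects.usage_concentration
        sample_v = rng.dirichlet(np.maximum(group_v * conc, 1e-6))
        sample_j = rng.dirichlet(np.maximum(base_j * conc, 1e-6))
        sparams = replace(
            base_params,
            clone_size_sigma=float(sigma),
            v_usage=sample_v,
            j_usage=sample_j,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth = sample_clones(sparams, ref)
        truths.append(truth)
        row = {"sample_id": sample_id, "group": group, **clinical}
        if mode == "tables":
            repertoires.append(
                repertoire_from_truth(truth, sparams, sample_id, group, clinical)
            )
        else:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            reads, provenance = emit_reads(truth, sparams)
            fastq = out / f"{sample_id}.fastq"
            write_fastq(reads, fastq)
            truth.clones.to_csv(out / f"{sample_id}.truth.tsv", sep="\t", index=False)
            provenance.to_csv(out / f"{sample_id}.provenance.tsv", sep="\t", index=False)
            row["fastq"] = fastq.name
        rows.append(row)

    manifest = pd.DataFrame(rows)
    if mode == "reads":
        out = Path(out_dir)
        manifest.to_csv(out / "metadata.tsv", sep="\t", index=False)
        with open(out / "params.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "seed": seed,
                    "n_tumor": n_tumor,
                    "n_normal": n_normal,
                    "n_clones": base_params.n_clones,
                    "read_depth": base_params.read_depth,
                    "error_rate": base_params.error_rate,
                    "frac_junk_reads": base_params.frac_junk_reads,
                    "usage_shifts": dict(effects.usage_shifts),
                    "covariate_rho": {k: list(v) for k, v in effects.covariate_rho.items()},
                },
                fh,
            )
        return manifest
    return repertoires, truths, manifest
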