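"""Per-sample repertoire statistics.

Diversity indices operate on unique-CDR3aa frequencies (V/J collapsed):

* Shannon entropy  H = -sum p_i ln p_i  (natural log, nats)
* clonality        1 - H / ln R        (R = number of unique clonotypes)
* Simpson          D = sum p_i^2       (dominance form)
* CF100            cumulative frequency of the 100 most abundant clonotypes
* D50              k / R, k the smallest number of top clonotypes whose
                   cumulative frequency reaches 0.5

Usage statistics operate on read-level V/J calls over the full reference
gene space (58 x 14 = 812 cells for the bundled reference).  The overlap
rate between two samples is the overlap coefficient on unique CDR3aa sets
(shared / smaller), so nested repertoires score 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import Repertoire
from .germline import Reference, collapse_families

__all__ = [
    "DiversityProfile",
    "UsageMatrix",
    "FrequencyRegions",
    "shannon_entropy",
    "clonality",
    "simpson",
    "cf100",
    "d50",
    "diversity_profile",
    "length_distribution",
    "frequency_regions",
    "vj_usage",
    "overlap_rate",
    "DEFAULT_REGION_EDGES",
]

DEFAULT_REGION_EDGES = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, 1.0)


def _check_freqs(freqs, name: str = "freqs") -> np.ndarray:
    f = np.asarray(freqs, dtype=float)
    if f.size == 0:
        raise ValueError(f"{name} must be nonempty")
    if (f <= 0).any():
        raise ValueError(f"{name} must be strictly positive")
    return f


def shannon_entropy(freqs) -> float:
    """H = -sum p ln p in nats; requires positive frequencies summing to 1."""
    f = _check_freqs(freqs)
    return float(-(f * np.log(f)).sum())


def clonality(freqs) -> float:
    """1 - H/ln(R); 0 for a perfectly even repertoire, undefined for R = 1."""
    f = _check_freqs(freqs)
    if f.size < 2:
        raise ValueError("clonality undefined for a single clonotype")
    return float(1.0 - shannon_entropy(f) / np.log(f.size))


def simpson(freqs) -> float:
    """Simpson dominance D = sum p^2 (1/R for uniform, 1 for monoclonal)."""
    f = _check_freqs(freqs)
    return float((f * f).sum())


def cf100(freqs, top: int = 100) -> float:
    """Cumulative frequency of the ``top`` most abundant clonotypes (1.0 if R <= top)."""
    f = _check_freqs(freqs)
    if f.size <= top:
        return float(f.sum())
    return float(np.sort(f)[::-1][:top].sum())


def d50(freqs) -> float:
    """Fraction of unique clonotypes (most abundant first) covering half the reads."""
    f = np.sort(_check_freqs(freqs))[::-1]
    cum = np.cumsum(f)
    k = int(np.searchsorted(cum, 0.5 - 1e-12)) + 1
    return k / f.size


@dataclass(frozen=True)
class DiversityProfile:
    """The per-sample statistic vector reported for each repertoire."""

    sample_id: str
    shannon_entropy: float
    clonality: float
    simpson: float
    cf100: float
    d50: float
    n_clonotypes: int
    n_v_segments: int
    n_vj_pairs: int
    n_vdj_combos: int
    mean_cdr3_len: float

    def as_row(self) -> dict:
        return dict(self.__dict__)


def diversity_profile(rep: Repertoire) -> DiversityProfile:
    """Compute the full diversity vector for one repertoire.

    Diversity indices use unique-CDR3aa frequencies; segment counts use
    the clonotype table's read-level calls.  Clonality is NaN for a
    single-clonotype repertoire; an empty repertoire yields zero counts
    and NaN indices.
    """
    if rep.n_clonotypes == 0:
        nan = float("nan")
        return DiversityProfile(rep.sample_id, nan, nan, nan, nan, nan, 0, 0, 0, 0, nan)
    freqs = rep.cdr3_frequencies()
    clon = clonality(freqs) if freqs.size >= 2 else float("nan")
    table = rep.clonotypes
    with_d = table[table["d_call"].notna() & (table["d_call"] != "")]
    lengths = table["cdr3_aa"].drop_duplicates().str.len()
    return DiversityProfile(
        sample_id=rep.sample_id,
        shannon_entropy=shannon_entropy(freqs),
        clonality=clon,
        simpson=simpson(freqs),
        cf100=cf100(freqs),
        d50=d50(freqs),
        n_clonotypes=int(pd.unique(table["cdr3_aa"]).size),
        n_v_segments=int(pd.unique(table["v_call"]).size),
        n_vj_pairs=int(len(table[["v_call", "j_call"]].drop_duplicates())),
        n_vdj_combos=int(len(with_d[["v_call", "d_call", "j_call"]].drop_duplicates())),
        mean_cdr3_len=float(lengths.mean()),
    )


@dataclass
class LengthDistribution:
    histogram: pd.Series  # proportion per integer aa length
    mean: float
    sd: float
    gaussian_fit_r2: float


def length_distribution(rep: Repertoire, weighting: str = "by_clonotype") -> LengthDistribution:
    """CDR3aa length histogram with moment estimates and a Gaussian fit R^2.

    ``by_clonotype`` weights each unique CDR3aa once (default);
    ``by_read`` weights by read counts.  The fit R^2 compares observed
    length proportions with the Normal(mean, sd) density discretized over
    integer lengths (unit-interval CDF mass per length).
    """
    if rep.n_clonotypes == 0:
        raise ValueError("empty repertoire")
    if weighting == "by_clonotype":
        lengths = rep.clonotypes["cdr3_aa"].drop_duplicates().str.len()
        weights = np.ones(len(lengths), dtype=float)
    elif weighting == "by_read":
        lengths = rep.clonotypes["cdr3_aa"].str.len()
        weights = rep.clonotypes["count"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    lengths = lengths.to_numpy()
    total = weights.sum()
    mean = float((lengths * weights).sum() / total)
    sd = float(np.sqrt(((lengths - mean) ** 2 * weights).sum() / total))
    hist = (
        pd.Series(weights, index=lengths).groupby(level=0).sum().sort_index() / total
    )
    if sd == 0:
        r2 = 1.0 if len(hist) == 1 else 0.0
    else:
        grid = hist.index.to_numpy(dtype=float)
        expected = sps.norm.cdf(grid + 0.5, mean, sd) - sps.norm.cdf(grid - 0.5, mean, sd)
        obs = hist.to_numpy()
        ss_res = float(((obs - expected) ** 2).sum())
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return LengthDistribution(hist, mean, sd, r2)


@dataclass
class FrequencyRegions:
    """Clonotype counts per half-open frequency bin (lo, hi]."""

    edges: tuple[float, ...]
    counts: np.ndarray

    @property
    def labels(self) -> list[str]:
        return [
            f"({self.edges[i]:g}, {self.edges[i + 1]:g}]" for i in range(len(self.edges) - 1)
        ]


def frequency_regions(freqs, edges=DEFAULT_REGION_EDGES) -> FrequencyRegions:
    """Bin clonotype frequencies into half-open regions (lo, hi]."""
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    if edges[0] != 0.0 or edges[-1] != 1.0:
        raise ValueError("edges must span (0, 1]")
    f = _check_freqs(freqs)
    if (f > 1.0).any():
        raise ValueError("frequencies must lie in (0, 1]")
    # (lo, hi]: a frequency equal to an edge belongs to the bin below it.
    idx = np.searchsorted(edges, f, side="left") - 1
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return FrequencyRegions(edges, counts)


@dataclass
class UsageMatrix:
    """Read-level V x J usage frequencies over the full reference gene space."""

    v_ids: list[str]
    j_ids: list[str]
    freqs: pd.DataFrame  # index v_ids, columns j_ids

    @property
    def n_cells(self) -> int:
        return len(self.v_ids) * len(self.j_ids)

    @property
    def v_usage(self) -> pd.Series:
        return self.freqs.sum(axis=1)

    @property
    def j_usage(self) -> pd.Series:
        return self.freqs.sum(axis=0)

    @property
    def v_family_usage(self) -> pd.Series:
        return pd.Series(collapse_families(self.v_usage.to_dict())).sort_index()

    @property
    def n_vj_pairs(self) -> int:
        return int((self.freqs.to_numpy() > 0).sum())

    def long_format(self) -> pd.DataFrame:
        """Heatmap-ready (v, j, frequency) rows."""
        out = self.freqs.stack().rename("frequency").reset_index()
        out.columns = ["v_call", "j_call", "frequency"]
        return out


def vj_usage(rep: Repertoire, ref: Reference) -> UsageMatrix:
    """Per-sample V x J usage: cell (v, j) = fraction of productive reads."""
    v_ids, j_ids = ref.v_ids, ref.j_ids
    mat = pd.DataFrame(0.0, index=v_ids, columns=j_ids)
    if rep.n_clonotypes:
        bad_v = set(rep.clonotypes["v_call"]) - set(v_ids)
        bad_j = set(rep.clonotypes["j_call"]) - set(j_ids)
        if bad_v or bad_j:
            raise ValueError(f"calls outside the reference: {sorted(bad_v | bad_j)}")
        counts = rep.clonotypes.groupby(["v_call", "j_call"])["count"].sum()
        total = counts.sum()
        for (v, j), c in counts.items():
            mat.loc[v, j] = c / total
    return UsageMatrix(list(v_ids), list(j_ids), mat)


def overlap_rate(rep_a: Repertoire, rep_b: Repertoire) -> float:
    """Overlap coefficient on unique CDR3aa sets: |A & B| / min(|A|, |B|)."""
    a, b = rep_a.unique_cdr3aa(), rep_b.unique_cdr3aa()
    if not a or not b:
        raise ValueError("overlap rate undefined for an empty repertoire")
    return len(a & b) / min(len(a), len(b))
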