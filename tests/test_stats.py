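import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trbrep.annotate import Repertoire
from trbrep.simulate import SimulationParams, repertoire_from_truth, sample_clones
from trbrep.stats import (
    DEFAULT_REGION_EDGES,
    cf100,
    clonality,
    d50,
    diversity_profile,
    frequency_regions,
    length_distribution,
    overlap_rate,
    shannon_entropy,
    simpson,
    vj_usage,
)

from conftest import make_repertoire

positive_freqs = st.lists(
    st.floats(1e-6, 1.0, allow_nan=False), min_size=2, max_size=40
).map(lambda w: np.asarray(w) / np.sum(w))


class TestDiversityIndices:
    def test_entropy_uniform_is_log_n(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)

    def test_entropy_monoclonal_is_zero(self):
        assert shannon_entropy([1.0]) == 0.0

    def test_entropy_direct_evaluation(self):
        assert shannon_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.0397207708399179)

    def test_clonality_uniform_is_zero(self):
        for n in (2, 5, 17):
            assert clonality([1 / n] * n) == pytest.approx(0.0, abs=1e-12)

    def test_clonality_skewed_direct_evaluation(self):
        # H = -(0.97 ln 0.97 + 3 * 0.01 ln 0.01) = 0.1677005...
        assert clonality([0.97, 0.01, 0.01, 0.01]) == pytest.approx(0.8790296335733946)

    def test_clonality_single_clonotype_undefined(self):
        with pytest.raises(ValueError, match="single clonotype"):
            clonality([1.0])

    def test_simpson_uniform_is_reciprocal_n(self):
        for n in (1, 10, 1000):
            assert simpson([1 / n] * n) == pytest.approx(1 / n, abs=1e-12)

    def test_simpson_direct_evaluation(self):
        assert simpson([0.5, 0.3, 0.2]) == pytest.approx(0.38)

    def test_cf100_saturates_below_101_clonotypes(self):
        assert cf100([1 / 50] * 50) == pytest.approx(1.0)

    def test_cf100_uniform_200(self):
        assert cf100([1 / 200] * 200) == pytest.approx(0.5)

    def test_cf100_dominant_clone(self):
        freqs = [0.5] + [0.005] * 100
        assert cf100(freqs) == pytest.approx(0.995)

    def test_d50_uniform_even(self):
        assert d50([0.1] * 10) == pytest.approx(0.5)

    def test_d50_dominant_clone(self):
        assert d50([0.6, 0.1, 0.1, 0.1, 0.1]) == pytest.approx(0.2)

    def test_d50_monoclonal(self):
        assert d50([1.0]) == pytest.approx(1.0)

    def test_empty_inputs_rejected(self):
        for fn in (shannon_entropy, simpson, cf100, d50):
            with pytest.raises(ValueError):
                fn([])

    @settings(deadline=None, max_examples=60)
    @given(positive_freqs)
    def test_clonality_consistent_with_entropy(self, freqs):
        assert clonality(freqs) == pytest.approx(
            1 - shannon_entropy(freqs) / math.log(len(freqs)), abs=1e-12
        )

    @settings(deadline=None, max_examples=60)
    @given(positive_freqs, st.randoms(use_true_random=False))
    def test_cf100_and_d50_permutation_invariant(self, freqs, rnd):
        shuffled = list(freqs)
        rnd.shuffle(shuffled)
        assert cf100(shuffled) == pytest.approx(cf100(freqs))
        assert d50(shuffled) == pytest.approx(d50(freqs))

    @settings(deadline=None, max_examples=60)
    @given(positive_freqs)
    def test_d50_bounded_by_half_ceiling(self, freqs):
        r = len(freqs)
        assert d50(freqs) <= math.ceil(r / 2) / r + 1e-12

    def test_d50_equality_iff_uniform(self):
        rng = np.random.default_rng(0)
        for r in range(2, 51):
            uniform = np.full(r, 1 / r)
            assert d50(uniform) == pytest.approx(math.ceil(r / 2) / r)
            w = rng.dirichlet(np.ones(r) * 0.5)
            if np.ptp(w) > 1e-6:
                assert d50(w) <= math.ceil(r / 2) / r


class TestDiversityProfile:
    def test_entropy_bounded_by_log_clonotypes(self, ref):
        params = SimulationParams(n_clones=500, read_depth=5000, seed=4)
        rep = repertoire_from_truth(sample_clones(params, ref), params, "S")
        prof = diversity_profile(rep)
        assert 0 <= prof.shannon_entropy <= math.log(prof.n_clonotypes)
        assert prof.simpson >= 1 / prof.n_clonotypes
        assert prof.d50 <= math.ceil(prof.n_clonotypes / 2) / prof.n_clonotypes

    def test_empty_repertoire_yields_zero_counts(self):
        empty = Repertoire("S", None, pd.DataFrame(
            columns=["cdr3_aa", "v_call", "d_call", "j_call", "count", "frequency"]
        ), 0)
        prof = diversity_profile(empty)
        assert prof.n_clonotypes == 0 and math.isnan(prof.shannon_entropy)

    def test_subsampling_never_increases_clonotypes(self, ref):
        params = SimulationParams(n_clones=400, read_depth=4000, seed=8)
        rep = repertoire_from_truth(sample_clones(params, ref), params, "S")
        rng = np.random.default_rng(0)
        counts = rep.clonotypes["count"].to_numpy()
        reads = np.repeat(np.arange(len(counts)), counts)
        for frac in (0.5, 0.2, 0.05):
            sub = rng.choice(reads, size=int(len(reads) * frac), replace=False)
            assert len(np.unique(sub)) <= rep.n_clonotypes


class TestLengthDistribution:
    def test_constant_length(self):
        rep = make_repertoire([0.5, 0.5])
        dist = length_distribution(rep)
        assert dist.mean == pytest.approx(10.0)  # CASS%05dF = 10 aa
        assert dist.sd == 0.0

    def test_two_lengths_average(self):
        table = pd.DataFrame(
            {
                "cdr3_aa": ["C" + "A" * 11 + "F", "C" + "A" * 13 + "F"],
                "v_call": "TRBV16",
                "d_call": None,
                "j_call": "TRBJ2-1",
                "count": [5, 5],
                "frequency": [0.5, 0.5],
            }
        )
        rep = Repertoire("S", None, table, 10)
        assert length_distribution(rep).mean == pytest.approx(14.0)

    def test_simulated_lengths_fit_gaussian(self, ref):
        params = SimulationParams(n_clones=5000, read_depth=50_000, seed=15)
        rep = repertoire_from_truth(sample_clones(params, ref), params, "S")
        dist = length_distribution(rep, weighting="by_clonotype")
        assert 13.8 <= dist.mean <= 14.2
        assert dist.gaussian_fit_r2 >= 0.95

    def test_unknown_weighting_rejected(self):
        with pytest.raises(ValueError, match="weighting"):
            length_distribution(make_repertoire([1.0, 0.0]), weighting="by_magic")


class TestFrequencyRegions:
    def test_default_edges_place_midrange_frequency(self):
        fr = frequency_regions([0.0005] + [0.9995])
        assert fr.counts[list(fr.labels).index("(0.0001, 0.001]")] == 1

    def test_edge_value_belongs_to_lower_bin(self):
        fr = frequency_regions([1e-3, 1 - 1e-3])
        assert fr.counts[2] == 1  # (1e-4, 1e-3]

    def test_abundant_uniform_clonotypes_fill_top_bin(self):
        fr = frequency_regions([1 / 80] * 80)
        assert fr.counts[-1] == 80

    def test_exact_hundredth_belongs_to_lower_bin(self):
        # the half-open (lo, hi] rule puts a frequency of exactly 1e-2 below the top bin
        fr = frequency_regions([0.01] * 100)
        assert fr.counts[3] == 100 and fr.counts[-1] == 0

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            frequency_regions([0.5, 1.5])
        with pytest.raises(ValueError):
            frequency_regions([0.0, 1.0])

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            frequency_regions([0.5], edges=(0.0, 0.5, 0.25, 1.0))

    @settings(deadline=None, max_examples=80)
    @given(positive_freqs)
    def test_counts_conserve_clonotypes(self, freqs):
        fr = frequency_regions(freqs, DEFAULT_REGION_EDGES)
        assert fr.counts.sum() == len(freqs)


class TestVjUsage:
    def test_gene_space_has_812_cells(self, ref):
        usage = vj_usage(make_repertoire([0.5, 0.5]), ref)
        assert usage.n_cells == 812
        assert usage.freqs.shape == (58, 14)

    def test_single_pair_concentrates_mass(self, ref):
        usage = vj_usage(make_repertoire([1.0], v_call="TRBV16", j_call="TRBJ2-1"), ref)
        assert usage.freqs.loc["TRBV16", "TRBJ2-1"] == pytest.approx(1.0)
        assert usage.freqs.to_numpy().sum() == pytest.approx(1.0)

    def test_call_outside_reference_rejected(self, ref):
        rep = make_repertoire([1.0], v_call="TRBV99")
        with pytest.raises(ValueError, match="TRBV99"):
            vj_usage(rep, ref)

    def test_known_usage_recovered_within_binomial_bound(self, ref):
        nv, nj = len(ref.v_ids), len(ref.j_ids)
        params = SimulationParams(
            n_clones=20_000,
            read_depth=100_000,
            v_usage=np.full(nv, 1 / nv),
            j_usage=np.full(nj, 1 / nj),
            clone_size_sigma=0.0,
            seed=30,
        )
        rep = repertoire_from_truth(sample_clones(params, ref), params, "S")
        usage = vj_usage(rep, ref)
        expected = 1 / (nv * nj)
        assert np.abs(usage.freqs.to_numpy() - expected).max() <= 0.01

    def test_marginals_sum_to_one(self, ref):
        params = SimulationParams(n_clones=300, read_depth=2000, seed=2)
        rep = repertoire_from_truth(sample_clones(params, ref), params, "S")
        usage = vj_usage(rep, ref)
        assert usage.v_usage.sum() == pytest.approx(1.0, abs=1e-9)
        assert usage.j_usage.sum() == pytest.approx(1.0, abs=1e-9)
        assert usage.v_family_usage.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(usage.v_family_usage) == 28


class TestOverlapRate:
    def test_identical_sets(self):
        rep = make_repertoire([0.5, 0.3, 0.2])
        assert overlap_rate(rep, rep) == pytest.approx(1.0)

    def test_disjoint_sets(self):
        a = make_repertoire([0.5, 0.5])
        b = make_repertoire([0.5, 0.5])
        b.clonotypes["cdr3_aa"] = ["CXXAF", "CXXBF"]
        assert overlap_rate(a, b) == 0.0

    def test_partial_overlap_uses_smaller_denominator(self):
        a = make_repertoire([0.25] * 4)  # clonotypes 0..3
        b = make_repertoire([0.4, 0.3, 0.3])
        b.clonotypes["cdr3_aa"] = ["CASS00000F", "CASS00001F", "CXXQF"]
        assert overlap_rate(a, b) == pytest.approx(2 / 3)

    def test_empty_repertoire_rejected(self):
        a = make_repertoire([1.0])
        empty = Repertoire("E", None, pd.DataFrame(
            columns=["cdr3_aa", "v_call", "d_call", "j_call", "count", "frequency"]
        ), 0)
        with pytest.raises(ValueError):
            overlap_rate(a, empty)
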