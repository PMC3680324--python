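"""M-value/beta conversion, region scoring, random-region matching, t-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clustermir import (
    GenomicRegion, RunConfig, SimulationSpec, analyse_target_region,
    hypermethylation_test, m_to_beta, pick_random_regions, score_region,
    simulate_methylation, default_methylation_regions,
)
from clustermir.methylation import beta_to_m

from oracles import welch_t_one_tailed_p


class TestMToBeta:
    @pytest.mark.parametrize("m,beta", [(0.0, 0.5), (2.0, 0.8), (-2.0, 0.2)])
    def test_known_values(self, m, beta):
        assert m_to_beta(m) == pytest.approx(beta, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-40, 40))
    def test_antisymmetry(self, m):
        assert m_to_beta(-m) == pytest.approx(1 - m_to_beta(m), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.01, 0.99))
    def test_inverse_identity(self, beta):
        assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, abs=1e-12)

    def test_monotone_and_bounded(self):
        m = np.linspace(-30, 30, 201)
        b = m_to_beta(m)
        assert (np.diff(b) > 0).all()
        assert ((b > 0) & (b < 1)).all()

    def test_nan_propagates(self):
        assert np.isnan(m_to_beta(np.nan))


def _probe_table(m_values, chrom="chr1", start=100):
    """n_probes x n_samples M-values at consecutive positions."""
    m = np.atleast_2d(np.asarray(m_values, float))
    df = pd.DataFrame({
        "probe_id": [f"cg{i}" for i in range(m.shape[0])],
        "chrom": chrom,
        "pos": np.arange(start, start + m.shape[0]),
    })
    for j in range(m.shape[1]):
        df[f"s{j}"] = m[:, j]
    return df


class TestScoreRegion:
    def test_constant_high_m_is_hyper(self, config):
        probes = _probe_table(np.full((10, 4), 2.5))
        rm = score_region(probes, GenomicRegion("chr1", 0, 1000, "r"), config)
        assert rm.call == "hyper"
        assert rm.median_beta == pytest.approx(2**2.5 / (2**2.5 + 1))
        assert rm.n_probes == 10

    def test_zero_m_is_normal(self, config):
        probes = _probe_table(np.zeros((5, 3)))
        rm = score_region(probes, GenomicRegion("chr1", 0, 1000, "r"), config)
        assert rm.call == "normal" and rm.median_beta == 0.5

    def test_median_exactly_at_threshold_is_normal(self, config):
        """The hypermethylation call needs median beta strictly above 0.8;
        M = 2 gives exactly 0.8 and stays normal."""
        probes = _probe_table(np.full((7, 2), 2.0))
        rm = score_region(probes, GenomicRegion("chr1", 0, 1000, "r"), config)
        assert rm.median_beta == pytest.approx(0.8, abs=1e-12)
        assert rm.call == "normal"

    def test_low_m_is_hypo(self, config):
        probes = _probe_table(np.full((5, 2), -3.0))
        rm = score_region(probes, GenomicRegion("chr1", 0, 1000, "r"), config)
        assert rm.call == "hypo"

    def test_probe_and_sample_order_invariance(self, config, rng):
        m = rng.normal(1.0, 0.5, (20, 6))
        probes = _probe_table(m)
        region = GenomicRegion("chr1", 0, 1000, "r")
        base = score_region(probes, region, config)
        shuffled = probes.sample(frac=1, random_state=3)
        cols = ["probe_id", "chrom", "pos"] + [f"s{j}" for j in (4, 2, 0, 5, 1, 3)]
        again = score_region(shuffled[cols], region, config)
        assert again.median_beta == base.median_beta
        assert again.call == base.call

    def test_empty_region_raises_with_name(self, config):
        probes = _probe_table(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="elsewhere"):
            score_region(probes, GenomicRegion("chr2", 0, 10, "elsewhere"), config)

    def test_only_in_region_probes_counted(self, config):
        probes = _probe_table(np.vstack([np.full((5, 1), 3.0),
                                         np.full((5, 1), -3.0)]))
        rm = score_region(probes, GenomicRegion("chr1", 100, 105, "left"), config)
        assert rm.n_probes == 5
        assert rm.call == "hyper"


class TestPickRandomRegions:
    def _probes(self, seed=0):
        spec = SimulationSpec(seed=seed, n_probes_region=200, n_case=5)
        target, controls = default_methylation_regions()
        return simulate_methylation(spec, [target, *controls]), target

    def test_count_matching_and_disjointness(self):
        probes, target = self._probes()
        regions = pick_random_regions(probes, target, 10, seed=11)
        assert len(regions) == 10
        for i, r in enumerate(regions):
            n = ((probes["chrom"] == r.chrom) &
                 (probes["pos"] >= r.start) & (probes["pos"] < r.end)).sum()
            assert 180 <= n <= 220
            assert not r.overlaps(target)
            for other in regions[i + 1:]:
                assert not r.overlaps(other)

    def test_seed_reproducibility(self):
        probes, target = self._probes()
        assert pick_random_regions(probes, target, 5, seed=2) == \
            pick_random_regions(probes, target, 5, seed=2)

    def test_insufficient_candidates_raises_with_achieved_count(self):
        probes, target = self._probes()
        with pytest.raises(ValueError, match="of 50"):
            pick_random_regions(probes, target, 50, seed=1)


class TestHypermethylationTest:
    def test_separated_groups_near_zero_p(self, config):
        rng = np.random.default_rng(0)
        target = _region_methylation(0.85 + rng.normal(0, 0.005, 200), "t", config)
        ctrl = _region_methylation(0.5 + rng.normal(0, 0.005, 200), "c", config)
        assert hypermethylation_test(target, [ctrl]) < 1e-50

    def test_matches_welch_oracle(self, config):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.4, 0.9, 50)
        b = rng.uniform(0.3, 0.8, 80)
        target = _region_methylation(a, "t", config)
        ctrl = _region_methylation(b, "c", config)
        assert hypermethylation_test(target, [ctrl]) == pytest.approx(
            welch_t_one_tailed_p(a, b), abs=1e-12
        )

    def test_null_rejection_rate_near_alpha(self, config):
        """Target and controls drawn from the same beta distribution: the
        one-tailed test rejects at roughly its nominal level."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_trials = 400
        for _ in range(n_trials):
            a = rng.uniform(0.3, 0.7, 40)
            b = rng.uniform(0.3, 0.7, 40)
            t = _region_methylation(a, "t", config)
            c = _region_methylation(b, "c", config)
            if hypermethylation_test(t, [c]) < 0.05:
                rejections += 1
        assert rejections / n_trials == pytest.approx(0.05, abs=0.03)

    def test_degenerate_zero_variance(self, config):
        t_eq = _region_methylation(np.full(5, 0.5), "t", config)
        c = _region_methylation(np.full(5, 0.5), "c", config)
        assert hypermethylation_test(t_eq, [c]) == 1.0
        t_hi = _region_methylation(np.full(5, 0.9), "t", config)
        assert hypermethylation_test(t_hi, [c]) == 0.0

    def test_region_medians_mode_needs_multiple_controls(self, config):
        t = _region_methylation(np.full(5, 0.9), "t", config)
        c = _region_methylation(np.linspace(0.4, 0.6, 5), "c", config)
        with pytest.raises(ValueError):
            hypermethylation_test(t, [c], mode="region_medians")

    def test_no_controls_raises(self, config):
        t = _region_methylation(np.full(5, 0.9), "t", config)
        with pytest.raises(ValueError):
            hypermethylation_test(t, [])


def _region_methylation(betas, name, config):
    from clustermir import RegionMethylation

    betas = np.asarray(betas, float)
    median = float(np.median(betas))
    call = ("hyper" if median > config.beta_hyper
            else "hypo" if median < config.beta_hypo else "normal")
    return RegionMethylation(
        region=GenomicRegion("chr1", 0, 100, name), n_probes=len(betas),
        beta_values=betas, median_beta=median, call=call,
    )


class TestEndToEnd:
    def test_planted_hyper_region_recovered(self):
        """Simulated genome: the flagged region is called hyper, the ten
        probe-matched random regions normal, and the one-tailed test is
        decisive."""
        spec = SimulationSpec(seed=5, n_case=20)
        target, controls = default_methylation_regions()
        probes = simulate_methylation(spec, [target, *controls])
        cfg = RunConfig(rng_seed=5)
        analysis = analyse_target_region(probes, target, None, cfg,
                                         n_random_regions=10)
        assert analysis.target.call == "hyper"
        assert analysis.target.median_beta > 0.8
        assert all(c.call == "normal" for c in analysis.controls)
        assert analysis.p_pooled < 0.003
        assert analysis.p_region_medians < 0.003

    def test_overlapping_regions_rejected_by_generator(self):
        spec = SimulationSpec(seed=0)
        a = GenomicRegion("chr1", 0, 70_000, "a")
        b = GenomicRegion("chr1", 60_000, 130_000, "b")
        with pytest.raises(ValueError, match="overlap"):
            simulate_methylation(spec, [a, b], hyper_region="a")
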