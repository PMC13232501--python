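"""Unit and property tests of the forward breeding-design simulator."""

import numpy as np
import pytest
from scipy import stats

from xopaint.config import SimulationConfig
from xopaint.origins import HI, LO
from xopaint import simkit
from xopaint.simkit import (
    CrossoverWeights,
    build_parental_snps,
    crossover_weights,
    sample_crossover_positions,
    select_extreme_pools,
    simulate_generations,
    simulate_phenotypes,
)


class TestParentalSnps:
    def test_dense_region_count_matches_poisson_mean(self, default_config):
        """Region C (2.6 Mb at 25 SNPs/10 kb) carries ~6,500 sites; the
        mean over 100 seeds must sit within 4 sigma of the Poisson mean."""
        expected = 2_600_000 * 25 / 10_000
        counts = []
        for seed in range(100):
            par = build_parental_snps(default_config, seed)
            in_c = (par.positions >= 13_900_000) & (par.positions < 16_500_000)
            counts.append(int(in_c.sum()))
        se_mean = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se_mean

    def test_zero_sparse_rate_leaves_background_empty(self, default_config):
        cfg = SimulationConfig(
            **{**default_config.to_dict(), "sparse_snp_rate": 0.0}
        )
        par = build_parental_snps(cfg, 0)
        in_dense = np.zeros(par.n_sites, bool)
        for _, s, e in cfg.dense_regions:
            in_dense |= (par.positions >= s) & (par.positions < e)
        assert in_dense.all()

    def test_default_divergence_magnitude(self, default_config):
        """Printed densities imply ~0.10% genome-wide divergence, i.e.
        >99.8% identity between the parental X's."""
        par = build_parental_snps(default_config, 3)
        assert 0.0008 < par.divergence() < 0.0013
        assert 1 - par.divergence() > 0.998

    def test_het_mask_fractions(self, default_config):
        par = build_parental_snps(default_config, 5)
        assert par.het_hi.mean() == pytest.approx(0.079, abs=0.01)
        assert par.het_lo.mean() == pytest.approx(0.058, abs=0.01)

    def test_rejects_degenerate_config(self, default_config):
        with pytest.raises(ValueError):
            SimulationConfig(**{**default_config.to_dict(), "chrom_len": 0})
        with pytest.raises(ValueError):
            SimulationConfig(
                **{
                    **default_config.to_dict(),
                    "dense_snp_rate": 0.0,
                    "sparse_snp_rate": 0.0,
                }
            )


class TestCrossoverPlacement:
    def test_no_suppression_is_uniform(self, default_config):
        cfg = SimulationConfig(
            **{**default_config.to_dict(), "suppression_factor": 1.0}
        )
        pos = sample_crossover_positions(crossover_weights(cfg), 10_000, 123)
        u = pos / cfg.chrom_len
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_zero_weight_interval_excluded(self):
        w = CrossoverWeights(
            bounds=np.array([0, 1_000_000, 2_000_000, 3_000_000]),
            weights=np.array([1.0, 0.0, 1.0]),
        )
        pos = sample_crossover_positions(w, 5_000, 9)
        assert not np.any((pos >= 1_000_000) & (pos < 2_000_000))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            CrossoverWeights(
                bounds=np.array([0, 1_000_000]), weights=np.array([0.0])
            )

    def test_suppression_ratio_recovered(self, default_config):
        """Empirical sparse:dense per-Mb hit ratio converges to 3.4."""
        cfg = default_config
        pos = sample_crossover_positions(crossover_weights(cfg), 100_000, 77)
        in_dense = np.zeros(len(pos), bool)
        dense_bp = 0
        for _, s, e in cfg.dense_regions:
            in_dense |= (pos >= s) & (pos < e)
            dense_bp += e - s
        sparse_bp = cfg.chrom_len - dense_bp
        ratio = ((~in_dense).sum() / sparse_bp) / (in_dense.sum() / dense_bp)
        assert ratio == pytest.approx(3.4, rel=0.08)


class TestGenerations:
    def test_zero_generations_pure_parental(self, small_config):
        cfg = SimulationConfig(**{**small_config.to_dict(), "generations": 0})
        cohort = simulate_generations(cfg, 1)
        assert all(c.is_pure() for c in cohort)

    def test_no_crossovers_no_mosaics(self, small_config):
        cfg = SimulationConfig(
            **{**small_config.to_dict(), "mean_cos_per_meiosis": 0.0}
        )
        cohort = simulate_generations(cfg, 2)
        assert all(c.is_pure() for c in cohort)

    def test_tracts_tile_and_alternate(self, small_config):
        for seed in range(5):
            for c in simulate_generations(small_config, seed)[:30]:
                assert c.starts[0] == 0
                assert np.all(np.diff(c.starts) > 0)
                assert c.starts[-1] < c.chrom_len
                assert np.all(c.origins[1:] != c.origins[:-1])
                assert set(np.unique(c.origins)) <= {HI, LO}

    def test_expected_breakpoints_per_fly(self, small_config):
        """A transmitted X realises ~0.5 crossover breakpoints per female
        meiosis; over ~2/3 female transmission of 15 generations that is
        ~5 lineage breakpoints per assayed male X (checked over 50 seeds)."""
        cfg = SimulationConfig(
            **{
                **small_config.to_dict(),
                "chrom_len": 23_500_000,
                "dense_regions": tuple(
                    (l, s, e) for l, s, e in SimulationConfig().dense_regions
                ),
                "causal_regions": (),
                "effect_sizes": {},
                "generations": 15,
                "pop_size": 60,
                "n_assayed_males": 10,
            }
        )
        means = [
            np.mean([len(c.lineage) for c in simulate_generations(cfg, s)])
            for s in range(50)
        ]
        # expected female-line meioses: 1 + 14 * (2/3) ~ 10.3 -> ~5.2 COs
        assert np.mean(means) == pytest.approx(5.2, abs=0.8)

    def test_extinction_rejected(self, small_config):
        with pytest.raises(ValueError):
            SimulationConfig(**{**small_config.to_dict(), "pop_size": 0})

    def test_bitwise_reproducibility(self, small_config):
        a = simulate_generations(small_config, 42)
        b = simulate_generations(small_config, 42)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.starts, y.starts)
            assert np.array_equal(x.origins, y.origins)
            assert x.lineage == y.lineage


class TestPhenotypes:
    def test_no_noise_monotone_in_causal_fraction(self, small_config):
        cfg = SimulationConfig(**{**small_config.to_dict(), "activity_sd": 0.0})
        cohort = simulate_generations(cfg, 3)
        phen = simulate_phenotypes(cohort, cfg, 4)
        s, e = 1_000_000, 2_000_000
        frac = np.array([c.hi_fraction(s, e) for c in cohort])
        order = np.argsort(frac)
        assert np.all(np.diff(phen["activity"].to_numpy()[order]) >= 0)

    def test_negative_sd_rejected(self, small_config):
        with pytest.raises(ValueError):
            SimulationConfig(**{**small_config.to_dict(), "activity_sd": -1.0})

    def test_null_effects_pools_uncorrelated_with_parentage(self, small_config):
        """With all effects zero the rank-sum test between pools on region
        parentage is null-calibrated: false-positive rate near alpha and
        p-values not systematically small (200 seeds)."""
        cfg = SimulationConfig(
            **{
                **small_config.to_dict(),
                "causal_regions": (),
                "effect_sizes": {},
                "generations": 4,
                "pop_size": 80,
                "n_assayed_males": 60,
                "pool_size": 15,
            }
        )
        pvals = []
        for seed in range(200):
            rng_root = np.random.SeedSequence(seed).spawn(2)
            cohort = simulate_generations(cfg, np.random.default_rng(rng_root[0]))
            phen = simulate_phenotypes(
                cohort, cfg, np.random.default_rng(rng_root[1])
            )
            phen = select_extreme_pools(phen, cfg.pool_size)
            frac = np.array([c.hi_fraction(1_000_000, 2_000_000) for c in cohort])
            hi = frac[(phen["pool"] == "high").to_numpy()]
            lo = frac[(phen["pool"] == "low").to_numpy()]
            pvals.append(
                stats.mannwhitneyu(hi, lo, alternative="two-sided").pvalue
            )
        pvals = np.array(pvals)
        assert (pvals < 0.05).mean() < 0.10
        assert np.median(pvals) > 0.3

    def test_default_calibration_pool_regimes(self, default_config):
        """Extreme pools land in the low-hundreds vs mid-thousands
        counts/day regime the design was calibrated to."""
        cohort = simulate_generations(default_config, 6)
        phen = simulate_phenotypes(cohort, default_config, 7)
        phen = select_extreme_pools(phen, default_config.pool_size)
        means = phen.groupby("pool")["activity"].mean()
        assert 50 < means["low"] < 400
        assert 1_000 < means["high"] < 2_200


class TestGenotyping:
    def test_noise_free_calls_match_truth(self, noise_free_study):
        cfg, study = noise_free_study
        par, cohort, calls = study["parental"], study["cohort"], study["calls"]
        for i in (0, len(cohort) // 2, len(cohort) - 1):
            origin = cohort[i].origin_at(par.positions)
            truth = np.where(origin == HI, par.hi_allele, par.lo_allele)
            assert np.array_equal(calls[i], truth)

    def test_full_dropout_all_missing(self, small_config):
        cfg = SimulationConfig(**{**small_config.to_dict(), "dropout_prob": 1.0})
        par = simkit.build_parental_snps(cfg, 0)
        cohort = simulate_generations(cfg, 0)[:10]
        calls = simkit.genotype_cohort(cohort, par, cfg, 0)
        assert np.all(calls == -1)

    def test_error_rate_binomial(self, small_config):
        cfg = SimulationConfig(
            **{
                **small_config.to_dict(),
                "dropout_prob": 0.0,
                "genotype_error_prob": 0.02,
            }
        )
        par = simkit.build_parental_snps(cfg, 1)
        cohort = simulate_generations(cfg, 1)[:40]
        calls = simkit.genotype_cohort(cohort, par, cfg, 1)
        truth = np.empty_like(calls)
        for i, c in enumerate(cohort):
            origin = c.origin_at(par.positions)
            truth[i] = np.where(origin == HI, par.hi_allele, par.lo_allele)
        n = calls.size
        rate = (calls != truth).mean()
        se = np.sqrt(0.02 * 0.98 / n)
        assert abs(rate - 0.02) < 4 * se


class TestPools:
    def test_study_scale_pools(self, default_config):
        cohort = simulate_generations(default_config, 8)
        phen = simulate_phenotypes(cohort, default_config, 8)
        phen = select_extreme_pools(phen, 45)
        assert (phen["pool"] == "low").sum() == 45
        assert (phen["pool"] == "high").sum() == 45
        assert not (
            set(phen.loc[phen["pool"] == "low", "fly_id"])
            & set(phen.loc[phen["pool"] == "high", "fly_id"])
        )

    def test_pools_are_order_statistics(self, small_config):
        cohort = simulate_generations(small_config, 9)
        phen = simulate_phenotypes(cohort, small_config, 9)
        phen = select_extreme_pools(phen, 10)
        act = phen["activity"]
        assert act[phen["pool"] == "low"].max() <= act[phen["pool"] == "unassayed"].min()
        assert act[phen["pool"] == "high"].min() >= act[phen["pool"] == "unassayed"].max()

    def test_tied_activities_split_by_id(self, small_config):
        import pandas as pd

        phen = pd.DataFrame(
            {"fly_id": [f"f{i:02d}" for i in range(30)], "activity": 100.0}
        )
        out = select_extreme_pools(phen, 5)
        assert list(out.loc[out["pool"] == "low", "fly_id"]) == [
            f"f{i:02d}" for i in range(5)
        ]
        assert list(out.loc[out["pool"] == "high", "fly_id"]) == [
            f"f{i:02d}" for i in range(25, 30)
        ]

    def test_too_few_flies_rejected(self, small_config):
        import pandas as pd

        phen = pd.DataFrame({"fly_id": ["a", "b"], "activity": [1.0, 2.0]})
        with pytest.raises(ValueError):
            select_extreme_pools(phen, 2)
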