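import numpy as np
import pytest

from yeastiron.fitting import fit_c1, fit_c4, fit_c9
from yeastiron.mb_data import POOL_NAMES, groups_from_pools, pools_from_groups
from yeastiron.synthetic import (
    SyntheticConfig,
    effective_c1_truth,
    generate_observations,
    noiseless_truth,
)


@pytest.fixture(scope="module")
def base(wt, dd):
    return {"WT": wt, "DD": dd}


@pytest.fixture(scope="module")
def c9_truth(base):
    cfg = SyntheticConfig(true_parameters=base, N_values=(2.0, 41.0))
    return cfg, noiseless_truth(cfg)


class TestNoiseFreeGeneration:
    def test_equals_model_output_exactly(self, c9_truth):
        cfg, truth = c9_truth
        records, ground = generate_observations(cfg, truth)
        for rec, entry in zip(records, truth):
            assert rec.alpha_dat == entry["alpha"]
            assert rec.Fe_cell_dat == entry["Fe_cell"]
            for k in POOL_NAMES:
                assert rec.pools_dat[k] == pytest.approx(entry["pools"][k], rel=1e-9, abs=1e-9)

    def test_passes_all_consistency_validators(self, c9_truth, geometry):
        """Noise-free synthetic records satisfy the bookkeeping the real data
        only satisfies within rounding: exact conservation, exact group
        round-trip, exact production=dilution flux algebra."""
        cfg, truth = c9_truth
        records, _ = generate_observations(cfg, truth)
        for rec in records:
            assert rec.whole_cell_from_pools() == pytest.approx(rec.Fe_cell_dat, rel=1e-9)
            back = pools_from_groups(
                groups_from_pools(rec.pools_dat, geometry), rec.pools_dat["C"], geometry
            )
            for k in POOL_NAMES:
                assert back[k] == pytest.approx(rec.pools_dat[k], rel=1e-9, abs=1e-9)
            f = rec.fluxes_dat
            assert f.R_cell == pytest.approx(rec.alpha_dat * rec.Fe_cell_dat, rel=1e-12)
            assert f.R_isu == pytest.approx(rec.alpha_dat * rec.pools_dat["FS"], rel=1e-12)


class TestDeterminism:
    def test_same_seed_same_tables(self, c9_truth):
        cfg0, truth = c9_truth
        cfg = SyntheticConfig(true_parameters=cfg0.true_parameters,
                              N_values=cfg0.N_values, noise_cv=0.1, seed=42)
        r1, _ = generate_observations(cfg, truth)
        r2, _ = generate_observations(cfg, truth)
        for a, b in zip(r1, r2):
            assert a.alpha_dat == b.alpha_dat
            assert a.pools_dat == b.pools_dat

    def test_different_seed_different_tables(self, c9_truth):
        cfg0, truth = c9_truth
        mk = lambda s: SyntheticConfig(true_parameters=cfg0.true_parameters,
                                       N_values=cfg0.N_values, noise_cv=0.1, seed=s)
        r1, _ = generate_observations(mk(1), truth)
        r2, _ = generate_observations(mk(2), truth)
        assert r1[0].alpha_dat != r2[0].alpha_dat


class TestNoiseCalibration:
    def test_empirical_cv_matches_nominal(self, c9_truth):
        """Across 200 replicates at CV=0.1 the empirical CV of each observable
        sits within 20% of nominal."""
        cfg0, truth = c9_truth
        alphas, fes, fss = [], [], []
        for seed in range(200):
            cfg = SyntheticConfig(true_parameters=cfg0.true_parameters,
                                  N_values=cfg0.N_values, noise_cv=0.1, seed=seed)
            recs, _ = generate_observations(cfg, truth)
            alphas.append(recs[0].alpha_dat)
            fes.append(recs[0].Fe_cell_dat)
            fss.append(recs[0].pools_dat["FS"])
        for vals in (alphas, fes, fss):
            cv = np.std(vals) / np.mean(vals)
            assert 0.08 <= cv <= 0.12

    def test_unit_mean_noise(self, c9_truth):
        cfg0, truth = c9_truth
        vals = []
        for seed in range(300):
            cfg = SyntheticConfig(true_parameters=cfg0.true_parameters,
                                  N_values=(41.0,), noise_cv=0.2, seed=seed)
            recs, ground = generate_observations(cfg, truth[1:2])
            vals.append(recs[0].alpha_dat / ground[0]["alpha"])
        assert np.mean(vals) == pytest.approx(1.0, abs=0.03)


class TestSelfConsistentRecovery:
    """Each fitting stage, given noise-free observations generated by its own
    tier, starts at zero error and leaves the truth (essentially) untouched."""

    def test_c1_stage(self, base):
        cfg = SyntheticConfig(true_parameters=base, source_tier="C1",
                              N_values=(1.0, 2.0, 11.0, 41.0))
        records, _ = generate_observations(cfg)
        res = fit_c1(records, base, schedule=(0.01,))
        assert res.err_value <= 1e-3
        for key, v in res.parameters.items():
            name = key.split("@")[0]
            truth = getattr(base["WT" if "WT" in key else "DD"], name)
            assert abs(v / truth - 1.0) <= 0.0101, key

    def test_c4_stage(self, base):
        cfg = SyntheticConfig(true_parameters=base, source_tier="C4",
                              N_values=(1.0, 2.0, 11.0, 41.0))
        records, _ = generate_observations(cfg)
        res = fit_c4(records, base, schedule=(0.01,))
        assert res.err_value <= 1e-3
        assert res.parameters["R_cia_max"] == pytest.approx(56.0, rel=0.0101)

    def test_c9_stage(self, base):
        cfg = SyntheticConfig(true_parameters=base, source_tier="C9",
                              N_values=(2.0, 41.0))
        records, _ = generate_observations(cfg)
        # base already carries the true full-model k_mit; the coarse-tier
        # rescale would displace the start from the generating optimum
        res = fit_c9(records, base, schedule=(0.01,), max_sweeps=1, rescale_k_mit=False)
        assert res.err_value <= 1e-3
        for key, v in res.parameters.items():
            name = key.split("@")[0]
            truth = getattr(base["WT" if "WT" in key else "DD"], name)
            assert abs(v / truth - 1.0) <= 0.0101, key


class TestEffectiveTruth:
    def test_compartmental_source_rescales_import_vmax(self, base, geometry):
        cfg = SyntheticConfig(true_parameters=base)
        eff = effective_c1_truth(cfg)
        assert eff["WT"]["R_cell_max"] == pytest.approx(geometry.f_cyt * 230.0)
        assert eff["WT"]["alpha_max"] == base["WT"].alpha_max

    def test_c1_source_keeps_printed_vmax(self, base):
        cfg = SyntheticConfig(true_parameters=base, source_tier="C1")
        eff = effective_c1_truth(cfg)
        assert eff["DD"]["R_cell_max"] == 390.0
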