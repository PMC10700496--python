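"""Design enumeration, evaluation formulas and the study runner."""

import numpy as np
import pytest

from bayes2pl import (
    ChainSpec,
    DesignGrid,
    aggregate_item_parameters,
    apply_discard_rules,
    bias,
    build_design_grid,
    conditional_mean_table,
    rmse,
    run_study,
)
from bayes2pl.simstudy import ReplicationRecord


class TestDesignGrid:
    def test_full_crossing_has_864_cells(self):
        grid = build_design_grid()
        assert len(grid) == 864
        assert sum(1 for _ in grid.cells()) == 864

    def test_single_sample_size_has_144_cells(self):
        assert len(build_design_grid(sample_sizes=(100,))) == 144

    def test_cell_ids_unique(self):
        ids = [c.cell_id for c in build_design_grid().cells()]
        assert len(set(ids)) == 864


class TestEvaluationFormulas:
    def test_bias_examples(self):
        assert bias(1.0, 1.0) == 0.0
        assert bias(1.2, 1.0) == pytest.approx(0.2, abs=1e-15)
        assert bias(3.1, 0.4) == -bias(0.4, 3.1)

    def test_rmse_examples(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([1.0, 3.0], [2.0, 2.0]) == pytest.approx(1.0, abs=1e-15)
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])

    def test_rmse_squared_decomposition(self, rng):
        """rmse^2 = mean(bias)^2 + var(bias) with the n denominator."""
        for _ in range(10):
            est = rng.normal(size=17)
            tru = rng.normal(size=17)
            dev = bias(est, tru)
            assert rmse(est, tru) ** 2 == pytest.approx(
                dev.mean() ** 2 + dev.var(ddof=0), abs=1e-12)


class TestAggregation:
    def _rec(self, rep, dev_items, dev_tau=(0.0, 0.0), usable=True, model="m"):
        d = np.asarray(dev_items, dtype=float)
        return ReplicationRecord("cell", rep, model, usable, dev_alpha=d,
                                 dev_beta=d.copy(), dev_theta=np.zeros(2),
                                 dev_tau_alpha=dev_tau[0], dev_tau_beta=dev_tau[1])

    def test_perfect_estimates_give_zero_summaries(self):
        out = aggregate_item_parameters([self._rec(r, [0.0, 0.0]) for r in range(3)])
        assert out["bias_alpha"] == 0.0 and out["rmse_alpha"] == 0.0
        assert out["bias_tau_alpha"] == 0.0

    def test_constructed_deviations_hand_oracle(self):
        """Two items deviating +-0.1: item-averaged bias 0, average RMSE 0.1."""
        recs = [self._rec(0, [0.1, -0.1]), self._rec(1, [0.1, -0.1])]
        out = aggregate_item_parameters(recs)
        assert out["bias_alpha"] == pytest.approx(0.0, abs=1e-15)
        assert out["rmse_alpha"] == pytest.approx(0.1, abs=1e-15)

    def test_replication_order_irrelevant(self, rng):
        recs = [self._rec(r, rng.normal(size=4), dev_tau=tuple(rng.normal(size=2)))
                for r in range(6)]
        a = aggregate_item_parameters(recs)
        b = aggregate_item_parameters(recs[::-1])
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-14)

    def test_empty_cell_flagged(self):
        out = aggregate_item_parameters([self._rec(0, [0.1], usable=False)])
        assert out["empty"] is True and out["n_used"] == 0


class TestDiscardRules:
    def _recs(self, flags):
        return [ReplicationRecord("c", i, "m", usable=f) for i, f in enumerate(flags)]

    def test_all_converged_all_kept(self):
        usable, rates = apply_discard_rules(self._recs([True] * 10))
        assert len(usable) == 10 and rates["m"] == 0.0

    def test_rates_and_retention(self):
        usable, rates = apply_discard_rules(self._recs([False] * 3 + [True] * 7))
        assert len(usable) == 7
        assert rates["m"] == pytest.approx(0.3)

    def test_discarded_never_reach_aggregation(self):
        recs = self._recs([False, True])
        recs[0].dev_alpha = np.array([99.0])
        recs[1].dev_alpha = np.array([0.0])
        recs[1].dev_beta = np.array([0.0])
        recs[1].dev_theta = np.array([0.0])
        usable, _ = apply_discard_rules(recs)
        out = aggregate_item_parameters(usable)
        assert out["bias_alpha"] == 0.0


class TestConditionalMeans:
    def test_equal_values(self):
        cmean, dev = conditional_mean_table({s: 0.2 for s in ("WI1", "WI2", "NI1", "NI2")})
        assert cmean == pytest.approx(0.2)
        assert all(v == 0.0 for v in dev.values())

    def test_printed_example(self):
        cmean, dev = conditional_mean_table(
            dict(WI1=0.1, WI2=0.2, NI1=0.3, NI2=0.4))
        assert cmean == pytest.approx(0.25)
        assert sum(dev.values()) == pytest.approx(0.0, abs=1e-15)

    def test_partial_cell_rejected(self):
        with pytest.raises(ValueError):
            conditional_mean_table(dict(WI1=0.1, WI2=0.2, NI1=0.3))


class TestStudyRunner:
    SMOKE = dict(sample_sizes=(40,), test_lengths=(8,),
                 tau_pairs=((0.25, 0.90),), rhos=(0.3,),
                 families=("exponential",), spec_labels=("WI2",),
                 replications=2)
    CHAINS = ChainSpec(n_chains=2, n_iterations=200, n_burnin=90, seed=0,
                       max_leapfrog=12)

    def test_smoke_run_emits_one_condition_result(self):
        grid = build_design_grid(**self.SMOKE)
        results = list(run_study(grid, ["oh2pl", "mml"], self.CHAINS, master_seed=3))
        assert len(results) == 1
        res = results[0]
        assert set(res.per_model) == {"oh2pl:exponential:WI2", "mml"}
        assert 0.0 <= res.rates["mml"] <= 1.0
        summ = res.per_model["oh2pl:exponential:WI2"]
        if not summ["empty"]:
            assert np.isfinite(summ["bias_alpha"])
            assert summ["rmse_alpha"] >= 0.0

    def test_rerun_with_same_master_seed_identical(self):
        grid = build_design_grid(**self.SMOKE)
        r1 = list(run_study(grid, ["oh2pl"], self.CHAINS, master_seed=7))
        r2 = list(run_study(grid, ["oh2pl"], self.CHAINS, master_seed=7))
        s1 = r1[0].per_model["oh2pl:exponential:WI2"]
        s2 = r2[0].per_model["oh2pl:exponential:WI2"]
        assert s1 == s2

    def test_rmse_decreases_with_sample_size(self):
        """Item-parameter RMSE shrinks from N=50 to N=500 at fixed k
        (typical variances, 10 replications each)."""
        from bayes2pl import (GeneratingCondition, Hierarchical2PL,
                              HyperpriorConfig, generate_dataset)

        config = HyperpriorConfig.from_label("exponential", "WI2")
        rmses = {}
        for n in (50, 500):
            dev_a, dev_b = [], []
            for rep in range(10):
                ds = generate_dataset(GeneratingCondition(n, 25, (0.25, 0.90), 0.3,
                                                          seed=4000 + rep))
                res = Hierarchical2PL(ds.responses, config).fit(
                    ChainSpec(n_chains=3, n_iterations=500, n_burnin=220,
                              seed=6000 + rep, max_leapfrog=16))
                dev_a.append(res.posterior_mean("alpha") - ds.items.alpha)
                dev_b.append(res.posterior_mean("beta") - ds.items.beta)
            rmses[n] = (float(np.mean(np.sqrt(np.mean(np.vstack(dev_a) ** 2, axis=0)))),
                        float(np.mean(np.sqrt(np.mean(np.vstack(dev_b) ** 2, axis=0)))))
        assert rmses[500][0] < rmses[50][0]
        assert rmses[500][1] < rmses[50][1]

    def test_checkpoint_resume_skips_finished_records(self, tmp_path):
        grid = build_design_grid(**self.SMOKE)
        ckpt = tmp_path / "ck.jsonl"
        r1 = list(run_study(grid, ["mml"], self.CHAINS, master_seed=1,
                            checkpoint_path=ckpt))
        n_lines = len(ckpt.read_text().splitlines())
        r2 = list(run_study(grid, ["mml"], self.CHAINS, master_seed=1,
                            checkpoint_path=ckpt))
        assert len(ckpt.read_text().splitlines()) == n_lines  # nothing recomputed
        assert r1[0].per_model["mml"] == pytest.approx(r2[0].per_model["mml"])
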