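"""Best-first search: greedy semantics, convergence, caching, multi-start."""

import numpy as np
import pytest

from nloswitch.bfs_optimizer import (
    BFSConfig,
    multi_start_driver,
    optimize_site,
    run_bfs,
)
from nloswitch.property_oracle import (
    LandscapeSpec,
    SwitchEvaluator,
    SyntheticOracle,
    fixture_landscape_26r,
    random_landscape,
    separable_landscape,
)
from nloswitch.scaffold_space import enumerate_space, parse_pattern, toy_scaffold


def exhaustive_argmax(evaluator, scaffold):
    best_name, best_value = None, -np.inf
    for pattern in enumerate_space(scaffold, max_size=5000):
        value = evaluator.evaluate(pattern).value
        if value > best_value:
            best_name, best_value = pattern.canonical_name, value
    return best_name, best_value


def random_start(scaffold, rng):
    assignment = {
        s.name: rng.choice(scaffold.allowed(s.name)) for s in scaffold.site_sets
    }
    name = "_".join(assignment[s.name] for s in scaffold.site_sets)
    return parse_pattern(name, scaffold)


class TestOptimizeSite:
    def test_fixture_landscape_site_step(self, fixture_evaluator_26r):
        """From the donor-substituted intermediate, the acceptor wins
        the R2,5 site with the published optimum contrast."""
        scaffold = fixture_evaluator_26r.scaffold
        current = parse_pattern("NH_NH_NH2_H_NH2", scaffold)
        best, steps = optimize_site(current, "R2,5", fixture_evaluator_26r)
        assert best.canonical_name == "NH_NH_NH2_CN_NH2"
        accepted = [s for s in steps if s.accepted]
        assert len(accepted) == 1
        assert accepted[0].value == pytest.approx(5.99e4)
        # candidate count equals the meso library size
        assert len(steps) == 7

    def test_all_equal_keeps_incumbent(self, small_scaffold):
        spec = LandscapeSpec(seed=0, off_state="OFF", base={"ON": 10.0}, on_cap=None)
        oracle = SyntheticOracle(spec, small_scaffold)
        ev = SwitchEvaluator(oracle, small_scaffold, metric="revised")
        current = parse_pattern("CN_H_H", small_scaffold)
        best, steps = optimize_site(current, "R1", ev, tie_policy="keep-incumbent")
        assert best.canonical_name == "CN_H_H"
        best2, _ = optimize_site(current, "R1", ev, tie_policy="first-in-library")
        assert best2.canonical_name == "H_H_H"

    def test_single_fragment_site_returns_input(self, fixture_evaluator_26r):
        scaffold = fixture_evaluator_26r.scaffold
        current = parse_pattern("NH_NH_H_H_H", scaffold)
        best, steps = optimize_site(current, "X", fixture_evaluator_26r)
        assert best.canonical_name == current.canonical_name
        assert len(steps) == 1  # only NH is valid on X for 26R


class TestRunBFS:
    def test_published_run_reaches_published_optimum(self, fixture_oracle_26r):
        """Replay of the published 26R search: start NH_O_NH2_F_OH,
        site sequence (R3,6; R1,4; Y; R2,5)."""
        oracle, scaffold = fixture_oracle_26r
        cfg = BFSConfig(
            scaffold,
            "NH_O_NH2_F_OH",
            metric="revised",
            site_sequence=("R3,6", "R1,4", "Y", "R2,5"),
        )
        traj = run_bfs(cfg, oracle)
        assert traj.converged
        assert traj.optimum.canonical_name == "NH_NH_NH2_CN_NH2"
        assert traj.optimum_value == pytest.approx(5.99e4)

    def test_varied_core_starts_reach_same_optimum(self, fixture_oracle_26r):
        oracle, scaffold = fixture_oracle_26r
        for start in ("NH_S_NH2_F_OH", "NH_Se_NH2_F_OH", "NH_NH_CN_CN_CN"):
            cfg = BFSConfig(scaffold, start, metric="revised")
            traj = run_bfs(cfg, oracle)
            assert traj.optimum.canonical_name == "NH_NH_NH2_CN_NH2"

    def test_separable_landscape_equals_exhaustive_from_any_start(
        self, small_scaffold
    ):
        spec = separable_landscape(small_scaffold, seed=42)
        oracle = SyntheticOracle(spec, small_scaffold)
        ev = SwitchEvaluator(oracle, small_scaffold, metric="revised")
        best_name, best_value = exhaustive_argmax(ev, small_scaffold)
        rng = np.random.default_rng(0)
        for _ in range(20):
            start = random_start(small_scaffold, rng)
            traj = run_bfs(BFSConfig(small_scaffold, start), oracle)
            assert traj.converged
            assert traj.optimum.canonical_name == best_name
            assert traj.optimum_value == pytest.approx(best_value)
            # one improving sweep plus one confirming sweep suffices
            assert traj.global_iterations <= 2

    def test_bfs_never_beats_exhaustive_maximum(self, small_scaffold):
        rng = np.random.default_rng(1)
        for seed in range(5):
            spec = random_landscape(small_scaffold, seed=seed)
            oracle = SyntheticOracle(spec, small_scaffold)
            ev = SwitchEvaluator(oracle, small_scaffold, metric="revised")
            _, best_value = exhaustive_argmax(ev, small_scaffold)
            traj = run_bfs(
                BFSConfig(small_scaffold, random_start(small_scaffold, rng)),
                oracle,
            )
            assert traj.optimum_value <= best_value + 1e-9

    def test_greedy_monotonicity(self, small_scaffold):
        spec = random_landscape(small_scaffold, seed=9)
        oracle = SyntheticOracle(spec, small_scaffold)
        traj = run_bfs(BFSConfig(small_scaffold, "H_H_H"), oracle)
        accepted = traj.accepted_values()
        assert all(b >= a - 1e-12 for a, b in zip(accepted, accepted[1:]))
        assert traj.steps[-1].global_iteration == traj.global_iterations

    def test_start_at_optimum_converges_in_one_sweep(self, fixture_oracle_26r):
        oracle, scaffold = fixture_oracle_26r
        cfg = BFSConfig(scaffold, "NH_NH_NH2_CN_NH2")
        traj = run_bfs(cfg, oracle)
        assert traj.converged
        assert traj.global_iterations == 1

    def test_cache_equivalence(self, small_scaffold):
        """Cached and cache-disabled runs walk identical trajectories,
        but caching removes repeated oracle work."""
        spec = random_landscape(small_scaffold, seed=4)

        def run(use_cache):
            oracle = SyntheticOracle(spec, small_scaffold)
            traj = run_bfs(
                BFSConfig(small_scaffold, "H_H_H"), oracle, use_cache=use_cache
            )
            log = [
                (s.global_iteration, s.site, s.fragment, s.value, s.accepted)
                for s in traj.steps
            ]
            return traj, log, oracle.calls

        cached, log_c, calls_c = run(True)
        uncached, log_u, calls_u = run(False)
        assert log_c == log_u
        assert cached.optimum.canonical_name == uncached.optimum.canonical_name
        assert calls_c < calls_u
        assert cached.evaluations <= calls_c

    def test_determinism(self, small_scaffold):
        spec = random_landscape(small_scaffold, seed=17)
        runs = []
        for _ in range(2):
            oracle = SyntheticOracle(spec, small_scaffold)
            traj = run_bfs(BFSConfig(small_scaffold, "H_CN_H"), oracle)
            runs.append(
                [(s.site, s.fragment, s.value, s.accepted) for s in traj.steps]
            )
        assert runs[0] == runs[1]

    def test_nonconvergence_reported_not_raised(self, small_scaffold):
        spec = random_landscape(small_scaffold, seed=2)
        oracle = SyntheticOracle(spec, small_scaffold)
        cfg = BFSConfig(small_scaffold, "H_H_H", max_global_iterations=1)
        traj = run_bfs(cfg, oracle)
        assert traj.converged is False

    def test_bad_site_sequence_rejected(self, small_scaffold):
        with pytest.raises(ValueError):
            BFSConfig(small_scaffold, "H_H_H", site_sequence=("R1", "R2"))


class TestMultiStart:
    def test_merged_database_deduplicates(self, fixture_oracle_26r):
        oracle, scaffold = fixture_oracle_26r
        configs = [
            BFSConfig(scaffold, "NH_O_NH2_F_OH"),
            BFSConfig(scaffold, "NH_S_NH2_F_OH"),
        ]
        result = multi_start_driver(configs, oracle)
        assert result.database.pattern.is_unique
        visited = {
            s.pattern.canonical_name
            for t in result.trajectories
            for s in t.steps
        }
        assert len(result.database) == len(visited)

    def test_two_basin_landscape_reports_both_optima(self, small_scaffold):
        """Two incompatible synergy peaks: starts in each basin find
        their own optimum; exhaustive enumeration confirms both are
        local maxima and identifies the global one."""
        additive = {("ON", f"R{i}", frag): 0.0
                    for i in (1, 2, 3)
                    for frag in ("H", "OH", "NH2", "CN")}
        additive[("ON", "R1", "NH2")] = 100.0
        additive[("ON", "R1", "CN")] = 90.0
        synergy = {
            ("ON", "R1", "NH2", "R2", "NH2"): 500.0,
            ("ON", "R1", "CN", "R2", "CN"): 480.0,
        }
        spec = LandscapeSpec(
            seed=0,
            off_state="OFF",
            base={"ON": 1000.0},
            additive=additive,
            synergy=synergy,
            on_cap=None,
        )
        oracle = SyntheticOracle(spec, small_scaffold)
        configs = [
            BFSConfig(small_scaffold, "NH2_NH2_H"),
            BFSConfig(small_scaffold, "CN_CN_H"),
        ]
        result = multi_start_driver(configs, oracle)
        optima = set(result.optima.pattern)
        assert optima == {"NH2_NH2_H", "CN_CN_H"}
        assert result.best_pattern == "NH2_NH2_H"
        assert result.basin_fraction == pytest.approx(0.5)

    def test_empty_config_list_rejected(self, fixture_oracle_26r):
        oracle, _ = fixture_oracle_26r
        with pytest.raises(ValueError):
            multi_start_driver([], oracle)
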