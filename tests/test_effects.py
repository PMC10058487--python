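import numpy as np
import pytest

from blockpath import (
    CVConfig,
    PathDiagram,
    global_effect,
    partial_effect,
    residualize,
    run_path,
    scale_unit_variance,
    training_global_effect,
    training_partial_effect,
    generate_multiblock,
    generate_trivariate,
    SyntheticSpec,
)


def sample_correlations(a, b, c):
    """Sample correlation triple (r_AB, r_AC, r_BC) from data columns."""
    r = np.corrcoef(np.column_stack([a, b, c]).T)
    return r[0, 1], r[0, 2], r[1, 2]


class TestTrainingOracles:
    """In the unidimensional case the method must reduce exactly to the
    squared correlation (global) and squared partial correlation (partial)."""

    def test_global_equals_squared_correlation(self):
        A, B, C = generate_trivariate((0.3, 0.6, 0.4), n=150, seed=5)
        a, c = A.values.ravel(), C.values.ravel()
        r_ac = np.corrcoef(a, c)[0, 1]
        assert training_global_effect(A.values, C.values) == pytest.approx(
            r_ac**2, abs=1e-10
        )

    def test_partial_equals_squared_partial_correlation(self):
        A, B, C = generate_trivariate((0.5, 0.5, 0.5), n=200, seed=8)
        a, b, c = (x.values.ravel() for x in (A, B, C))
        r_ab, r_ac, r_bc = sample_correlations(a, b, c)
        expected = (
            (r_ac - r_ab * r_bc) / np.sqrt((1 - r_ab**2) * (1 - r_bc**2))
        ) ** 2
        assert training_partial_effect(A.values, C.values, B.values) == pytest.approx(
            expected, abs=1e-10
        )

    def test_many_random_correlation_specs(self, rng):
        """Oracle equivalence across a sweep of random PSD correlation
        structures (sample correlations are the exact finite-n truth)."""
        for trial in range(30):
            # random PSD correlation matrix via random factor structure
            load = rng.normal(size=(3, 2))
            cov = load @ load.T + np.diag(rng.uniform(0.1, 1.0, 3))
            d = np.sqrt(np.diag(cov))
            corr = cov / np.outer(d, d)
            draws = rng.multivariate_normal(np.zeros(3), corr, size=60)
            a, b, c = draws[:, 0], draws[:, 1], draws[:, 2]
            r_ab, r_ac, r_bc = sample_correlations(a, b, c)
            g = training_global_effect(a[:, None], c[:, None])
            p = training_partial_effect(a[:, None], c[:, None], b[:, None])
            exp_p = (
                (r_ac - r_ab * r_bc) / np.sqrt((1 - r_ab**2) * (1 - r_bc**2))
            ) ** 2
            assert g == pytest.approx(r_ac**2, abs=1e-8)
            assert p == pytest.approx(exp_p, abs=1e-8)


class TestGlobalEffect:
    def test_self_prediction_near_100(self, rng):
        A = rng.normal(size=(60, 3))
        C = A[:, 0]
        cv = CVConfig(seed=3, k=6, repeats=5)
        est = global_effect(A, C, cv)
        assert est.mean_percent >= 99.0
        assert est.kind == "global"

    def test_recovers_population_squared_correlation(self):
        A, _, C = generate_trivariate((0.0, 0.6, 0.0), n=500, seed=21)
        cv = CVConfig(seed=9, k=10, repeats=5, max_components=1)
        est = global_effect(A, C.values, cv)
        assert est.mean_percent == pytest.approx(36.0, abs=5.0)


class TestResidualize:
    def test_target_in_block_leaves_no_residual(self, rng):
        B = rng.normal(size=(50, 4))
        target = B[:, 2].copy()
        cv = CVConfig(seed=5, k=5, repeats=3)
        res = residualize(target, B, cv)
        centered = target - target.mean()
        assert np.linalg.norm(res.values) <= 1e-6 * np.linalg.norm(centered)

    def test_independent_target_keeps_its_variance(self, rng):
        B = rng.normal(size=(500, 3))
        target = rng.normal(size=500)
        cv = CVConfig(seed=5, k=10, repeats=3)
        res = residualize(target, B, cv, n_components=1)
        corr = np.corrcoef(target, res.values.ravel())[0, 1]
        assert corr >= 0.95

    def test_residual_means_are_zero(self, rng):
        B = rng.normal(size=(40, 5))
        target = B @ rng.normal(size=(5, 2)) + rng.normal(size=(40, 2))
        res = residualize(target, B, CVConfig(seed=1, k=5, repeats=3))
        np.testing.assert_allclose(res.values.mean(axis=0), 0.0, atol=1e-10)


class TestPartialEffect:
    def test_recovers_squared_partial_correlation(self):
        A, B, C = generate_trivariate((0.5, 0.5, 0.5), n=1000, seed=33)
        strata = tuple((C.values.ravel() > 0).astype(int))
        cv = CVConfig(seed=7, k=10, repeats=5, strata=strata)
        est = partial_effect(A, C.values, B, cv)
        # population squared partial correlation = (1/3)^2 = 11.1%
        assert est.mean_percent == pytest.approx(11.1, abs=5.0)
        assert est.kind == "partial"
        assert est.n_components_CB == 1 and est.n_components_AB == 1

    def test_markov_chain_has_zero_partial_effect(self):
        # r_AC = r_AB * r_BC: C independent of A given B
        A, B, C = generate_trivariate((0.9, 0.81, 0.9), n=800, seed=14)
        cv = CVConfig(seed=8, k=10, repeats=5)
        est = partial_effect(A, C.values, B, cv)
        assert est.mean_percent <= 5.0

    def test_degenerate_mediator_returns_zero_with_warning(self, rng):
        A = rng.normal(size=(40, 2))
        B = A.copy()  # mediator reproduces the input exactly
        C = A[:, 0] + rng.normal(size=40)
        cv = CVConfig(seed=2, k=5, repeats=3)
        with pytest.warns(UserWarning, match="degenerate"):
            est = partial_effect(A, C, B, cv, n_components_AB=2)
        assert est.degenerate
        assert est.mean_percent == 0.0

    def test_independent_mediator_leaves_effect_unchanged(self, rng):
        # B independent of A and C: partial ~ global
        A = rng.normal(size=(400, 2))
        B = rng.normal(size=(400, 3))
        C = A[:, 0] + rng.normal(size=400)
        cv = CVConfig(seed=6, k=10, repeats=5)
        g = global_effect(A, C, cv)
        p = partial_effect(A, C, B, cv)
        assert abs(g.mean_percent - p.mean_percent) <= 5.0

    def test_nested_variant_agrees_roughly_with_default(self):
        A, B, C = generate_trivariate((0.5, 0.5, 0.5), n=400, seed=3)
        cv = CVConfig(seed=4, k=10, repeats=3)
        default = partial_effect(A, C.values, B, cv)
        nested = partial_effect(A, C.values, B, cv, nested=True)
        assert abs(default.mean_percent - nested.mean_percent) <= 5.0


@pytest.fixture(scope="module")
def dataset():
    spec = SyntheticSpec(
        seed=17, n_samples=80, p_A=4, p_B=12, n_latents=3,
        mediation_scenario="shared_plus_unique",
    )
    A, B, outcome, _ = generate_multiblock(spec)
    return scale_unit_variance(A), scale_unit_variance(B), outcome


class TestRunPath:
    def make_report(self, dataset, seed=5):
        A, B, outcome = dataset
        diagram = PathDiagram("A", "B", "y", name="p1")
        cv = CVConfig(seed=seed, k=5, repeats=3, max_components=4)
        return run_path(
            diagram, {"A": A, "B": B}, outcome, cv, n_boot=25,
            unscaled_blocks={"A": A},
        )

    def test_report_is_complete(self, dataset):
        rep = self.make_report(dataset)
        assert rep.global_estimate.kind == "global"
        assert rep.partial_estimate.kind == "partial"
        assert len(rep.vip_global.variable_ids) == 4
        assert all(v.endswith("residual") for v in rep.vip_partial.variable_ids)
        assert set(rep.log2_fc) == {"A1", "A2", "A3", "A4"}

    def test_role_swap_changes_only_assignment(self, dataset):
        A, B, outcome = dataset
        cv = CVConfig(seed=5, k=5, repeats=3, max_components=3)
        swapped = PathDiagram("B", "A", "y", name="p2")
        rep = run_path(swapped, {"A": A, "B": B}, outcome, cv, n_boot=10)
        assert len(rep.vip_global.variable_ids) == 12

    def test_outcome_coding_swap_invariance(self, dataset):
        from blockpath import encode_outcome

        A, B, outcome = dataset
        flipped = encode_outcome(
            outcome.sample_ids, outcome.labels, case_label=outcome.control_label
        )
        cv = CVConfig(seed=5, k=5, repeats=3, max_components=4)
        diagram = PathDiagram("A", "B", "y", name="p1")
        r1 = run_path(diagram, {"A": A, "B": B}, outcome, cv, n_boot=10)
        r2 = run_path(diagram, {"A": A, "B": B}, flipped, cv, n_boot=10)
        assert r1.global_estimate.mean_percent == pytest.approx(
            r2.global_estimate.mean_percent, abs=1e-10
        )
        assert r1.partial_estimate.mean_percent == pytest.approx(
            r2.partial_estimate.mean_percent, abs=1e-10
        )

    def test_report_round_trips_through_serialization(self, dataset, tmp_path):
        from blockpath import read_report, write_report

        rep = self.make_report(dataset)
        path = tmp_path / "report.json"
        write_report(rep, path)
        back = read_report(path)
        assert back.to_dict() == rep.to_dict()


class TestInvariants:
    def test_partial_invariant_to_mediator_rescaling_at_full_rank(self, rng):
        A = rng.normal(size=(100, 2))
        B = rng.normal(size=(100, 3)) + A[:, [0]]
        C = A @ np.array([1.0, -0.5]) + B @ np.array([0.3, 0.2, 0.1])
        scale = np.diag([2.0, 0.5, 7.0])
        p1 = training_partial_effect(A, C[:, None], B, n_components=2,
                                     n_components_resid=3)
        p2 = training_partial_effect(A, C[:, None], B @ scale, n_components=2,
                                     n_components_resid=3)
        assert p1 == pytest.approx(p2, abs=1e-8)

    def test_effects_reproducible_with_fixed_seed(self):
        A, B, C = generate_trivariate((0.4, 0.5, 0.3), n=200, seed=2)
        cv = CVConfig(seed=31, k=5, repeats=4)
        e1 = partial_effect(A, C.values, B, cv)
        e2 = partial_effect(A, C.values, B, cv)
        assert e1 == e2
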