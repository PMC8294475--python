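"""Local optimization, multi-start, superspace checks, and greedy splitting."""

import numpy as np
import pytest

from ljtypes.chem import build_model, refinement_relation
from ljtypes.core import LJParameterSet, from_math, to_math
from ljtypes.objective import total_objective
from ljtypes.optimize import (
    OptConfig,
    consistency_check,
    embed_coarse_optimum,
    exhaustive_pair_search,
    greedy_split_search,
    multi_start,
    optimize,
)
from ljtypes.synth import SurrogateObjective, make_split, make_study


def quadratic_objective(center, weight=50.0):
    """Convex quadratic surrogate with known minimizer in k-space."""

    def fn(params):
        k = to_math(params)
        value = weight * float((k - center) @ (k - center))
        return total_objective({"quad": value}, k, w_reg=0.0)

    return fn


def double_well_objective(offset=0.05):
    """Two-basin surrogate along one r_1/2 coordinate, convex elsewhere.

    The well sits on k[1] (a radius coordinate) so basin centers at k = +-1
    stay inside the physical domain.
    """

    def fn(params):
        k = to_math(params)
        rest = np.concatenate([k[:1], k[2:]])
        value = (k[1] ** 2 - 1.0) ** 2 + offset * k[1] + 1.0 + float(rest @ rest)
        return total_objective({"well": value}, k, w_reg=0.0)

    return fn


class TestOptimize:
    def test_recovers_quadratic_minimum(self):
        model = build_model("HCON")
        start = LJParameterSet.from_model(model)
        center = np.full(start.n_params, 0.4)
        cfg = OptConfig(step_tol=1e-4, objective_tol=1e-8, max_iter=100)
        result = optimize(model, start, quadratic_objective(center), cfg)
        assert np.allclose(to_math(result.params), center, atol=cfg.step_tol)

    def test_start_at_optimum_terminates_immediately(self):
        model = build_model("HCON")
        start = LJParameterSet.from_model(model)
        center = np.zeros(start.n_params)
        result = optimize(model, start, quadratic_objective(center), OptConfig())
        assert len(result.trace) <= 2
        assert result.termination in ("step-tol", "objective-tol")

    def test_two_basins_two_endpoints(self):
        model = build_model("HCON")
        ref = LJParameterSet.from_model(model)
        fn = double_well_objective()
        cfg = OptConfig(step_tol=1e-5, objective_tol=1e-9, max_iter=200)
        starts = []
        for k1 in (1.2, -1.2):
            k = np.zeros(ref.n_params)
            k[1] = k1
            starts.append(from_math(k, ref))
        res_pos = optimize(model, starts[0], fn, cfg)
        res_neg = optimize(model, starts[1], fn, cfg)
        k_pos = to_math(res_pos.params)[1]
        k_neg = to_math(res_neg.params)[1]
        assert k_pos > 0.5 and k_neg < -0.5  # distinct terminal parameter sets
        assert res_pos.objective != pytest.approx(res_neg.objective, abs=1e-3)

    def test_trace_non_increasing(self):
        model = build_model("HCON")
        start = LJParameterSet.from_model(model)
        center = np.full(start.n_params, 0.7)
        result = optimize(model, start, quadratic_objective(center), OptConfig())
        objectives = [obj for _k, obj in result.trace]
        assert all(b <= a + 1e-12 for a, b in zip(objectives, objectives[1:]))

    def test_non_finite_objective_aborts(self):
        model = build_model("HCON")
        start = LJParameterSet.from_model(model)

        def bad(params):
            return total_objective({"bad": float("nan")}, to_math(params), 0.0)

        with pytest.raises(FloatingPointError):
            optimize(model, start, bad, OptConfig())

    def test_gradient_descent_variant(self):
        model = build_model("HCON")
        start = LJParameterSet.from_model(model)
        center = np.full(start.n_params, 0.3)
        cfg = OptConfig(
            step_tol=1e-4, objective_tol=1e-8, max_iter=500, method="gradient-descent"
        )
        result = optimize(model, start, quadratic_objective(center), cfg)
        assert np.allclose(to_math(result.params), center, atol=0.01)


class TestMultiStart:
    def test_identical_starts_identical_results(self):
        model = build_model("HCON")
        start = LJParameterSet.from_model(model)
        fn = quadratic_objective(np.full(start.n_params, 0.2))
        ms = multi_start(model, start, fn, OptConfig(), n_replicates=3)
        objs = [r.objective for r in ms.replicates]
        assert objs[0] == objs[1] == objs[2]

    def test_best_is_minimum_of_replicates(self):
        model = build_model("HCON")
        ref = LJParameterSet.from_model(model)
        fn = double_well_objective()
        ms = multi_start(
            model,
            ref,
            fn,
            OptConfig(step_tol=1e-5, objective_tol=1e-8, max_iter=200),
            n_replicates=3,
            seeds=[3, 5, 8],
            start_perturbation=1.5,
        )
        assert ms.best.objective == min(r.objective for r in ms.replicates)
        lo, hi = ms.objective_range
        assert lo <= hi

    def test_needs_one_replicate(self):
        model = build_model("HCON")
        start = LJParameterSet.from_model(model)
        with pytest.raises(ValueError):
            multi_start(model, start, quadratic_objective(np.zeros(8)), n_replicates=0)


@pytest.fixture(scope="module")
def fitted_pair(study40):
    """HCO3N (coarse) and H2CO3N (fine) both fit on the same training data."""
    train, _test = make_split(study40.library, 1, seed=5)
    cfg = OptConfig(step_tol=1e-4, objective_tol=1e-5, max_iter=200)
    results = {}
    for name in ("HCO3N", "H2CO3N"):
        model = build_model(name)
        obj = SurrogateObjective(
            train, study40.references, model, constants=study40.constants
        )
        start = LJParameterSet.from_model(model)
        results[name] = (model, obj, optimize(model, start, obj, cfg))
    return results


class TestConsistencyCheck:
    def test_under_optimized_verdict(self, fitted_pair, study40):
        probes = [c.mol for c in study40.library]
        coarse_model, _obj, coarse = fitted_pair["HCO3N"]
        fine_model, _fobj, fine = fitted_pair["H2CO3N"]
        ok, mapping = refinement_relation(coarse_model, fine_model, probes)
        assert ok
        # force the published-style pathology: pretend fine stopped high
        fine_bad = type(fine)(
            params=fine.params,
            breakdown=total_objective({"stuck": 84.0}, np.zeros(1), 0.0),
            trace=fine.trace,
            termination=fine.termination,
            seed=fine.seed,
        )
        coarse_good = type(coarse)(
            params=coarse.params,
            breakdown=total_objective({"ok": 39.0}, np.zeros(1), 0.0),
            trace=coarse.trace,
            termination=coarse.termination,
            seed=coarse.seed,
        )
        verdict = consistency_check(fine_bad, coarse_good, mapping)
        assert verdict.verdict == "under-optimized"

    def test_expected_ordering_passes(self, fitted_pair, study40):
        probes = [c.mol for c in study40.library]
        coarse_model, _obj, coarse = fitted_pair["HCO3N"]
        fine_model, _fobj, fine = fitted_pair["H2CO3N"]
        _ok, mapping = refinement_relation(coarse_model, fine_model, probes)
        if fine.objective <= coarse.objective:
            assert consistency_check(fine, coarse, mapping).verdict == "pass"

    def test_missing_relation_is_contract_error(self, fitted_pair):
        _m, _o, fine = fitted_pair["H2CO3N"]
        _m2, _o2, coarse = fitted_pair["HCO3N"]
        with pytest.raises(ValueError):
            consistency_check(fine, coarse, None)

    def test_restart_from_embedding_descends_below_coarse(self, fitted_pair, study40):
        probes = [c.mol for c in study40.library]
        coarse_model, _cobj, coarse = fitted_pair["HCO3N"]
        fine_model, fine_obj, _fine = fitted_pair["H2CO3N"]
        _ok, mapping = refinement_relation(coarse_model, fine_model, probes)
        fine_ref = LJParameterSet.from_model(fine_model)
        embedded = embed_coarse_optimum(coarse.params, fine_ref, mapping).as_reference()
        cfg = OptConfig(step_tol=1e-4, objective_tol=1e-5, max_iter=200)
        restarted = optimize(fine_model, embedded, fine_obj, cfg)
        assert restarted.objective <= coarse.objective + cfg.objective_tol


class TestSuperspaceLaw:
    @pytest.mark.parametrize(
        "coarse_name,fine_name",
        [("HCON", "H2CON"), ("HCON", "HCO3N"), ("H2CON", "H2CO3N")],
    )
    def test_embedding_never_ends_above_coarse(self, coarse_name, fine_name):
        # deterministic surrogate: noise-free oracle
        study = make_study(n=40, seed=13, noise=False)
        train, _test = make_split(study.library, 1, seed=13)
        cfg = OptConfig(step_tol=1e-4, objective_tol=1e-5, max_iter=200)
        coarse_model = build_model(coarse_name)
        fine_model = build_model(fine_name)
        coarse_obj = SurrogateObjective(
            train, study.references, coarse_model, constants=study.constants
        )
        fine_obj = SurrogateObjective(
            train, study.references, fine_model, constants=study.constants
        )
        coarse = optimize(
            coarse_model, LJParameterSet.from_model(coarse_model), coarse_obj, cfg
        )
        probes = [c.mol for c in study.library]
        _ok, mapping = refinement_relation(coarse_model, fine_model, probes)
        embedded = embed_coarse_optimum(
            coarse.params, LJParameterSet.from_model(fine_model), mapping
        ).as_reference()
        restarted = optimize(fine_model, embedded, fine_obj, cfg)
        assert restarted.objective <= coarse.objective + cfg.objective_tol


@pytest.fixture(scope="module")
def search_setup():
    study = make_study(n=75, seed=7)
    train, test = make_split(study.library, 1, seed=7)
    cfg = OptConfig(step_tol=1e-4, objective_tol=1e-4, max_iter=200)

    def fit_fn(model):
        obj = SurrogateObjective(
            train, study.references, model, constants=study.constants
        )
        return optimize(model, LJParameterSet.from_model(model), obj, cfg)

    def score_fn(model, result):
        test_obj = SurrogateObjective(
            test, study.references, model, constants=study.constants
        )
        return float(test_obj(result.params).data_term)

    return fit_fn, score_fn


class TestGreedySplitSearch:

    def test_accepts_h2_then_o3_rejects_c3_n2(self, search_setup):
        fit_fn, score_fn = search_setup
        result = greedy_split_search(
            build_model("HCON"),
            {"H": 2, "C": 3, "O": 3, "N": 2},
            fit_fn,
            score_fn,
            margin=1.0,
        )
        assert result.accepted == ["H->H2", "O->O3"]
        assert result.final_model.name == "H2CO3N"

    def test_no_improving_candidate_returns_base(self, search_setup):
        fit_fn, score_fn = search_setup
        # candidates that are property-neutral by construction
        result = greedy_split_search(
            build_model("H2CO3N"), {"C": 3, "N": 2}, fit_fn, score_fn, margin=1.0
        )
        assert result.accepted == []
        assert result.final_model.name == "H2CO3N"

    def test_joint_splits_greedy_blind_spot(self):
        """Constructed oracle where two splits help only jointly."""
        # score depends only on whether BOTH H and O are split
        def fit_fn(model):
            return None

        def score_fn(model, _result):
            split_h = model.name.startswith("H2")
            split_o = "O3" in model.name
            return 1.0 if (split_h and split_o) else 10.0

        base = build_model("HCON")
        candidates = {"H": 2, "O": 3}
        greedy = greedy_split_search(base, candidates, fit_fn, score_fn, margin=0.0)
        assert greedy.accepted == []  # greedy never sees the joint gain
        best_model, best_score = exhaustive_pair_search(
            base, candidates, fit_fn, score_fn
        )
        assert best_model.name == "H2CO3N" and best_score == 1.0


class TestParameterRecovery:
    def test_median_recovery_over_seeds(self):
        cfg = OptConfig(step_tol=1e-4, objective_tol=1e-6, max_iter=300)
        model = build_model("H2CO3N")
        errs_eps, errs_r = [], []
        for seed in range(1, 6):
            study = make_study(n=75, seed=seed)
            obj = SurrogateObjective(
                study.library, study.references, model, constants=study.constants
            )
            result = optimize(model, LJParameterSet.from_model(model), obj, cfg)
            truth = study.truth_params
            errs_eps.append(
                max(
                    abs(result.params.get(t).epsilon - truth.get(t).epsilon)
                    for t in result.params.type_order
                )
            )
            errs_r.append(
                max(
                    abs(result.params.get(t).rmin_half - truth.get(t).rmin_half)
                    for t in result.params.type_order
                )
            )
        assert np.median(errs_eps) < 0.02
        assert np.median(errs_r) < 0.05
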