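"""Functional profiling, functional diversity and ridge attribution."""

import math

import numpy as np
import pandas as pd
import pytest

from wormbiome.core_io import AbundanceTable, TraitTable, ValidationError
from wormbiome.diversity import diversity_trend
from wormbiome.functions import (
    RIDGE_LAMBDA_GRID,
    function_abundance,
    functional_diversity,
    taxon_contribution,
)
from wormbiome.simulate import SimulationConfig, generate_dataset


def _traits(presence: dict, subsystem: dict, taxa) -> TraitTable:
    return TraitTable(pd.DataFrame(presence, index=list(taxa)), subsystem)


class TestFunctionAbundance:
    def test_hand_sum(self):
        ab = AbundanceTable.from_arrays(
            np.array([[10, 5, 0]]), ["s1"], ["t1", "t2", "t3"]
        )
        tt = _traits({"f1": [1, 0, 1]}, {"f1": "gut"}, ["t1", "t2", "t3"])
        F = function_abundance(ab, tt)
        assert F.values.at["s1", "f1"] == 10

    def test_uncarried_function_is_zero_and_universal_equals_library_size(self):
        ab = AbundanceTable.from_arrays(
            np.array([[7, 3], [2, 8]]), ["s1", "s2"], ["t1", "t2"]
        )
        tt = _traits(
            {"none": [0, 0], "all": [1, 1]},
            {"none": "gut", "all": "gut"},
            ["t1", "t2"],
        )
        F = function_abundance(ab, tt)
        assert (F.values["none"] == 0).all()
        assert np.array_equal(F.values["all"].to_numpy(), ab.library_sizes)

    def test_monotone_bound(self):
        rng = np.random.default_rng(0)
        ab = AbundanceTable.from_arrays(
            rng.integers(0, 30, size=(5, 6)) + 1,
            [f"s{i}" for i in range(5)],
            [f"t{i}" for i in range(6)],
        )
        presence = {f"f{j}": rng.integers(0, 2, size=6) for j in range(8)}
        presence["f0"] = np.ones(6, dtype=int)
        tt = _traits(presence, {f"f{j}": "gut" for j in range(8)}, ab.taxon_ids)
        F = function_abundance(ab, tt)
        assert np.all(F.values.to_numpy() <= ab.library_sizes[:, None])

    def test_linearity_in_abundance(self):
        rng = np.random.default_rng(1)
        taxa = [f"t{i}" for i in range(5)]
        a1 = rng.integers(0, 20, size=(3, 5))
        a2 = rng.integers(0, 20, size=(3, 5))
        ids = ["s1", "s2", "s3"]
        tt = _traits(
            {f"f{j}": rng.integers(0, 2, size=5) for j in range(4)},
            {f"f{j}": "cazyme" for j in range(4)},
            taxa,
        )
        F1 = function_abundance(AbundanceTable.from_arrays(a1, ids, taxa), tt)
        F2 = function_abundance(AbundanceTable.from_arrays(a2, ids, taxa), tt)
        F12 = function_abundance(AbundanceTable.from_arrays(a1 + a2, ids, taxa), tt)
        assert np.array_equal(
            F12.values.to_numpy(), F1.values.to_numpy() + F2.values.to_numpy()
        )

    def test_strict_mode_rejects_missing_taxa(self):
        ab = AbundanceTable.from_arrays(np.array([[1, 2]]), ["s1"], ["t1", "tX"])
        tt = _traits({"f1": [1]}, {"f1": "gut"}, ["t1"])
        with pytest.raises(ValidationError):
            function_abundance(ab, tt, mode="strict")
        F = function_abundance(ab, tt, mode="lenient")
        assert F.values.at["s1", "f1"] == 1


class TestFunctionalDiversity:
    def test_closed_forms(self):
        values = pd.DataFrame(
            {"f1": [10, 10], "f2": [10, 0]}, index=["even", "single"]
        )
        from wormbiome.functions import FunctionAbundanceTable

        F = FunctionAbundanceTable(values, {"f1": "gut", "f2": "gut"})
        fd = functional_diversity(F)
        assert fd["even"] == pytest.approx(math.log(2), abs=1e-12)
        assert fd["single"] == pytest.approx(0.0, abs=1e-12)

    def test_host_selection_shifts_profile_toward_gut_functions(self):
        """The emergent signature of gut-linked host fitness: the gut share
        of the host functional profile rises with time and outpaces the
        worm-free controls."""
        host_wins = vs_control_wins = 0
        n_seeds = 10
        for seed in range(1, n_seeds + 1):
            cfg = SimulationConfig(
                S=20, N=2000, depth=2000, replicates=6, seed=seed, n_host_fit_taxa=10
            )
            ab, md, traits, _ = generate_dataset(cfg)
            F = function_abundance(ab, traits)
            gut = [f for f in F.function_ids if F.subsystem[f] == "gut"]
            share = F.values[gut].sum(axis=1) / F.values.sum(axis=1)
            trends = {}
            for source in ("host", "control"):
                ids = [s for s in ab.sample_ids if md.source[s] == source]
                trends[source] = diversity_trend(
                    share.loc[ids].to_numpy(), md.time_h.loc[ids].to_numpy()
                ).rho
            host_wins += trends["host"] > 0
            vs_control_wins += trends["host"] > trends["control"]
        assert host_wins >= 8
        assert vs_control_wins >= 8


class TestTaxonContribution:
    def test_ridge_matches_closed_form_at_fixed_lambda(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 3))
        y = rng.normal(size=4)
        lam = 2.5
        from sklearn.linear_model import Ridge

        model = Ridge(alpha=lam, fit_intercept=False).fit(X, y)
        closed = np.linalg.solve(X.T @ X + lam * np.eye(3), X.T @ y)
        assert np.allclose(model.coef_, closed, atol=1e-8)

    def test_exclusive_carrier_gets_largest_coefficient(self):
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(50, size=(40, 8))  # independent taxa
            ab = AbundanceTable.from_arrays(
                counts, [f"s{i}" for i in range(40)], [f"t{i}" for i in range(8)]
            )
            tt = _traits(
                {"f_only_t0": [1] + [0] * 7},
                {"f_only_t0": "gut"},
                ab.taxon_ids,
            )
            F = function_abundance(ab, tt)
            res = taxon_contribution(ab, F, cv_folds=5, seed=seed)
            coefs = res.coefficients["f_only_t0"].abs()
            if coefs.idxmax() == "t0":
                wins += 1
        assert wins >= int(0.95 * n_seeds)

    def test_constant_function_all_zero_coefficients(self):
        rng = np.random.default_rng(1)
        ab = AbundanceTable.from_arrays(
            rng.integers(1, 30, size=(10, 4)),
            [f"s{i}" for i in range(10)],
            [f"t{i}" for i in range(4)],
        )
        from wormbiome.functions import FunctionAbundanceTable

        F = FunctionAbundanceTable(
            pd.DataFrame({"flat": np.full(10, 9.0)}, index=list(ab.sample_ids)),
            {"flat": "gut"},
        )
        res = taxon_contribution(ab, F, seed=0)
        assert (res.coefficients["flat"] == 0).all()

    def test_constant_taxon_dropped(self):
        counts = np.column_stack(
            [np.full(8, 5), np.arange(8) + 1, np.arange(8)[::-1] + 1]
        )
        ab = AbundanceTable.from_arrays(
            counts, [f"s{i}" for i in range(8)], ["flat", "t1", "t2"]
        )
        tt = _traits({"f": [0, 1, 1]}, {"f": "gut"}, ab.taxon_ids)
        F = function_abundance(ab, tt)
        res = taxon_contribution(ab, F, cv_folds=4, seed=0)
        assert res.dropped_taxa == ("flat",)
        assert "flat" not in res.coefficients.index

    def test_coefficient_norm_shrinks_with_lambda(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=30)
        from sklearn.linear_model import Ridge

        norms = [
            np.linalg.norm(Ridge(alpha=lam, fit_intercept=False).fit(X, y).coef_)
            for lam in RIDGE_LAMBDA_GRID
        ]
        assert np.all(np.diff(norms) <= 1e-12)

    def test_cv_folds_validation(self):
        ab = AbundanceTable.from_arrays(
            np.arange(12).reshape(4, 3) + 1,
            [f"s{i}" for i in range(4)],
            [f"t{i}" for i in range(3)],
        )
        tt = _traits({"f": [1, 0, 0]}, {"f": "gut"}, ab.taxon_ids)
        F = function_abundance(ab, tt)
        with pytest.raises(ValidationError):
            taxon_contribution(ab, F, cv_folds=1)
        with pytest.raises(ValidationError):
            taxon_contribution(ab, F, cv_folds=5)  # more folds than samples


def test_lasso_penalty_and_relative_switch():
    rng = np.random.default_rng(3)
    ab = AbundanceTable.from_arrays(
        rng.poisson(50, size=(30, 5)),
        [f"s{i}" for i in range(30)],
        [f"t{i}" for i in range(5)],
    )
    tt = _traits({"f": [1, 0, 0, 0, 0]}, {"f": "gut"}, ab.taxon_ids)
    F = function_abundance(ab, tt)
    res = taxon_contribution(ab, F, seed=0, penalty="lasso")
    assert res.coefficients["f"].abs().idxmax() == "t0"
    with pytest.raises(ValidationError):
        taxon_contribution(ab, F, penalty="elastic")
    F_rel = function_abundance(ab, tt, relative=True)
    assert F_rel.values.to_numpy().max() <= 1.0
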