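"""Spline bases and the sparse interaction design matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fire_extremes.design import (
    build_design_matrix,
    coefficient_for_region,
    evaluate_basis,
    fit_spline_specs,
    make_spline_spec,
)
from fire_extremes.hierarchy import generate_hierarchy
from fire_extremes.preprocess import COVARIATE_COLUMNS


def _cox_de_boor(knots, degree, i, x):
    """Reference Cox-de Boor recursion for one B-spline basis function."""
    if degree == 0:
        # half-open intervals, closed at the right boundary
        if knots[i] <= x < knots[i + 1]:
            return 1.0
        if x == knots[-1] and knots[i] < knots[i + 1] <= knots[-1]:
            return 1.0 if knots[i + 1] == knots[-1] else 0.0
        return 0.0
    out = 0.0
    d1 = knots[i + degree] - knots[i]
    if d1 > 0:
        out += (x - knots[i]) / d1 * _cox_de_boor(knots, degree - 1, i, x)
    d2 = knots[i + degree + 1] - knots[i + 1]
    if d2 > 0:
        out += (knots[i + degree + 1] - x) / d2 * _cox_de_boor(knots, degree - 1, i + 1, x)
    return out


class TestSplineSpec:
    def test_df5_basis_dimension_and_knots(self):
        rng = np.random.default_rng(0)
        spec = make_spline_spec(rng.uniform(0, 1, 500), df=5)
        assert spec.df == 5
        assert len(spec.interior_knots) == spec.df - spec.degree - 1
        lo, hi = spec.boundary
        assert all(lo < k < hi for k in spec.interior_knots)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            make_spline_spec(np.full(100, 3.0), df=5)

    def test_too_few_distinct_values_error(self):
        with pytest.raises(ValueError):
            make_spline_spec(np.array([1.0, 2.0, 3.0]), df=5)

    def test_partition_of_unity_dense_grid(self):
        rng = np.random.default_rng(1)
        spec = make_spline_spec(rng.normal(size=300), df=5)
        lo, hi = spec.boundary
        grid = np.linspace(lo, hi, 10_000)
        rows = evaluate_basis(spec, grid)
        assert np.all(rows >= 0)
        assert np.max(np.abs(rows.sum(axis=1) - 1.0)) < 1e-10

    def test_constant_function_in_span(self):
        rng = np.random.default_rng(2)
        spec = make_spline_spec(rng.uniform(-3, 5, 200), df=5)
        grid = np.linspace(*spec.boundary, 50)
        rows = evaluate_basis(spec, grid)
        coef, *_ = np.linalg.lstsq(rows, np.ones(50), rcond=None)
        assert np.allclose(rows @ coef, 1.0, atol=1e-10)


class TestEvaluateBasis:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.spec = make_spline_spec(rng.uniform(0, 10, 400), df=5)

    def test_matches_cox_de_boor_recursion(self):
        knots = self.spec.knot_vector
        for x in [self.spec.boundary[0], 2.3, 5.0, 9.1, self.spec.boundary[1]]:
            ours = evaluate_basis(self.spec, x)[0]
            ref = [_cox_de_boor(knots, self.spec.degree, i, x) for i in range(self.spec.df)]
            assert np.allclose(ours, ref, atol=1e-12), x

    def test_boundary_minimum_concentrates_first_basis(self):
        row = evaluate_basis(self.spec, self.spec.boundary[0])[0]
        assert row[0] == pytest.approx(1.0)
        assert np.allclose(row[1:], 0.0)

    def test_clamping_beyond_max(self):
        hi = self.spec.boundary[1]
        assert np.allclose(
            evaluate_basis(self.spec, hi + 100.0), evaluate_basis(self.spec, hi)
        )

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            evaluate_basis(self.spec, np.nan)


class TestDesignMatrix:
    def test_thirty_global_basis_vectors(self, toy_design):
        assert len(toy_design.columns_for(kind="basis", level="global")) == 30

    def test_toy_column_count(self, toy_design):
        # B = 30, R = 2 + 4 + 12 = 18 -> p = 30 * 19 + 18
        assert toy_design.shape[1] == 588
        # metadata covers every column exactly once
        assert len(toy_design.meta) == 588

    def test_row_sparsity_bound(self, toy_design):
        nnz_per_row = np.diff(toy_design.X.indptr)
        assert nnz_per_row.max() <= 4 * 30 + 3

    def test_sparse_matches_rowwise_dense_assembly(
        self, toy_panel_nofires, toy_hierarchy, toy_specs, toy_design
    ):
        rows = toy_panel_nofires.iloc[:40]
        dense = toy_design.X[:40].toarray()
        covs = list(toy_specs)
        for i, (_, row) in enumerate(rows.iterrows()):
            expected = np.zeros(toy_design.shape[1])
            bases = {c: evaluate_basis(toy_specs[c], row[c])[0] for c in covs}
            region = int(row["region"])
            units = {
                "global": -1,
                "L1": toy_hierarchy.l1_of_l3(region),
                "L2": toy_hierarchy.parent_l2[region],
                "L3": region,
            }
            for level, unit in units.items():
                for c in covs:
                    idx = toy_design.columns_for(
                        kind="basis", covariate=c, level=level, region=unit
                    )
                    expected[idx] = bases[c]
            for level, unit in list(units.items())[1:]:
                idx = toy_design.columns_for(
                    kind="intercept_adjustment", level=level, region=unit
                )
                expected[idx] = 1.0
            assert np.allclose(dense[i], expected, atol=1e-12)

    def test_round_trip_serialization(self, toy_design, tmp_path):
        toy_design.to_files(tmp_path / "x.csv", tmp_path / "meta.json")
        from fire_extremes.design import DesignMatrix

        back = DesignMatrix.from_files(tmp_path / "x.csv", tmp_path / "meta.json")
        assert np.allclose(back.X.toarray(), toy_design.X.toarray())

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(1, 3), st.integers(0, 3), st.integers(0, 6), st.integers(0, 100))
    def test_column_count_formula_random_hierarchies(self, n1, d2, d3, seed):
        import pandas as pd

        h = generate_hierarchy(n1, n1 + d2, n1 + d2 + d3, seed=seed)
        rng = np.random.default_rng(seed)
        rows = pd.DataFrame(
            {
                "region": rng.choice(h.l3_ids, size=60),
                "x1": rng.normal(size=60),
                "x2": rng.uniform(1, 2, size=60),
            }
        )
        specs = {
            "x1": make_spline_spec(rows["x1"].to_numpy(), df=4, covariate="x1"),
            "x2": make_spline_spec(rows["x2"].to_numpy(), df=5, covariate="x2"),
        }
        dm = build_design_matrix(rows, h, specs)
        B = 4 + 5
        R = h.n_l1 + h.n_l2 + h.n_l3
        assert dm.shape == (60, B * (1 + R) + R)


class TestCoefficientForRegion:
    def test_zero_adjustments_give_global(self, toy_design, toy_hierarchy):
        beta = np.zeros(toy_design.shape[1])
        g = toy_design.columns_for(kind="basis", covariate="humidity", level="global")
        beta[g] = [1.0, 2.0, 3.0, 4.0, 5.0]
        eff = coefficient_for_region(beta, toy_design, "humidity", toy_hierarchy.l3_ids[0], toy_hierarchy)
        assert np.allclose(eff, [1, 2, 3, 4, 5])

    def test_siblings_differ_only_in_l3_terms(self, toy_design, toy_hierarchy):
        h = toy_hierarchy
        sibs = [r for r in h.l3_ids if h.parent_l2[r] == h.parent_l2[h.l3_ids[0]]]
        assert len(sibs) >= 2
        rng = np.random.default_rng(0)
        beta = rng.normal(size=toy_design.shape[1])
        a = coefficient_for_region(beta, toy_design, "wind_speed", sibs[0], h)
        b = coefficient_for_region(beta, toy_design, "wind_speed", sibs[1], h)
        ca = beta[toy_design.columns_for(kind="basis", covariate="wind_speed", level="L3", region=sibs[0])]
        cb = beta[toy_design.columns_for(kind="basis", covariate="wind_speed", level="L3", region=sibs[1])]
        assert np.allclose(a - ca, b - cb)

    def test_dot_product_matches_dense_contribution(
        self, toy_design, toy_hierarchy, toy_panel_nofires, toy_specs
    ):
        rng = np.random.default_rng(4)
        beta = rng.normal(size=toy_design.shape[1])
        i = 123
        row = toy_panel_nofires.iloc[i]
        region = int(row["region"])
        eff = coefficient_for_region(beta, toy_design, "temperature", region, toy_hierarchy)
        basis_row = evaluate_basis(toy_specs["temperature"], row["temperature"])[0]
        cols = toy_design.columns_for(kind="basis", covariate="temperature")
        direct = float(toy_design.X[i].toarray()[0, cols] @ beta[cols])
        assert np.isclose(eff @ basis_row, direct, atol=1e-12)

    def test_unknown_covariate_raises(self, toy_design, toy_hierarchy):
        with pytest.raises(ValueError):
            coefficient_for_region(
                np.zeros(toy_design.shape[1]), toy_design, "nope", toy_hierarchy.l3_ids[0], toy_hierarchy
            )


def test_specs_fitted_on_training_only(toy_panel_nofires):
    train = toy_panel_nofires[toy_panel_nofires["split"] == "train"]
    specs = fit_spline_specs(train, COVARIATE_COLUMNS)
    for c in COVARIATE_COLUMNS:
        vals = train[c].to_numpy()
        if specs[c].log_transform:
            vals = np.log(vals)
        assert specs[c].boundary == (vals.min(), vals.max())
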