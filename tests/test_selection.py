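"""Correlation screening, VIF, and exhaustive BIC subset selection."""

import numpy as np
import pandas as pd
import pytest

from mpbselect import (
    best_model,
    exhaustive_selection,
    screen_correlated,
    selection_table,
    vif,
)
from mpbselect.errors import EnumerationCapError, UnknownCovariateError


def correlated_pair(rng, n, rho):
    """Two columns with sample correlation exactly rho (orthonormalized)."""
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a = (a - a.mean()) / a.std()
    b = b - b.mean()
    b -= a * (a @ b) / (a @ a)  # exact orthogonalization
    b /= b.std()
    return a, rho * a + np.sqrt(1 - rho**2) * b


class TestScreening:
    def _table(self, rng, n=3000):
        height, age = correlated_pair(rng, n, 0.95)
        tmax, smi = correlated_pair(rng, n, -0.71)
        _, peak_extra = correlated_pair(rng, n, 0.0)
        peak = -0.71 * tmax + np.sqrt(1 - 0.71**2) * peak_extra
        return pd.DataFrame(
            {
                "T_max": tmax, "SMI": smi, "Peak": peak,
                "T_min": rng.normal(size=n), "CT": rng.normal(size=n),
                "Cover": rng.normal(size=n), "Height": height, "Age": age,
                "Dist": rng.normal(size=n), "N": rng.normal(size=n),
                "E": rng.normal(size=n),
                "I_c": rng.normal(size=n), "I_u": rng.normal(size=n),
            }
        )

    def test_paper_style_removals(self, rng):
        """T_max falls to its SMI/Peak correlations; Age falls to Height."""
        report = screen_correlated(self._table(rng))
        removed = {r[0] for r in report.removed}
        assert removed == {"T_max", "Age"}
        assert "SMI" in report.retained and "Peak" in report.retained
        assert "Height" in report.retained and "Age" not in report.retained

    def test_nothing_removed_when_below_threshold(self, rng):
        n = 3000
        table = pd.DataFrame(rng.normal(size=(n, 4)), columns=["SMI", "CT", "N", "E"])
        report = screen_correlated(
            table, categories={"weather": ["SMI", "CT"], "topography": ["N", "E"]}
        )
        assert report.removed == []
        assert sorted(report.retained) == ["CT", "E", "N", "SMI"]

    def test_cross_category_pairs_exempt(self, rng):
        a, b = correlated_pair(rng, 2000, 0.9)
        table = pd.DataFrame({"SMI": a, "Cover": b})
        report = screen_correlated(
            table, categories={"weather": ["SMI"], "vegetation": ["Cover"]}
        )
        assert report.removed == []
        assert sorted(report.retained) == ["Cover", "SMI"]

    def test_missing_covariate_rejected(self, rng):
        table = pd.DataFrame({"SMI": rng.normal(size=10)})
        with pytest.raises(UnknownCovariateError):
            screen_correlated(table, categories={"weather": ["SMI", "T_max"]})


class TestVif:
    def test_orthogonal_columns_are_one(self, rng):
        a, b = correlated_pair(rng, 500, 0.0)
        per_cov, vmax = vif(pd.DataFrame({"a": a, "b": b}))
        assert per_cov["a"] == pytest.approx(1.0, abs=1e-9)
        assert vmax == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.6, 0.9])
    def test_bivariate_closed_form(self, rng, rho):
        a, b = correlated_pair(rng, 800, rho)
        _, vmax = vif(pd.DataFrame({"a": a, "b": b}))
        assert vmax == pytest.approx(1.0 / (1.0 - rho**2), abs=1e-9)

    def test_matches_statsmodels(self, rng):
        smo = pytest.importorskip("statsmodels.stats.outliers_influence")
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        X["c"] += 0.8 * X["a"]
        per_cov, _ = vif(X)
        D = np.column_stack([np.ones(len(X)), X.to_numpy()])
        for j, name in enumerate(X.columns):
            ref = smo.variance_inflation_factor(D, j + 1)
            assert per_cov[name] == pytest.approx(ref, rel=1e-8)

    def test_perfect_collinearity_is_infinite(self, rng):
        x = rng.normal(size=100)
        per_cov, vmax = vif(pd.DataFrame({"a": x, "b": 3 * x + 1}))
        assert np.isinf(vmax)


def _selection_data(rng, n, betas, extra=3):
    names = [f"x{i}" for i in range(len(betas) + extra)]
    X = pd.DataFrame(rng.normal(size=(n, len(names))), columns=names)
    eta = -2.5 + sum(b * X[f"x{i}"] for i, b in enumerate(betas))
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    X["response"] = y
    X["year"] = rng.integers(2001, 2005, size=n)
    return X, names


class TestExhaustiveSelection:
    def test_two_candidates_report_best_per_size(self, rng):
        table, names = _selection_data(rng, 2000, [1.0], extra=1)
        records = exhaustive_selection(
            table, names, with_cv=False, competitor_delta=0.0
        )
        assert sorted(r.size for r in records) == [0, 1, 2]  # 4 subsets, best of each size
        assert best_model(records).delta_bic == 0.0

    def test_strong_support_recovered(self, rng):
        table, _ = _selection_data(rng, 40_000, [0.9, 0.7, -0.6], extra=3)
        records = exhaustive_selection(
            table, [f"x{i}" for i in range(6)], with_cv=False
        )
        assert set(best_model(records).subset) == {"x0", "x1", "x2"}

    def test_null_response_selects_null_model(self, rng):
        table, names = _selection_data(rng, 40_000, [], extra=4)
        records = exhaustive_selection(table, names, with_cv=False)
        assert best_model(records).subset == ()

    def test_bic_ordering_invariant_to_affine_rescaling(self, rng):
        table, names = _selection_data(rng, 5000, [0.8, -0.5], extra=2)
        records = exhaustive_selection(table, names, with_cv=False)
        rescaled = table.copy()
        rescaled["x0"] = rescaled["x0"] * 1000.0 - 77.0
        rescaled["x2"] = rescaled["x2"] / 500.0 + 3.0
        records2 = exhaustive_selection(rescaled, names, with_cv=False)
        assert [r.subset for r in records] == [r.subset for r in records2]
        for a, b in zip(records, records2):
            assert a.bic == pytest.approx(b.bic, abs=1e-5)

    def test_vif_exclusion_applied_a_posteriori(self, rng):
        n = 4000
        a, b = correlated_pair(rng, n, 0.97)  # VIF ~ 16.9 > 10
        table = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=n)})
        eta = -2.0 + 1.0 * a
        table["response"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        table["year"] = rng.integers(2001, 2003, size=n)
        records = exhaustive_selection(table, ["a", "b", "c"], with_cv=False)
        flagged = {r.subset: r.excluded_by_vif for r in records}
        assert any(
            excl for subset, excl in flagged.items() if {"a", "b"} <= set(subset)
        )
        assert not set(best_model(records).subset) >= {"a", "b"}

    def test_candidate_cap_enforced(self, rng):
        table, _ = _selection_data(rng, 100, [0.5], extra=0)
        with pytest.raises(EnumerationCapError):
            exhaustive_selection(table, ["x0"], with_cv=False, max_candidates=0)

    def test_report_table_layout(self, rng):
        table, names = _selection_data(rng, 2000, [1.0], extra=1)
        records = exhaustive_selection(table, names, with_cv=True)
        report = selection_table(records)
        assert list(report.columns) == [
            "size", "variables", "vif_max", "bic", "delta_bic",
            "auroc", "aupr", "excluded_by_vif", "evidence",
        ]
        null_row = report[report["variables"] == "null"].iloc[0]
        assert null_row["auroc"] == pytest.approx(0.5)
        assert (report["delta_bic"] >= 0).all()
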