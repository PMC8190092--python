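"""Normalization, polynomial trajectory fits and oligomer ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thylaquant.abundance_trajectories import (
    CONDITIONS,
    fit_all_trajectories,
    fit_trajectory,
    normalize_to_reference,
    oligomer_ratios,
    simulate_abundance_table,
)


def _table(values: dict[str, list[float]], n_rep=2) -> pd.DataFrame:
    rows = []
    for prot, per_cond in values.items():
        for cond, v in zip(CONDITIONS, per_cond):
            for rep in range(1, n_rep + 1):
                rows.append(
                    {"protein": prot, "condition": cond,
                     "replicate": rep, "abundance": v}
                )
    return pd.DataFrame(rows)


class TestNormalizeToReference:
    def test_reference_mean_becomes_one(self):
        tab = _table({"A": [4, 2, 1, 1, 1, 1, 1], "B": [10, 5, 2, 2, 2, 2, 2]})
        res = normalize_to_reference(tab, "GL")
        ref = res.table[res.table["condition"] == "GL"]
        means = ref.groupby("protein")["abundance"].mean()
        np.testing.assert_allclose(means.to_numpy(), 1.0)

    def test_definition(self):
        tab = _table({"A": [2, 5, 1, 1, 1, 1, 1]})
        res = normalize_to_reference(tab, "GL")
        hl = res.table[res.table["condition"] == "HL"]["abundance"]
        np.testing.assert_allclose(hl.to_numpy(), 2.5)

    def test_zero_reference_mean_dropped_and_reported(self):
        tab = _table({"A": [1, 2, 1, 1, 1, 1, 1], "Z": [0, 2, 1, 1, 1, 1, 1]})
        res = normalize_to_reference(tab, "GL")
        assert res.dropped == ["Z"]
        assert "Z" not in set(res.table["protein"])

    def test_missing_reference_rejected(self):
        tab = _table({"A": [1, 2, 1, 1, 1, 1, 1]})
        with pytest.raises(ValueError, match="reference"):
            normalize_to_reference(tab, "DARK")

    def test_idempotent(self):
        tab = simulate_abundance_table(seed=3)
        once = normalize_to_reference(tab, "GL").table
        twice = normalize_to_reference(once, "GL").table
        np.testing.assert_allclose(
            once["abundance"].to_numpy(), twice["abundance"].to_numpy(), rtol=1e-12
        )


class TestFitTrajectory:
    def test_exact_quartic_recovered(self):
        x = np.arange(7, dtype=float)
        c_true = np.array([1.0, -0.5, 0.2, 0.03, -0.004])
        y = np.polynomial.polynomial.polyval(x, c_true)
        fit = fit_trajectory(x, y, degree=4)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.coefficients, c_true, rtol=1e-8)

    def test_adjusted_r2_closed_form(self):
        # construct data with R2 = 0.97 at n = 7, degree 4:
        # adj = 1 - 0.03 * 6 / 2 = 0.91
        rng = np.random.default_rng(0)
        x = np.arange(7, dtype=float)
        for _ in range(200):
            y = np.polynomial.polynomial.polyval(x, [0, 1, 0.3, 0, 0]) + rng.normal(
                0, 0.8, 7
            )
            fit = fit_trajectory(x, y, degree=4)
            expected = 1 - (1 - fit.r2) * 6 / 2
            assert fit.adj_r2 == pytest.approx(expected, rel=1e-12)

    def test_too_few_points_rejected(self):
        x = np.arange(5, dtype=float)
        with pytest.raises(ValueError, match="distinct x"):
            fit_trajectory(x, x**2, degree=4)

    def test_matches_normal_equations_oracle(self):
        """Agrees with an explicit normal-equations solve to 10 significant
        digits on 100 random instances (n = 7, degree 4)."""
        rng = np.random.default_rng(9)
        x = np.arange(7, dtype=float)
        for _ in range(100):
            y = rng.normal(size=7)
            fit = fit_trajectory(x, y, degree=4)
            V = np.vander(x, 5, increasing=True)
            coef = np.linalg.solve(V.T @ V, V.T @ y)
            np.testing.assert_allclose(fit.coefficients, coef, rtol=1e-10)
            resid = y - V @ coef
            r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
            assert fit.r2 == pytest.approx(r2, rel=1e-10)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_adjusted_leq_r2(self, seed):
        rng = np.random.default_rng(seed)
        x = np.arange(8, dtype=float)
        y = rng.normal(size=8)
        fit = fit_trajectory(x, y, degree=4)
        assert fit.adj_r2 <= fit.r2 + 1e-12

    def test_parameter_recovery_under_noise(self):
        """Quartic + N(0, 0.02) noise at n = 7: fitted curve within 3 sigma
        of the truth (max abs error) in >= 95% of 1000 replicates."""
        rng = np.random.default_rng(17)
        x = np.arange(7, dtype=float)
        c_true = np.array([1.0, -2.8, 1.0, 0.5, -0.08])
        y_true = np.polynomial.polynomial.polyval(x, c_true)
        sigma = 0.02
        ok = 0
        for _ in range(1000):
            y = y_true + rng.normal(0, sigma, 7)
            fit = fit_trajectory(x, y, degree=4)
            yhat = np.polynomial.polynomial.polyval(x, fit.coefficients)
            if np.max(np.abs(yhat - y_true)) < 3 * sigma:
                ok += 1
        assert ok >= 950


class TestFitAllTrajectories:
    def test_fits_normalized_simulated_table(self):
        tab = simulate_abundance_table(seed=5)
        norm = normalize_to_reference(tab, "GL").table
        fits = fit_all_trajectories(norm, degree=4, on="mean")
        assert set(fits.index) == set(tab["protein"])
        assert ((fits["adj_r2"] <= 1.0) | fits["adj_r2"].isna()).all()
        assert (fits["n"] == 7).all()


class TestOligomerRatios:
    def _bands(self, values):
        rows = []
        for (assembly, cond), reps in values.items():
            for i, v in enumerate(reps, start=1):
                rows.append({"assembly": assembly, "condition": cond,
                             "replicate": i, "intensity": v})
        return pd.DataFrame(rows)

    def test_equal_bands_ratio_one(self):
        bands = self._bands({
            ("PSI monomer", "GL"): [2.0, 2.0],
            ("PSI trimer", "GL"): [2.0, 2.0],
            ("PSII monomer", "GL"): [1.0],
            ("PSII dimer", "GL"): [1.0],
        })
        out = oligomer_ratios(bands)
        psi = out[(out["ratio"] == "PSI monomer/trimer")].iloc[0]
        assert psi["mean"] == pytest.approx(1.0) and psi["defined"]

    def test_definition(self):
        bands = self._bands({
            ("PSI monomer", "GL"): [3.0],
            ("PSI trimer", "GL"): [1.0],
            ("PSII monomer", "GL"): [1.0],
            ("PSII dimer", "GL"): [2.0],
        })
        out = oligomer_ratios(bands).set_index("ratio")
        assert out.loc["PSI monomer/trimer", "mean"] == pytest.approx(3.0)
        assert out.loc["PSII monomer/dimer", "mean"] == pytest.approx(0.5)

    def test_zero_oligomer_band_flagged_undefined(self):
        # e.g. no PSI trimers detectable on the first low-light day
        bands = self._bands({
            ("PSI monomer", "LL1"): [2.0],
            ("PSI trimer", "LL1"): [0.0],
            ("PSII monomer", "LL1"): [1.0],
            ("PSII dimer", "LL1"): [1.0],
        })
        out = oligomer_ratios(bands).set_index("ratio")
        row = out.loc["PSI monomer/trimer"]
        assert not row["defined"]
        assert np.isnan(row["mean"])

    def test_mismatched_replicates_rejected(self):
        bands = self._bands({
            ("PSI monomer", "GL"): [2.0, 2.0],
            ("PSI trimer", "GL"): [2.0],
            ("PSII monomer", "GL"): [1.0],
            ("PSII dimer", "GL"): [1.0],
        })
        with pytest.raises(ValueError, match="replicate"):
            oligomer_ratios(bands)
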