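"""Exact pi-group construction against independent symbolic oracles."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import sympy

from enviropinet.dimensions import (
    BASE_DIMENSIONS,
    DimensionalAnalysisError,
    PiGroup,
    build_dimensional_matrix,
    check_dimensionless,
    construct_pi_basis,
    evaluate_pi,
    rational_nullspace,
)

from conftest import make_spec


def _sympy_matrix(matrix):
    return sympy.Matrix(
        [[sympy.Rational(e) for e in row] for row in matrix.entries]
    )


def _span_equal(vecs_a, vecs_b):
    """Exact row-span equality via sympy RREF (independent oracle)."""
    a = sympy.Matrix([[sympy.Rational(x) for x in v] for v in vecs_a])
    b = sympy.Matrix([[sympy.Rational(x) for x in v] for v in vecs_b])
    return a.rref()[0] == b.rref()[0]


class TestDimensionalMatrix:
    def test_direct_transcription(self):
        m = build_dimensional_matrix(
            [make_spec("x", length=1), make_spec("y", length=1)]
        )
        assert m.symbols == ("x", "y")
        # one row per base dimension, zeros where unused
        assert len(m.entries) == len(BASE_DIMENSIONS)
        length_row = m.entries[BASE_DIMENSIONS.index("length")]
        assert length_row == (Fraction(1), Fraction(1))
        assert all(
            all(e == 0 for e in row)
            for d, row in zip(BASE_DIMENSIONS, m.entries)
            if d != "length"
        )

    def test_biofilter_matrix_shape_and_rank(self, specs):
        indep = [s for s in specs if s.role == "independent"]
        m = build_dimensional_matrix(indep)
        assert m.n_variables == 8
        assert m.rank() == 4 == _sympy_matrix(m).rank()

    def test_duplicate_symbol_rejected(self):
        with pytest.raises(DimensionalAnalysisError, match="x"):
            build_dimensional_matrix([make_spec("x", length=1), make_spec("x", time=1)])


class TestNullspace:
    def test_trivial_nullspace_empty(self):
        m = build_dimensional_matrix(
            [make_spec("x", length=1), make_spec("t", time=1)]
        )
        assert rational_nullspace(m) == []

    def test_like_quantities_give_ratio(self):
        m = build_dimensional_matrix(
            [make_spec("x", length=1), make_spec("y", length=1)]
        )
        assert rational_nullspace(m) == [(Fraction(1), Fraction(-1))]

    @pytest.mark.parametrize("trial", range(20))
    def test_dimension_count_and_span_vs_sympy(self, trial):
        """n - rank vectors spanning exactly sympy's null space, up to 6x10."""
        rng = np.random.default_rng(100 + trial)
        n_rows = int(rng.integers(1, 7))
        n_cols = int(rng.integers(n_rows, 11))
        num = rng.integers(-3, 4, size=(n_rows, n_cols))
        den = rng.integers(1, 4, size=(n_rows, n_cols))
        rows = tuple(
            tuple(Fraction(int(a), int(b)) for a, b in zip(nr, dr))
            for nr, dr in zip(num, den)
        )
        # pad to the 4 fixed base-dimension rows
        rows = rows + tuple(
            tuple(Fraction(0) for _ in range(n_cols)) for _ in range(4 - n_rows)
        ) if n_rows < 4 else rows[:4]
        m = build_dimensional_matrix(
            [
                make_spec(f"v{j}")
                for j in range(n_cols)
            ]
        )
        m = type(m)(symbols=m.symbols, entries=rows[:4])
        ours = rational_nullspace(m)
        sm = _sympy_matrix(m)
        oracle = [tuple(v) for v in sm.nullspace()]
        assert len(ours) == n_cols - sm.rank()
        if ours:
            assert _span_equal(ours, oracle)
        # every vector is genuinely in the null space and canonicalized
        for v in ours:
            assert all(x == 0 for x in sm * sympy.Matrix(v))
            ints = [x for x in v]
            assert all(x.denominator == 1 for x in ints)

    def test_repeating_preference_changes_labels_not_span(self, specs):
        indep = [s for s in specs if s.role == "independent"]
        m = build_dimensional_matrix(indep)
        default = rational_nullspace(m)
        preferred = rational_nullspace(m, repeating=["T", "A", "IC_org", "C_fit"])
        assert _span_equal(default, preferred)


class TestPiBasis:
    def test_biofilter_groups_match_printed_ratios(self, basis):
        assert [g.label for g in basis.independent] == [
            "Pz/C_fit",
            "Bt/A",
            "P/C_fit",
            "t0/T",
        ]
        assert basis.dependent.exponents == {
            "EC_org": Fraction(1),
            "IC_org": Fraction(-1),
        }

    def test_span_equals_printed_groups(self, specs):
        # without any repeating-variable hint the span must still match
        b = construct_pi_basis(specs)
        symbols = [s.symbol for s in specs if s.role == "independent"]
        ours = [g.exponent_vector(symbols) for g in b.independent]
        printed = [
            PiGroup({"Pz": 1, "C_fit": -1}),
            PiGroup({"Bt": 1, "A": -1}),
            PiGroup({"P": 1, "C_fit": -1}),
            PiGroup({"t0": 1, "T": -1}),
        ]
        assert _span_equal(ours, [g.exponent_vector(symbols) for g in printed])

    def test_degenerate_single_independent(self):
        b = construct_pi_basis(
            [make_spec("x", length=1), make_spec("y", role="dependent")]
        )
        assert b.independent == ()
        assert b.dependent.exponents == {"y": Fraction(1)}

    def test_unmatchable_dependent_raises(self):
        with pytest.raises(DimensionalAnalysisError, match="nondimensionalized"):
            construct_pi_basis(
                [make_spec("x", length=1), make_spec("m", role="dependent", mass=1)]
            )

    def test_two_dependents_rejected(self):
        with pytest.raises(DimensionalAnalysisError, match="exactly one"):
            construct_pi_basis(
                [
                    make_spec("x", length=1),
                    make_spec("y", role="dependent"),
                    make_spec("z", role="dependent"),
                ]
            )

    @pytest.mark.parametrize("trial", range(8))
    def test_random_system_recovers_planted_span(self, trial):
        """Random 6-variable systems: emitted span equals sympy's null space."""
        rng = np.random.default_rng(300 + trial)
        specs = [
            make_spec(
                f"v{j}",
                **{
                    d: int(e)
                    for d, e in zip(
                        ("mass", "length", "time"), rng.integers(-2, 3, size=3)
                    )
                },
            )
            for j in range(6)
        ]
        m = build_dimensional_matrix(specs)
        sm = _sympy_matrix(m)
        if sm.rank() == 6:
            pytest.skip("full-rank draw has no pi-groups")
        b = construct_pi_basis(specs + [make_spec("y", role="dependent")])
        ours = [g.exponent_vector(m.symbols) for g in b.independent]
        assert _span_equal(ours, [tuple(v) for v in sm.nullspace()])

    def test_all_emitted_groups_dimensionless(self, specs, basis):
        for g in (*basis.independent, basis.dependent):
            assert check_dimensionless(g, specs)


class TestCheckDimensionless:
    def test_balanced_and_unbalanced(self, specs):
        assert check_dimensionless(PiGroup({"Pz": 1, "C_fit": -1}), specs)
        assert not check_dimensionless(PiGroup({"Bt": 1, "Pz": -1}), specs)

    def test_unknown_symbol_rejected(self, specs):
        with pytest.raises(DimensionalAnalysisError, match="nope"):
            check_dimensionless(PiGroup({"nope": 1}), specs)


class TestEvaluatePi:
    def _row(self, **kw):
        base = dict(
            T=285.0, Pz=5e-4, A=1e6, IC_org=3.0, EC_org=2.5,
            Bt=3600.0, P=1e-3, C_fit=0.5, t0=290.0,
        )
        base.update(kw)
        return pd.DataFrame([base])

    def test_identity_ratio_and_neutral_element(self, basis):
        row = self._row(P=0.5, C_fit=0.5)
        assert evaluate_pi(basis, row)["P/C_fit"].iloc[0] == pytest.approx(1.0)
        ones = self._row(**{c: 1.0 for c in self._row().columns})
        assert np.allclose(evaluate_pi(basis, ones).to_numpy(), 1.0)

    def test_matches_per_term_product_oracle(self, basis):
        rng = np.random.default_rng(5)
        rows = pd.DataFrame(
            {s: np.exp(rng.uniform(-2, 2, 20)) for s in basis.symbols}
        )
        got = evaluate_pi(basis, rows)
        for g in (*basis.independent, basis.dependent):
            expected = np.ones(len(rows))
            for s, e in g.exponents.items():
                expected *= rows[s].to_numpy() ** float(e)
            assert np.allclose(got[g.label], expected, rtol=1e-12)

    def test_nonpositive_value_reports_row_and_symbol(self, basis):
        bad = self._row(Pz=0.0)
        with pytest.raises(DimensionalAnalysisError, match="Pz"):
            evaluate_pi(basis, bad)

    def test_column_scaling_law(self, basis):
        """pi scales by c^exponent when one variable column is scaled by c."""
        row = self._row()
        base = evaluate_pi(basis, row)
        c = 7.3
        scaled = evaluate_pi(basis, row.assign(Bt=row["Bt"] * c))
        assert scaled["Bt/A"].iloc[0] == pytest.approx(base["Bt/A"].iloc[0] * c)
        assert scaled["P/C_fit"].iloc[0] == pytest.approx(base["P/C_fit"].iloc[0])

    def test_consistent_unit_change_is_invisible(self, basis):
        """Converting all lengths (or all times) leaves every pi unchanged."""
        row = self._row()
        base = evaluate_pi(basis, row).to_numpy()
        metric = row.copy()
        for s in ("Pz", "P", "C_fit"):
            metric[s] *= 1000.0  # m -> mm
        for s in ("A", "Bt"):
            metric[s] /= 3600.0  # s -> h
        # concentrations share mass*length^-3: scale consistently too
        for s in ("IC_org", "EC_org"):
            metric[s] *= 1e-9
        assert np.allclose(evaluate_pi(basis, metric).to_numpy(), base, rtol=1e-12)
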