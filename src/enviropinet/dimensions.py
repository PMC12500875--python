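"""Dimensional analysis: construction of dimensionless pi-groups.

The Buckingham Pi theorem states that a physical relation among ``n``
variables measured in ``m`` independent base dimensions can be rewritten
in terms of ``n - m`` dimensionless power-products (pi-groups).
Algebraically, the exponent vectors of the pi-groups span the right null
space of the *dimensional matrix* — the matrix whose rows are base
dimensions, columns are variables, and entries are dimension exponents.

All linear algebra in this module is carried out over exact rationals
(:class:`fractions.Fraction`); floating point only enters when a basis is
evaluated on data (:func:`evaluate_pi`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BASE_DIMENSIONS",
    "VariableSpec",
    "DimensionalMatrix",
    "PiGroup",
    "PiBasis",
    "DimensionalAnalysisError",
    "build_dimensional_matrix",
    "rational_nullspace",
    "construct_pi_basis",
    "evaluate_pi",
    "check_dimensionless",
]

#: The fixed, ordered set of base dimensions handled by this package.
BASE_DIMENSIONS: tuple[str, ...] = ("mass", "length", "time", "temperature")


class DimensionalAnalysisError(ValueError):
    """Raised for ill-posed dimensional systems (duplicate symbols,
    non-nondimensionalizable dependent variables, unknown symbols...)."""


@dataclass(frozen=True)
class VariableSpec:
    """A physical variable with exact rational dimension exponents.

    Parameters
    ----------
    symbol:
        Short name used as the column header in observation tables
        (e.g. ``"Pz"`` for pore size).
    dimensions:
        Mapping base dimension -> exact rational exponent. Dimensions
        absent from the mapping have exponent zero.
    role:
        ``"independent"`` or ``"dependent"``. Exactly one variable per
        system is dependent (the quantity being predicted).
    unit:
        Canonical unit the variable is stored in after ingest.
    scale, offset:
        Affine conversion from the raw file unit to the canonical unit:
        ``canonical = raw * scale + offset`` (offset is needed for
        Celsius -> kelvin).
    """

    symbol: str
    dimensions: Mapping[str, Fraction]
    role: str = "independent"
    unit: str = ""
    description: str = ""
    scale: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("independent", "dependent"):
            raise DimensionalAnalysisError(
                f"role of {self.symbol!r} must be 'independent' or 'dependent', "
                f"got {self.role!r}"
            )
        unknown = set(self.dimensions) - set(BASE_DIMENSIONS)
        if unknown:
            raise DimensionalAnalysisError(
                f"unknown base dimension(s) {sorted(unknown)} in spec for {self.symbol!r}"
            )
        object.__setattr__(
            self,
            "dimensions",
            {d: Fraction(self.dimensions.get(d, 0)) for d in BASE_DIMENSIONS},
        )

    def dimension_vector(self) -> tuple[Fraction, ...]:
        """Exponents ordered as :data:`BASE_DIMENSIONS`."""
        return tuple(self.dimensions[d] for d in BASE_DIMENSIONS)

    @property
    def is_dimensionless(self) -> bool:
        return all(e == 0 for e in self.dimensions.values())


@dataclass(frozen=True)
class DimensionalMatrix:
    """Rows indexed by base dimension, columns by variable symbol."""

    symbols: tuple[str, ...]
    entries: tuple[tuple[Fraction, ...], ...]  # one row per base dimension

    @property
    def n_variables(self) -> int:
        return len(self.symbols)

    def rank(self) -> int:
        _, pivots = _rref([list(r) for r in self.entries], self.n_variables)
        return len(pivots)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[float(e) for e in row] for row in self.entries],
            index=list(BASE_DIMENSIONS),
            columns=list(self.symbols),
        )


@dataclass(frozen=True)
class PiGroup:
    """A dimensionless power-product of variables.

    ``exponents`` maps variable symbol -> exact rational exponent; symbols
    with exponent zero are omitted.  The label renders the group the way
    it would be written on paper, e.g. ``"Pz/C_fit"``.
    """

    exponents: Mapping[str, Fraction]
    label: str = field(default="")

    def __post_init__(self) -> None:
        cleaned = {s: Fraction(e) for s, e in self.exponents.items() if e != 0}
        object.__setattr__(self, "exponents", cleaned)
        if not self.label:
            object.__setattr__(self, "label", format_group(cleaned))

    def exponent_vector(self, symbols: Sequence[str]) -> tuple[Fraction, ...]:
        return tuple(self.exponents.get(s, Fraction(0)) for s in symbols)


@dataclass(frozen=True)
class PiBasis:
    """Ordered independent pi-groups plus the dependent group."""

    independent: tuple[PiGroup, ...]
    dependent: PiGroup
    symbols: tuple[str, ...]  # all variable symbols, input order

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.independent]

    def to_frame(self) -> pd.DataFrame:
        """Exponent table: one row per group, one column per symbol."""
        rows = []
        for g in (*self.independent, self.dependent):
            rows.append([float(e) for e in g.exponent_vector(self.symbols)])
        idx = self.labels + [self.dependent.label]
        return pd.DataFrame(rows, index=idx, columns=list(self.symbols))

    def report(self) -> str:
        lines = [
            f"{len(self.independent)} independent dimensionless group(s):",
            *(f"  pi_{i + 1} = {g.label}" for i, g in enumerate(self.independent)),
            f"dependent group: {self.dependent.label}",
        ]
        return "\n".join(lines)


def _exp_str(e: Fraction) -> str:
    return str(e) if e.denominator == 1 else f"({e})"


def format_group(exponents: Mapping[str, Fraction]) -> str:
    """Human-readable label, e.g. ``{"Bt": 1, "A": -1}`` -> ``"Bt/A"``."""
    num = [(s, e) for s, e in exponents.items() if e > 0]
    den = [(s, -e) for s, e in exponents.items() if e < 0]

    def side(terms: list[tuple[str, Fraction]]) -> str:
        parts = [s if e == 1 else f"{s}^{_exp_str(e)}" for s, e in terms]
        return "*".join(parts)

    if not num and not den:
        return "1"
    if not den:
        return side(num)
    num_str = side(num) if num else "1"
    den_str = side(den)
    if len(den) > 1:
        den_str = f"({den_str})"
    return f"{num_str}/{den_str}"


# ---------------------------------------------------------------------------
# exact linear algebra
# ---------------------------------------------------------------------------


def _rref(rows: list[list[Fraction]], n_pivot_cols: int) -> tuple[list[list[Fraction]], list[int]]:
    """In-place reduced row echelon form over Fractions.

    Only the first ``n_pivot_cols`` columns are eligible as pivots (so an
    augmented column is never pivoted on).  Returns the nonzero rows and
    the pivot column indices, in row order.
    """
    rows = [list(r) for r in rows]
    pivots: list[int] = []
    r = 0
    for c in range(n_pivot_cols):
        pr = next((i for i in range(r, len(rows)) if rows[i][c] != 0), None)
        if pr is None:
            continue
        rows[r], rows[pr] = rows[pr], rows[r]
        pv = rows[r][c]
        rows[r] = [x / pv for x in rows[r]]
        for i in range(len(rows)):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[r])]
        pivots.append(c)
        r += 1
        if r == len(rows):
            break
    return rows[:r] + [row for row in rows[r:] if any(x != 0 for x in row)], pivots


def _canonicalize(vec: list[Fraction], distinguished: int) -> list[Fraction]:
    """Scale to integer entries with gcd 1 and positive distinguished entry."""
    den = math.lcm(*(x.denominator for x in vec))
    ints = [int(x * den) for x in vec]
    g = math.gcd(*(abs(i) for i in ints))
    if g > 1:
        ints = [i // g for i in ints]
    if ints[distinguished] < 0:
        ints = [-i for i in ints]
    return [Fraction(i) for i in ints]


def build_dimensional_matrix(specs: Sequence[VariableSpec]) -> DimensionalMatrix:
    """Assemble the dimensional matrix, one column per spec in input order."""
    if not specs:
        raise DimensionalAnalysisError("no variable specs given")
    seen: set[str] = set()
    for s in specs:
        if s.symbol in seen:
            raise DimensionalAnalysisError(f"duplicate variable symbol {s.symbol!r}")
        seen.add(s.symbol)
    entries = tuple(
        tuple(s.dimensions[d] for s in specs) for d in BASE_DIMENSIONS
    )
    return DimensionalMatrix(symbols=tuple(s.symbol for s in specs), entries=entries)


def _scan_order(matrix: DimensionalMatrix, repeating: Sequence[str] | None) -> list[int]:
    """Column order in which pivots are sought.

    Preferred repeating variables come first (so they end up as pivots and
    absorb the balancing exponents); remaining columns follow in reverse
    input order, so early-listed variables become the free (distinguished)
    ones when no preference is given.
    """
    n = matrix.n_variables
    index = {s: j for j, s in enumerate(matrix.symbols)}
    if repeating:
        unknown = [s for s in repeating if s not in index]
        if unknown:
            raise DimensionalAnalysisError(
                f"repeating variable(s) {unknown} not among matrix symbols"
            )
        rep = [index[s] for s in repeating]
        rest = [j for j in range(n - 1, -1, -1) if j not in set(rep)]
        return rep + rest
    return list(range(n - 1, -1, -1))


def rational_nullspace(
    matrix: DimensionalMatrix,
    repeating: Sequence[str] | None = None,
) -> list[tuple[Fraction, ...]]:
    """Exact basis of the right null space of the dimensional matrix.

    Each returned vector has a distinguished free variable with positive
    exponent; the pivot ("repeating") variables absorb the balancing
    exponents.  ``repeating`` optionally names the variables to prefer as
    pivots — the classical repeating-variable choice of the Buckingham Pi
    procedure (characteristic scales such as the filter-bed diameter).
    With the biofilter defaults this yields exactly the ratios
    ``Pz/C_fit, Bt/A, P/C_fit, t0/T``.

    Returns ``n - rank`` vectors aligned with ``matrix.symbols``, in
    input order of their distinguished variables, each scaled to integer
    entries with overall gcd 1.
    """
    n = matrix.n_variables
    perm = _scan_order(matrix, repeating)
    permuted = [[row[j] for j in perm] for row in matrix.entries]
    red, pivots = _rref(permuted, n)
    pivot_set = set(pivots)
    free = [j for j in range(n) if j not in pivot_set]
    vectors: list[tuple[Fraction, ...]] = []
    for f in sorted(free, key=lambda j: perm[j]):
        v = [Fraction(0)] * n
        v[f] = Fraction(1)
        for row, p in zip(red, pivots):
            v[p] = -row[f]
        orig = [Fraction(0)] * n
        for j, val in enumerate(v):
            orig[perm[j]] = val
        vectors.append(tuple(_canonicalize(orig, perm[f])))
    return vectors


def check_dimensionless(group: PiGroup, specs: Sequence[VariableSpec]) -> bool:
    """True iff the group's net dimension exponents are all exactly zero."""
    by_symbol = {s.symbol: s for s in specs}
    unknown = set(group.exponents) - set(by_symbol)
    if unknown:
        raise DimensionalAnalysisError(
            f"group {group.label!r} uses unknown symbol(s) {sorted(unknown)}"
        )
    for d in BASE_DIMENSIONS:
        total = sum(
            (e * by_symbol[s].dimensions[d] for s, e in group.exponents.items()),
            Fraction(0),
        )
        if total != 0:
            return False
    return True


def _solve_exact(matrix: DimensionalMatrix, target: Sequence[Fraction]) -> list[Fraction]:
    """Particular exact solution x of M x = target, free variables zeroed.

    Pivots are again chosen right-to-left so the solution is expressed in
    the later (repeating) variables.  Raises if the system is inconsistent.
    """
    n = matrix.n_variables
    aug = [
        list(row[::-1]) + [t] for row, t in zip(matrix.entries, target)
    ]
    red, pivots = _rref(aug, n)
    x_rev = [Fraction(0)] * n
    for row, p in zip(red, pivots):
        x_rev[p] = row[n]
    x = x_rev[::-1]
    # consistency check against the original system
    for row, t in zip(matrix.entries, target):
        if sum((a * b for a, b in zip(row, x)), Fraction(0)) != t:
            raise DimensionalAnalysisError(
                "target dimension vector lies outside the column space of the "
                "independent variables; the dependent variable cannot be "
                "nondimensionalized"
            )
    return x


def construct_pi_basis(
    specs: Sequence[VariableSpec],
    repeating: Sequence[str] | None = None,
) -> PiBasis:
    """Build the full pi-basis for a variable system.

    The independent groups are the canonicalized null-space basis of the
    independent-variable dimensional matrix.  The dependent group divides
    the dependent variable by a power-product of independent variables
    with matching dimensions; when a single independent variable already
    has the right dimensions (influent carbon for the biofilter system)
    that simple ratio is used, so the dependent group resolves to
    ``EC_org/IC_org``.
    """
    dependents = [s for s in specs if s.role == "dependent"]
    if len(dependents) != 1:
        raise DimensionalAnalysisError(
            f"exactly one dependent variable required, found {len(dependents)}"
        )
    dep = dependents[0]
    indep = [s for s in specs if s.role == "independent"]
    if not indep:
        raise DimensionalAnalysisError("no independent variables")

    m = build_dimensional_matrix(indep)
    groups = tuple(
        PiGroup(exponents=dict(zip(m.symbols, vec)))
        for vec in rational_nullspace(m, repeating=repeating)
    )

    if dep.is_dimensionless:
        dep_group = PiGroup(exponents={dep.symbol: Fraction(1)})
    else:
        target = dep.dimension_vector()
        exact = [s for s in indep if s.dimension_vector() == target]
        if exact:
            x = [Fraction(1) if s.symbol == exact[0].symbol else Fraction(0) for s in indep]
        else:
            x = _solve_exact(m, target)
        exps = {dep.symbol: Fraction(1)}
        exps.update({s: -e for s, e in zip(m.symbols, x) if e != 0})
        dep_group = PiGroup(exponents=exps)
    return PiBasis(
        independent=groups,
        dependent=dep_group,
        symbols=tuple(s.symbol for s in specs),
    )


def evaluate_pi(
    basis: PiBasis,
    table: pd.DataFrame,
    include_dependent: bool = True,
) -> pd.DataFrame:
    """Evaluate every pi-group on each row of an observation table.

    Returns a frame with one column per independent group (plus the
    dependent group unless ``include_dependent=False``), preserving the
    input row index.  All variables entering any group must be strictly
    positive — fractional powers and downstream logs are undefined
    otherwise — and violations are reported with row index and symbol.
    """
    groups = list(basis.independent) + ([basis.dependent] if include_dependent else [])
    needed = sorted({s for g in groups for s in g.exponents})
    missing = [s for s in needed if s not in table.columns]
    if missing:
        raise DimensionalAnalysisError(f"table is missing column(s) {missing}")
    for s in needed:
        col = pd.to_numeric(table[s], errors="coerce")
        bad = table.index[~(col > 0)]
        if len(bad):
            raise DimensionalAnalysisError(
                f"non-positive or missing value for {s!r} at row(s) "
                f"{list(bad[:5])}; pi-groups require strictly positive inputs"
            )
    out = pd.DataFrame(index=table.index)
    for g in groups:
        val = np.ones(len(table))
        for s, e in g.exponents.items():
            val = val * np.power(table[s].to_numpy(dtype=float), float(e))
        out[g.label] = val
    return out
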