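"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations that share no code with the package's
algorithms: exhaustive support-subset EFM search via Fraction Gaussian
elimination, O(n^2) Pareto domination, a mass-action reaction quotient for
driving forces, and an independent formula renderer.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

from efcm.model import MetabolicModel


def _fraction_nullspace(rows: list[list[Fraction]], n_cols: int) -> list[list[Fraction]]:
    """Basis of the nullspace of a rational matrix, by Gaussian elimination."""
    mat = [row[:] for row in rows]
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        pivot = next((i for i in range(r, len(mat)) if mat[i][c] != 0), None)
        if pivot is None:
            continue
        mat[r], mat[pivot] = mat[pivot], mat[r]
        inv = mat[r][c]
        mat[r] = [x / inv for x in mat[r]]
        for i in range(len(mat)):
            if i != r and mat[i][c] != 0:
                f = mat[i][c]
                mat[i] = [a - f * b for a, b in zip(mat[i], mat[r])]
        pivots.append(c)
        r += 1
    free = [c for c in range(n_cols) if c not in pivots]
    basis = []
    for fc in free:
        vec = [Fraction(0)] * n_cols
        vec[fc] = Fraction(1)
        for i, pc in enumerate(pivots):
            vec[pc] = -mat[i][fc]
        basis.append(vec)
    return basis


def exhaustive_efm_supports(model: MetabolicModel) -> set[frozenset[str]]:
    """All EFM supports by testing every support subset.

    A support is elementary iff the stoichiometric matrix restricted to it
    has nullity exactly 1, the kernel vector is nonzero on the whole
    support, and the vector (or its negation) respects irreversibilities.
    """
    _, s_int = model.internal_stoichiometric_matrix()
    rxns = model.reactions
    n = len(rxns)
    found: set[frozenset[str]] = set()
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            rows = [[s_int[i][j] for j in subset] for i in range(len(s_int))]
            basis = _fraction_nullspace(rows, len(subset))
            if len(basis) != 1:
                continue
            v = basis[0]
            if any(x == 0 for x in v):
                continue
            for sign in (1, -1):
                ok = all(
                    rxns[j].reversible or sign * x > 0 for j, x in zip(subset, v)
                )
                if ok:
                    found.add(frozenset(rxns[j].id for j in subset))
                    break
    return found


def pareto_by_domination(points) -> set[int]:
    """Ids of non-dominated points under (maximize mu, maximize yield)."""
    front = set()
    for p in points:
        dominated = any(
            (q.mu >= p.mu and q.yield_g_per_cmol >= p.yield_g_per_cmol)
            and (q.mu > p.mu or q.yield_g_per_cmol > p.yield_g_per_cmol)
            for q in points
        )
        if not dominated:
            front.add(p.efm_id)
    return front


def mass_action_driving_force(reaction, concentrations: dict[str, float],
                              keq: float, sign: int = 1) -> float:
    """theta = -(Delta G)/RT = ln Keq - ln Q with Q the mass-action ratio."""
    ln_q = sum(
        float(n) * math.log(concentrations[m]) for m, n in reaction.stoich.items()
    )
    theta = math.log(keq) - ln_q
    return sign * theta


def render_formula_independent(stoich, reversible: bool) -> str:
    """Canonical formula text, written without reusing the package renderer."""
    def side(items):
        parts = []
        for name, coeff in sorted(items):
            coeff = abs(coeff)
            parts.append(name if coeff == 1 else f"{coeff} {name}")
        return " + ".join(parts)

    lhs = side((m, c) for m, c in stoich.items() if c < 0)
    rhs = side((m, c) for m, c in stoich.items() if c > 0)
    return f"{lhs} {'<=>' if reversible else '->'} {rhs}".strip()
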