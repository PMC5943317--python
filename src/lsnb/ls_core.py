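"""Loosely symmetric (LS) association strength on 2x2 contingency tables.

The LS model scores the strength of the relation between two binary events
``p`` and ``q`` from the cells of their contingency table::

              q      not-q
    p         a        b
    not-p     c        d

It is a conditional probability modified by the correction terms
``ac/(a+c)`` and ``bd/(b+d)``, which interpolate between no cognitive bias
(plain conditional probability) and complete symmetric / mutually exclusive
bias.  The classical comparators (conditional probability, delta-P, the
dual-factor heuristic) are provided for reference.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "ContingencyTable",
    "Direction",
    "DomainError",
    "correction_terms",
    "ls_strength",
    "comparator_strength",
]


class DomainError(ValueError):
    """Raised when a strength measure is undefined for the given table."""


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of a 2x2 contingency table.

    Cells may be frequencies or joint probabilities; every strength measure
    here is invariant under a positive rescaling of all four cells, so the
    two conventions are interchangeable.

    Attributes
    ----------
    a : float
        Co-occurrence of ``p`` and ``q``.
    b : float
        ``p`` without ``q``.
    c : float
        ``q`` without ``p``.
    d : float
        Neither ``p`` nor ``q``.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(not math.isfinite(x) for x in cells):
            raise DomainError(f"table cells must be finite, got {cells}")
        if any(x < 0 for x in cells):
            raise DomainError(f"table cells must be non-negative, got {cells}")
        if all(x == 0 for x in cells):
            raise DomainError("all four table cells are zero")

    def scaled(self, k: float) -> "ContingencyTable":
        """Return the table with every cell multiplied by ``k > 0``."""
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return ContingencyTable(self.a * k, self.b * k, self.c * k, self.d * k)


class Direction(enum.Enum):
    """Which conditional strength to evaluate."""

    Q_GIVEN_P = "q|p"
    NOTQ_GIVEN_P = "~q|p"
    P_GIVEN_Q = "p|q"
    NOTQ_GIVEN_NOTP = "~q|~p"


def _ratio(num: float, den: float) -> float:
    """``num / den`` with the 0/0 -> 0 convention used by the correction terms."""
    return 0.0 if den == 0 else num / den


def correction_terms(table: ContingencyTable) -> tuple[float, float]:
    """Return the bias correction terms ``(ac/(a+c), bd/(b+d))``.

    A zero denominator (which forces a zero numerator, since cells are
    non-negative) yields a zero term: the limit of the term as both cells
    shrink to zero, which keeps the model defined on sparse tables and
    reproduces the no-bias collapse to conditional probability.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    return _ratio(a * c, a + c), _ratio(b * d, b + d)


def ls_strength(table: ContingencyTable, direction: Direction = Direction.Q_GIVEN_P) -> float:
    """Evaluate the LS strength of the table in the requested direction.

    The four directions share the same template — a cell plus one correction
    term over a margin plus both correction terms — but pair different cells
    with different corrections:

    * ``Q_GIVEN_P``:      (a + bd/(b+d)) / (a + b + ac/(a+c) + bd/(b+d))
    * ``NOTQ_GIVEN_P``:   (b + ac/(a+c)) / (a + b + ac/(a+c) + bd/(b+d))
    * ``P_GIVEN_Q``:      (a + cd/(c+d)) / (a + c + ab/(a+b) + cd/(c+d))
    * ``NOTQ_GIVEN_NOTP``: (d + ac/(a+c)) / (c + d + ac/(a+c) + bd/(b+d))

    Raises
    ------
    DomainError
        If the selected denominator is zero even after the 0/0 -> 0
        convention for the correction terms.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    t_ac, t_bd = correction_terms(table)
    if direction is Direction.Q_GIVEN_P:
        num = a + t_bd
        den = a + b + t_ac + t_bd
    elif direction is Direction.NOTQ_GIVEN_P:
        num = b + t_ac
        den = a + b + t_ac + t_bd
    elif direction is Direction.P_GIVEN_Q:
        t_cd = _ratio(c * d, c + d)
        t_ab = _ratio(a * b, a + b)
        num = a + t_cd
        den = a + c + t_ab + t_cd
    elif direction is Direction.NOTQ_GIVEN_NOTP:
        num = d + t_ac
        den = c + d + t_ac + t_bd
    else:  # pragma: no cover - closed enumeration
        raise ValueError(f"unknown direction {direction!r}")
    if den == 0:
        raise DomainError(
            f"LS({direction.value}) undefined: zero denominator for cells "
            f"(a={a}, b={b}, c={c}, d={d})"
        )
    return num / den


def comparator_strength(table: ContingencyTable, model: str) -> float:
    """Evaluate a comparator strength measure on the table.

    Parameters
    ----------
    table : ContingencyTable
    model : {"cp", "delta_p", "dh"}
        ``cp`` is the plain conditional probability ``a/(a+b)``; ``delta_p``
        is ``a/(a+b) - c/(c+d)``; ``dh`` is the dual-factor heuristic
        ``sqrt(a/(a+b) * a/(a+c))``.

    Raises
    ------
    DomainError
        If a required marginal is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if model == "cp":
        if a + b == 0:
            raise DomainError("cp undefined: a + b = 0")
        return a / (a + b)
    if model == "delta_p":
        if a + b == 0 or c + d == 0:
            raise DomainError("delta_p undefined: zero marginal")
        return a / (a + b) - c / (c + d)
    if model == "dh":
        if a + b == 0 or a + c == 0:
            raise DomainError("dh undefined: zero marginal")
        return math.sqrt((a / (a + b)) * (a / (a + c)))
    raise ValueError(f"unknown comparator model {model!r}; expected cp, delta_p or dh")
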