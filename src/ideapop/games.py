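"""Payoff structures and canonical 2x2 game fixtures.

A symmetric game is given by a single payoff matrix ``A = (a_ij)``: ``a_ij``
is the payoff to an individual of type *i* interacting with an individual of
type *j*.  An asymmetric (two-role) game is given by a bi-matrix ``(A, B)``
where both matrices are indexed (own action, opponent action): ``a_ij`` is
player A's payoff when A plays *i* against B's *j*, and ``b_ji`` is player B's
payoff in the same encounter.

The qualitative replicator flow of a symmetric 2x2 game is determined by the
sign pattern of the invasion margins ``a11 - a21`` and ``a22 - a12``:
both positive -> coordination (bistable), both negative -> coexistence
(stable interior mixture), one strategy (weakly) dominant -> dominance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

__all__ = [
    "PayoffMatrix",
    "PayoffBimatrix",
    "GameClass",
    "SYMMETRIC_CATALOGUE",
    "ASYMMETRIC_CATALOGUE",
    "make_symmetric_game",
    "make_asymmetric_game",
    "classify_symmetric",
    "game_from_config",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """2x2 payoff matrix with entries ``a11, a12, a21, a22`` (dimensionless)."""

    a11: float
    a12: float
    a21: float
    a22: float

    def __post_init__(self) -> None:
        for name in ("a11", "a12", "a21", "a22"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"payoff entry {name}={v!r} is not finite")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[Sequence[float]]) -> "PayoffMatrix":
        a = np.asarray(a, dtype=float)
        if a.shape != (2, 2):
            raise ValueError(f"payoff matrix must be 2x2, got shape {a.shape}")
        return cls(a[0, 0], a[0, 1], a[1, 0], a[1, 1])


@dataclass(frozen=True)
class PayoffBimatrix:
    """Payoff pair for an asymmetric game.

    ``A`` holds player A's payoffs ``a_ij`` (A plays i, B plays j); ``B`` holds
    player B's payoffs indexed the same way from B's perspective, i.e.
    ``B.array[j, i]`` is B's payoff when B plays j against A's i.
    """

    A: PayoffMatrix
    B: PayoffMatrix

    @classmethod
    def from_arrays(cls, a, b) -> "PayoffBimatrix":
        return cls(PayoffMatrix.from_array(a), PayoffMatrix.from_array(b))

    def is_zero_sum(self, tol: float = 0.0) -> bool:
        """True iff ``a_ij + b_ji = 0`` for all i, j."""
        return bool(np.all(np.abs(self.A.array + self.B.array.T) <= tol))


#: Game classes of symmetric 2x2 games under replicator flow.
GAME_CLASSES = ("coexistence", "dominance", "coordination", "other")


@dataclass(frozen=True)
class GameClass:
    label: str

    def __post_init__(self) -> None:
        if self.label not in GAME_CLASSES:
            raise ValueError(f"unknown game class {self.label!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


# Canonical fixture entries.  The structural results exercised in the tests
# (fixed-point counts, stability patterns, fixation-time phenomenology) are
# class properties and do not depend on the specific entries; these canonical
# representatives are documented in docs/methods.md.
SYMMETRIC_CATALOGUE: dict[str, tuple[float, float, float, float]] = {
    # interior attractor at x* = 2/3 for lambda = 0, moving to 0.5 as lambda grows
    "coexistence": (1.0, 3.0, 2.0, 1.0),
    # strategy 1 strictly dominant; constant payoff advantage pi1 - pi2 = 1
    "dominance": (3.0, 1.0, 2.0, 0.0),
    # bistable; unstable interior point at x = 1/3 for lambda = 0
    "coordination": (2.0, 0.0, 0.0, 1.0),
    # all payoffs equal: pure drift
    "neutral": (1.0, 1.0, 1.0, 1.0),
}

ASYMMETRIC_CATALOGUE: dict[str, tuple[list, list]] = {
    # zero-sum: A wants to match, B wants to mismatch; cyclic flow at lambda=0
    "matching_pennies": ([[1.0, -1.0], [-1.0, 1.0]], [[-1.0, 1.0], [1.0, -1.0]]),
    # A's action 1 strictly dominates; B coordinates with A -> one stable corner (1,1)
    "asym_dominance": ([[2.0, 0.0], [1.0, -1.0]], [[1.0, -1.0], [-1.0, 1.0]]),
    # symmetric coordination bi-matrix: interior saddle flanked by two stable
    # corners at (0,0), (1,1); the A<->B exchange symmetry makes both stable
    # points merge with the saddle simultaneously at the bifurcation
    "hyperbolic": ([[1.0, -1.0], [-1.0, 1.0]], [[1.0, -1.0], [-1.0, 1.0]]),
}


def make_symmetric_game(
    name_or_entries: Union[str, Sequence[float], Sequence[Sequence[float]]],
) -> PayoffMatrix:
    """Build a symmetric 2x2 game from a catalogue name or explicit entries.

    Entries may be a flat ``(a11, a12, a21, a22)`` or a 2x2 nested sequence.
    """
    if isinstance(name_or_entries, str):
        try:
            return PayoffMatrix(*SYMMETRIC_CATALOGUE[name_or_entries])
        except KeyError:
            raise KeyError(
                f"unknown symmetric game {name_or_entries!r}; "
                f"catalogue: {sorted(SYMMETRIC_CATALOGUE)}"
            ) from None
    arr = np.asarray(name_or_entries, dtype=float)
    if arr.shape == (4,):
        return PayoffMatrix(*arr)
    return PayoffMatrix.from_array(arr)


def make_asymmetric_game(name_or_entries) -> PayoffBimatrix:
    """Build an asymmetric game from a catalogue name or an ``(A, B)`` pair."""
    if isinstance(name_or_entries, str):
        try:
            a, b = ASYMMETRIC_CATALOGUE[name_or_entries]
        except KeyError:
            raise KeyError(
                f"unknown asymmetric game {name_or_entries!r}; "
                f"catalogue: {sorted(ASYMMETRIC_CATALOGUE)}"
            ) from None
        return PayoffBimatrix.from_arrays(a, b)
    a, b = name_or_entries
    return PayoffBimatrix.from_arrays(a, b)


def classify_symmetric(matrix: PayoffMatrix) -> GameClass:
    """Classify a symmetric 2x2 game by the sign pattern of its invasion margins.

    coordination iff a11 > a21 and a22 > a12 (each pure strategy resists
    invasion); coexistence iff both reversed; dominance iff one row weakly
    dominates the other with at least one strict inequality; other otherwise
    (e.g. the neutral game).
    """
    d1 = matrix.a11 - matrix.a21  # advantage of 1 against a 1-opponent
    d2 = matrix.a22 - matrix.a12  # advantage of 2 against a 2-opponent
    if d1 > 0 and d2 > 0:
        return GameClass("coordination")
    if d1 < 0 and d2 < 0:
        return GameClass("coexistence")
    row1_weak = matrix.a11 >= matrix.a21 and matrix.a12 >= matrix.a22
    row2_weak = matrix.a21 >= matrix.a11 and matrix.a22 >= matrix.a12
    row1_strict = matrix.a11 > matrix.a21 or matrix.a12 > matrix.a22
    row2_strict = matrix.a21 > matrix.a11 or matrix.a22 > matrix.a12
    if row1_weak and row1_strict:
        return GameClass("dominance")
    if row2_weak and row2_strict:
        return GameClass("dominance")
    return GameClass("other")


def game_from_config(source) -> Union[PayoffMatrix, PayoffBimatrix]:
    """Load a game from a config mapping or a YAML/JSON file path.

    Accepted forms under the ``game`` key (or as the top-level mapping)::

        game: {name: coordination}
        game: {a: [[2, 0], [0, 1]]}
        game: {a: [[...]], b: [[...]]}
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = json.loads(text) if str(source).endswith(".json") else yaml.safe_load(text)
    else:
        data = source
    spec = data.get("game", data)
    if not isinstance(spec, dict):
        raise ValueError("game config must be a mapping")
    unknown = set(spec) - {"name", "a", "b"}
    if unknown:
        raise ValueError(f"unknown game config keys: {sorted(unknown)}")
    if "name" in spec:
        name = spec["name"]
        if name in SYMMETRIC_CATALOGUE:
            return make_symmetric_game(name)
        if name in ASYMMETRIC_CATALOGUE:
            return make_asymmetric_game(name)
        raise KeyError(f"unknown game name {name!r}")
    if "b" in spec:
        return PayoffBimatrix.from_arrays(spec["a"], spec["b"])
    if "a" in spec:
        return PayoffMatrix.from_array(spec["a"])
    raise ValueError("game config needs 'name' or 'a' (and optionally 'b')")
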