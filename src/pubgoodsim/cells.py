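"""Per-cell state and update rules.

Each pathogen cell carries a vitality ``v`` in [0, 1] — its propensity
to survive and divide — and a binary drug-resistance state. Four rules
act on a cell each time step:

* **release**: the cell deposits one unit of its product variant into
  its own location. The drug destroys fraction ``d`` (the dose) of the
  sensitive variant at release; the resistant variant is untouched.
* **vitality update**: ``v' = v + min([p], 1) * (1 - v)`` where ``[p]``
  is the local total product concentration (sensitive + resistant),
  minus an optional metabolic cost for carrying resistance.
* **death trial**: the cell dies with probability ``1 - v``.
* **division**: with probability 0.9, if a von Neumann neighbour
  location is vacant, the cell is replaced by two daughters, each with
  half the parent's vitality; one stays in place, the other takes a
  uniformly chosen vacant neighbour; each daughter independently flips
  resistance state with probability mu (default 1e-3, symmetric).

These scalar functions define the model semantics; the engine runs a
compiled vectorised equivalent that is tested against them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .lattice import ProductField

__all__ = [
    "Cell",
    "DrugDose",
    "CellRates",
    "release_product",
    "update_vitality",
    "death_trial",
    "divide",
]


@dataclass(frozen=True)
class Cell:
    vitality: float
    resistant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.vitality <= 1.0:
            raise ValueError(f"vitality must be in [0, 1], got {self.vitality}")


@dataclass(frozen=True)
class DrugDose:
    """Scalar dose in [0, 1]: the fraction of drug-sensitive product
    destroyed at release. 1.0 is the full dose with maximal effect."""

    value: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"dose must be in [0, 1], got {self.value}")


@dataclass(frozen=True)
class CellRates:
    """Per-step cell event rates and amounts.

    reproduction_probability: chance a surviving cell with a vacant
        neighbour divides this step.
    mutation_probability: per-daughter chance of flipping resistance
        state at division (symmetric, both directions).
    release_amount: product units released per cell per step.
    resistance_cost: vitality decrement per step for resistant cells
        (0 by default: the product variant is the only difference
        between resistant and sensitive cells).
    """

    reproduction_probability: float = 0.90
    mutation_probability: float = 1e-3
    release_amount: float = 1.0
    resistance_cost: float = 0.0

    def __post_init__(self) -> None:
        for name in ("reproduction_probability", "mutation_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.release_amount <= 0:
            raise ValueError("release_amount must be positive")
        if self.resistance_cost < 0:
            raise ValueError("resistance_cost must be >= 0")


def release_product(
    cell: Cell,
    sensitive_field: ProductField,
    resistant_field: ProductField,
    location: tuple[int, int],
    dose: DrugDose,
    rates: CellRates,
) -> None:
    """Deposit the cell's product at its location (in place).

    A resistant cell adds ``release_amount`` to the resistant field; a
    sensitive cell adds ``release_amount * (1 - dose)`` to the
    sensitive field — the drug degrades the sensitive variant only.
    """
    if cell.resistant:
        resistant_field.concentrations[location] += rates.release_amount
    else:
        sensitive_field.concentrations[location] += rates.release_amount * (
            1.0 - dose.value
        )


def update_vitality(
    cell: Cell, local_concentration: float, resistance_cost: float = 0.0
) -> Cell:
    """Logistic vitality gain from local product: ``dv = [p](1 - v)``.

    ``[p]`` is clamped at 1 so vitality stays a probability ingredient;
    a resistance carrying cost (if any) is subtracted afterwards and
    the result clamped to [0, 1].
    """
    if local_concentration < 0:
        raise ValueError("negative local concentration")
    p = min(local_concentration, 1.0)
    v = cell.vitality + p * (1.0 - cell.vitality)
    if cell.resistant:
        v -= resistance_cost
    v = min(max(v, 0.0), 1.0)
    return replace(cell, vitality=v)


def death_trial(cell: Cell, rng: np.random.Generator) -> bool:
    """Return True (cell dies) with probability ``1 - v``."""
    return bool(rng.random() < 1.0 - cell.vitality)


def divide(
    parent: Cell,
    vacant_neighbors: list[tuple[int, int]],
    rng: np.random.Generator,
    rates: CellRates,
) -> tuple[Cell, Cell, tuple[int, int]] | None:
    """Attempt division; return (daughter_in_place, daughter_moved, site).

    No vacant neighbour means no division (no random draw consumed).
    Otherwise division happens with ``reproduction_probability``; both
    daughters get half the parent's vitality, each independently
    mutates its resistance state with ``mutation_probability``, one
    replaces the parent and the other moves to a uniformly chosen
    vacant neighbour. Returns None when no division occurs.
    """
    if not vacant_neighbors:
        return None
    if rng.random() >= rates.reproduction_probability:
        return None
    k = len(vacant_neighbors)
    site = vacant_neighbors[min(int(rng.random() * k), k - 1)]
    v_daughter = parent.vitality * 0.5
    flip_in_place = rng.random() < rates.mutation_probability
    flip_moved = rng.random() < rates.mutation_probability
    d1 = Cell(v_daughter, parent.resistant ^ flip_in_place)
    d2 = Cell(v_daughter, parent.resistant ^ flip_moved)
    return d1, d2, site
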