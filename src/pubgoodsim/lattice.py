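"""Discrete 2D habitat: occupancy grid and diffusible product fields.

The habitat is a rectangular lattice of microenvironments. Each location
carries a concentration of two product variants (drug-sensitive and
drug-resistant). Per time step, each product diffuses once down its
concentration gradient: for every pair of von Neumann (4-)adjacent
locations ``(i, j)`` an amount ``(T/4) * (c_i - c_j)`` flows from the
higher- to the lower-concentration location, where ``T`` in ``[0, 1]``
is the dimensionless transfer coefficient. All pairwise fluxes are
computed from the pre-step field (synchronous update), so a producer
retains fraction ``1 - T`` of a freshly released unit and shares
fraction ``T`` among its (up to four) neighbours: ``T = 0`` is a fully
private, cell-intrinsic product and ``T = 1`` a fully shared public
good. Boundaries are no-flux (reflecting), so total mass is conserved
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "LatticeConfig",
    "ProductVariant",
    "ProductField",
    "diffuse",
    "total_mass",
    "clear",
]


class ProductVariant(str, Enum):
    SENSITIVE = "sensitive"
    RESISTANT = "resistant"


@dataclass(frozen=True)
class LatticeConfig:
    """Shape and topology of the habitat.

    The neighbourhood is von Neumann (the four orthogonal neighbours)
    and boundaries are reflecting; both are fixed, recorded here so the
    topology used by every operator is explicit in run metadata.
    """

    width: int = 51
    height: int = 51
    neighborhood: str = "von_neumann"
    boundary: str = "no_flux"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.neighborhood != "von_neumann":
            raise ValueError(f"unsupported neighborhood: {self.neighborhood!r}")
        if self.boundary != "no_flux":
            raise ValueError(f"unsupported boundary: {self.boundary!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def n_locations(self) -> int:
        return self.width * self.height


@dataclass
class ProductField:
    """Per-location concentration of one product variant."""

    concentrations: np.ndarray
    variant: ProductVariant = ProductVariant.SENSITIVE

    @classmethod
    def zeros(cls, config: LatticeConfig, variant: ProductVariant) -> "ProductField":
        return cls(np.zeros(config.shape, dtype=np.float64), variant)

    def validate(self, config: LatticeConfig | None = None) -> None:
        if config is not None and self.concentrations.shape != config.shape:
            raise ValueError(
                f"field shape {self.concentrations.shape} does not match "
                f"lattice shape {config.shape}"
            )
        if np.any(self.concentrations < 0):
            raise ValueError("negative concentration in product field")


def _neighbor_count(shape: tuple[int, int]) -> np.ndarray:
    """Number of von Neumann neighbours per location (2, 3 or 4)."""
    deg = np.full(shape, 4.0)
    deg[0, :] -= 1.0
    deg[-1, :] -= 1.0
    deg[:, 0] -= 1.0
    deg[:, -1] -= 1.0
    return deg


def diffuse_array(conc: np.ndarray, transfer: float) -> np.ndarray:
    """One synchronous diffusion step on a raw concentration array.

    Equivalent to summing the pairwise flux ``(T/4)(c_i - c_j)`` over
    all adjacent pairs; written as a stencil for speed. Stable and
    non-negativity preserving for all ``T`` in [0, 1] because each
    location sends at most ``deg * T/4 <= 1`` of its own content.
    """
    if not 0.0 <= transfer <= 1.0:
        raise ValueError(f"transfer coefficient must be in [0, 1], got {transfer}")
    if transfer == 0.0:
        return conc.copy()
    f = transfer / 4.0
    nb = np.zeros_like(conc)
    nb[1:, :] += conc[:-1, :]
    nb[:-1, :] += conc[1:, :]
    nb[:, 1:] += conc[:, :-1]
    nb[:, :-1] += conc[:, 1:]
    deg = _neighbor_count(conc.shape)
    return conc * (1.0 - f * deg) + f * nb


def diffuse(
    field: ProductField, transfer: float, config: LatticeConfig | None = None
) -> ProductField:
    """Apply one diffusion step with transfer coefficient ``transfer``."""
    field.validate(config)
    return ProductField(diffuse_array(field.concentrations, transfer), field.variant)


def total_mass(field: ProductField) -> float:
    """Total product over the lattice (conserved by :func:`diffuse`)."""
    return float(field.concentrations.sum())


def clear(field: ProductField) -> ProductField:
    """Zero the field (full per-step product turnover)."""
    return ProductField(np.zeros_like(field.concentrations), field.variant)
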