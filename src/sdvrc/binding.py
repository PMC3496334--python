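"""Effective diffusion under binding, and cytoplasm-exploration timescales.

A molecule that spends part of its time freely diffusing and the rest bound
to a much larger partner (DNA, a plasmid, a large complex) shows an
effective DC equal to the time-weighted average of the two states.
Conversely, a measured DC below the curve prediction quantifies the bound
fraction — e.g. a repressor diffusing an order of magnitude slower than
predicted spends ~90% of its time on DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BindingScenario",
    "effective_D",
    "bound_fraction_from_Deff",
    "exploration_time",
]


@dataclass(frozen=True)
class BindingScenario:
    """Two-state (free/bound) diffusion scenario.

    ``f_free`` is the fraction of time spent freely diffusing; the DCs are
    in um^2/s and the cell volume in um^3.
    """

    f_free: float
    D_free: float
    D_bound: float
    cell_volume: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_free <= 1.0):
            raise ValueError("f_free must lie in [0, 1]")
        if not (self.D_free >= self.D_bound > 0):
            raise ValueError("require D_free >= D_bound > 0")
        if not (self.cell_volume > 0):
            raise ValueError("cell volume must be positive")


def effective_D(s: BindingScenario) -> float:
    """Time-share weighted DC: ``f_free*D_free + (1-f_free)*D_bound``."""
    return s.f_free * s.D_free + (1.0 - s.f_free) * s.D_bound


def bound_fraction_from_Deff(D_eff: float, D_free: float, D_bound: float) -> float:
    """Bound-time fraction inferred from a measured effective DC.

    Inverse of :func:`effective_D`: ``(D_free - D_eff) / (D_free - D_bound)``.
    A measured DC outside [D_bound, D_free] is inconsistent with the
    two-state model and raises.
    """
    if not (D_free > D_bound > 0):
        raise ValueError("require D_free > D_bound > 0")
    if not (D_bound <= D_eff <= D_free):
        raise ValueError(
            f"measured D_eff={D_eff} outside [D_bound={D_bound}, D_free={D_free}]: "
            "inconsistent with the two-state model"
        )
    return (D_free - D_eff) / (D_free - D_bound)


def exploration_time(D: float, cell_volume: float = 1.0) -> float:
    """Time (s) to explore a cell of the given volume (um^3) by diffusion.

    Convention: the 3-D mean-squared displacement ``6*D*t`` reaches the
    squared characteristic length ``L = V**(1/3)``, i.e.
    ``t = V**(2/3) / (6*D)``.  Isolated here so an alternative prefactor
    convention is a one-line change.
    """
    if not (D > 0):
        raise ValueError("diffusion coefficient must be positive")
    if not (cell_volume > 0):
        raise ValueError("cell volume must be positive")
    return cell_volume ** (2.0 / 3.0) / (6.0 * D)
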