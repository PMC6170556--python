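"""Grey relational analysis as an independent level classifier.

Given one expectation per pollutant (the monitoring vector ``a``) and the
matrix ``b`` of level expectations (levels × pollutants, from the standard
clouds), both are made dimensionless by dividing each column by its level-1
entry.  The grey relational coefficient of monitoring value d_j against
level value f_ij is

    ξ_ij = (Δmin + ρ·Δmax) / (|d_j − f_ij| + ρ·Δmax)

with Δmin/Δmax the global minimum/maximum of |d_j − f_ij| over the whole
matrix and ρ the resolution coefficient (0.5 by default).  Each pollutant's
grey relational degree r_j is the column maximum of ξ, and the level
attaining it is the pollutant's grey level — used here to cross-check the
cloud-model classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GreyInputs",
    "GreyAssessment",
    "dimensionless",
    "relational_coefficients",
    "degree_and_level",
    "grey_assess",
]


@dataclass(frozen=True)
class GreyInputs:
    """Monitoring vector ``a`` (one expectation per indicator), limiting
    matrix ``b`` (level expectations, levels × indicators) and the
    resolution coefficient ``rho``."""

    a: np.ndarray
    b: np.ndarray
    rho: float = 0.5
    indicators: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.ndim != 1 or b.ndim != 2:
            raise ValueError("a must be a vector and b a levels x indicators matrix")
        if b.shape[1] != a.size:
            raise ValueError(
                f"column mismatch: a has {a.size} indicators, b has {b.shape[1]}"
            )
        if not (0 < self.rho <= 1):
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if self.indicators is not None and len(self.indicators) != a.size:
            raise ValueError("indicator names do not match a's length")


@dataclass(frozen=True)
class GreyAssessment:
    """Full grey-relational run: dimensionless data, coefficient matrix,
    degrees and per-indicator levels (1-based)."""

    d: np.ndarray
    f: np.ndarray
    xi: np.ndarray
    r: np.ndarray
    levels: tuple[int, ...]
    degenerate: bool = False
    indicators: tuple[str, ...] | None = None


def dimensionless(inputs: GreyInputs) -> tuple[np.ndarray, np.ndarray]:
    """Divide monitoring values and level limits by the level-1 limits.

    Returns (d, f) with d_j = a_j / b_1j and f_ij = b_ij / b_1j; f's first
    row is identically 1.
    """
    b1 = inputs.b[0]
    if np.any(b1 <= 0):
        j = int(np.argmin(b1))
        name = inputs.indicators[j] if inputs.indicators else f"column {j}"
        raise ZeroDivisionError(
            f"level-1 limiting value for {name} is not positive; cannot normalise"
        )
    return inputs.a / b1, inputs.b / b1


def relational_coefficients(
    d: np.ndarray, f: np.ndarray, rho: float = 0.5
) -> tuple[np.ndarray, bool]:
    """Grey relational coefficient matrix ξ.

    Δmin and Δmax are global over all (i, j).  Returns (xi, degenerate);
    when every distance is zero (Δmax == 0) the matrix is all ones and
    flagged degenerate instead of raising.
    """
    d = np.asarray(d, dtype=float)
    f = np.asarray(f, dtype=float)
    if f.ndim != 2 or d.shape != (f.shape[1],):
        raise ValueError("shape mismatch between d and f")
    if not (0 < rho <= 1):
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    delta = np.abs(d[np.newaxis, :] - f)
    dmin, dmax = float(delta.min()), float(delta.max())
    if dmax == 0.0:
        return np.ones_like(delta), True
    xi = (dmin + rho * dmax) / (delta + rho * dmax)
    return xi, False


def degree_and_level(xi: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Per-column grey relational degree r_j = max_i ξ_ij and the level
    attaining it (1-based; exact ties go to the more severe level)."""
    xi = np.asarray(xi, dtype=float)
    if xi.ndim != 2 or xi.size == 0:
        raise ValueError("xi must be a non-empty levels x indicators matrix")
    r = xi.max(axis=0)
    m = xi.shape[0]
    # scan from the most severe row down so ties resolve upward in severity
    levels = tuple(
        int(m - np.argmax(xi[::-1, j] == r[j]) - 1) + 1 for j in range(xi.shape[1])
    )
    return r, levels


def grey_assess(inputs: GreyInputs) -> GreyAssessment:
    """Run the full grey relational pipeline on one set of inputs."""
    d, f = dimensionless(inputs)
    xi, degenerate = relational_coefficients(d, f, inputs.rho)
    r, levels = degree_and_level(xi)
    return GreyAssessment(
        d=d,
        f=f,
        xi=xi,
        r=r,
        levels=levels,
        degenerate=degenerate,
        indicators=inputs.indicators,
    )
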