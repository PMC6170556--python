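"""Normal cloud models: forward/backward generators and level classification.

A cloud model represents a qualitative concept (e.g. "Moderate air
pollution") by three numerical characteristics:

* ``ex`` — expectation, the most representative value of the concept;
* ``en`` — entropy, the spread of values the concept accepts (fuzziness);
* ``he`` — hyper-entropy, the uncertainty of ``en`` itself, visible as the
  "thickness" of the cloud of (x, mu) drops.

The forward generator samples drops (x, mu) from the three characteristics
via a two-stage normal scheme; the backward generator is a moment estimator
recovering (ex, en, he) from observed values.  Classification against an
ordered family of standard clouds uses a Gaussian similarity in the
expectations and the maximum membership principle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CloudModel",
    "BackwardResult",
    "CloudDrop",
    "DropSample",
    "SimilarityVector",
    "membership",
    "forward_generate",
    "backward_estimate",
    "similarity",
    "classify",
]


@dataclass(frozen=True)
class CloudModel:
    """Numerical characteristics (ex, en, he) of one normal cloud.

    All three share the unit of the underlying indicator (µg/m³, mg/m³ or
    index points); ``en`` and ``he`` must be non-negative and all fields
    finite.
    """

    ex: float
    en: float
    he: float

    def __post_init__(self) -> None:
        for name in ("ex", "en", "he"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"CloudModel.{name} must be finite, got {v!r}")
        if self.en < 0:
            raise ValueError(f"entropy must be >= 0, got {self.en}")
        if self.he < 0:
            raise ValueError(f"hyper-entropy must be >= 0, got {self.he}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ex, self.en, self.he)


@dataclass(frozen=True)
class BackwardResult(CloudModel):
    """Backward-generator estimate; ``clipped`` records whether the
    hyper-entropy formula's absolute value rescued a negative
    variance-minus-entropy² difference."""

    clipped: bool = False


@dataclass(frozen=True)
class CloudDrop:
    """One sampled drop: value ``x``, its per-drop entropy draw ``en_prime``
    and membership ``mu`` = exp(−(x − Ex)²/(2·En′²))."""

    x: float
    en_prime: float
    mu: float


@dataclass(frozen=True)
class DropSample:
    """An ordered collection of drops from one forward-generator run.

    ``resample_count`` counts rejected non-positive En′ draws (possible when
    he > 0); ``degenerate`` flags an en == 0 input, for which every drop sits
    at the expectation with membership 1.
    """

    drops: tuple[CloudDrop, ...]
    n: int
    seed: int | None = None
    resample_count: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n < 1 or len(self.drops) != self.n:
            raise ValueError("drop count must match n >= 1")

    @property
    def x(self) -> np.ndarray:
        return np.array([d.x for d in self.drops])

    @property
    def mu(self) -> np.ndarray:
        return np.array([d.mu for d in self.drops])


@dataclass(frozen=True)
class SimilarityVector:
    """Similarities λ_1..λ_m of an assessed cloud to each level's standard
    cloud, plus the arg-max level (1-based; ties go to the more severe
    level)."""

    lambdas: tuple[float, ...]
    best_level: int

    def __post_init__(self) -> None:
        if not self.lambdas:
            raise ValueError("lambdas must be non-empty")
        if not 1 <= self.best_level <= len(self.lambdas):
            raise ValueError("best_level out of range")

    @property
    def best_lambda(self) -> float:
        return self.lambdas[self.best_level - 1]


def membership(model: CloudModel, x: float, en_prime: float) -> float:
    """Gaussian membership of ``x`` in ``model`` at entropy draw ``en_prime``.

    Returns exp(−(x − ex)² / (2·en_prime²)), in (0, 1].
    """
    if en_prime <= 0:
        raise ValueError(f"en_prime must be > 0, got {en_prime}")
    return math.exp(-((x - model.ex) ** 2) / (2.0 * en_prime**2))


def forward_generate(model: CloudModel, n: int, seed: int = 0) -> DropSample:
    """Sample ``n`` cloud drops from ``model``.

    For each drop: draw En′ ~ N(en, he), then x ~ N(ex, En′), then
    mu = exp(−(x − ex)²/(2·En′²)).  Non-positive En′ draws are rejected and
    redrawn (counted in ``resample_count``).  With en == 0 the sample is
    degenerate — every drop is (ex, 1) — and flagged rather than an error,
    since constant observed data is legal downstream.  Deterministic given
    ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if model.en == 0:
        drops = tuple(CloudDrop(model.ex, 0.0, 1.0) for _ in range(n))
        return DropSample(drops, n, seed=seed, degenerate=True)

    rng = np.random.default_rng(seed)
    resamples = 0
    drops: list[CloudDrop] = []
    while len(drops) < n:
        en_prime = float(rng.normal(model.en, model.he))
        if en_prime <= 0:
            resamples += 1
            continue
        x = float(rng.normal(model.ex, en_prime))
        drops.append(CloudDrop(x, en_prime, membership(model, x, en_prime)))
    return DropSample(tuple(drops), n, seed=seed, resample_count=resamples)


def backward_estimate(values: Sequence[float] | np.ndarray) -> BackwardResult:
    """Moment-based backward cloud generator.

    ex is the sample mean; en = sqrt(π/2) times the mean absolute deviation
    about ex; he = sqrt(|S²_{n−1} − en²|), where S²_{n−1} is the sample
    variance with divisor n−1.  The absolute value guards against a negative
    difference (near-constant or light-tailed data); when it fires, the
    result's ``clipped`` flag is set.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input values must all be finite")

    ex = float(x.mean())
    en = float(math.sqrt(math.pi / 2.0) * np.abs(x - ex).mean())
    diff = float(x.var(ddof=1) - en**2)
    he = math.sqrt(abs(diff))
    return BackwardResult(ex=ex, en=en, he=he, clipped=diff < 0)


def similarity(assessed: CloudModel, standard: CloudModel) -> float:
    """Similarity λ of an assessed cloud to one standard cloud.

    λ = exp(−(Ex − Ex_j)² / (2·En_j²)) — only the assessed expectation and
    the standard cloud's (Ex_j, En_j) enter.
    """
    if standard.en <= 0:
        raise ValueError("standard cloud has degenerate (zero) entropy")
    return math.exp(-((assessed.ex - standard.ex) ** 2) / (2.0 * standard.en**2))


def classify(
    assessed: CloudModel, standards: Sequence[CloudModel]
) -> SimilarityVector:
    """Classify ``assessed`` against standards ordered by increasing severity.

    Returns the full λ vector and the maximum-membership level (1-based).
    Exact λ ties break toward the more severe level — protective reporting
    for a health-advisory context.
    """
    if len(standards) == 0:
        raise ValueError("standards must be non-empty")
    lambdas = tuple(similarity(assessed, s) for s in standards)
    best = max(range(len(lambdas)), key=lambda j: (lambdas[j], j))
    return SimilarityVector(lambdas=lambdas, best_level=best + 1)
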