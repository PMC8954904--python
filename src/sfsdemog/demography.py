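"""Piecewise-exponential single-population demographic models.

Time is measured backward from sampling, in generations; epoch intervals
are half-open ``[t_start, t_end)`` and tile ``[0, inf)``.  Within an epoch
the diploid effective size follows ``Ne(t) = size_start * exp(rate * (t -
t_start))``, so ``rate = 0`` gives a constant epoch.

Two model families are provided:

- the *bottleneck model*: a population of pre-decline size ``Ne_pre`` is
  reduced to ``Ne_bot`` during a fixed window (22 to 11 generations before
  sampling, matching the commercial-sealing era at a ten-year generation
  time) and then grows exponentially to ``Ne_post`` at sampling;
- the *null model*: a single constant size ``Ne_post``.

The exponential recovery rate is not a free parameter: it is the complex
parameter ``log(Ne_bot / Ne_post) / 11`` (natural log), which makes Ne(t)
continuous at the end of the bottleneck.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

__all__ = [
    "T_BOTTLENECK_START",
    "T_BOTTLENECK_END",
    "DEFAULT_MU",
    "GENERATION_TIME_YEARS",
    "Epoch",
    "DemographicModel",
    "SearchRange",
    "growth_rate",
    "build_bottleneck_model",
    "build_null_model",
    "default_search_ranges",
]

#: Start of the bottleneck, generations before sampling.
T_BOTTLENECK_START = 22.0
#: End of the bottleneck (start of the recovery), generations before sampling.
T_BOTTLENECK_END = 11.0
#: Default per-site per-generation mutation rate (marine-mammal scale).
DEFAULT_MU = 2.5e-8
#: Generation time in years; used only to annotate reports in calendar
#: units, never in any computation.
GENERATION_TIME_YEARS = 10.0


@dataclass(frozen=True)
class Epoch:
    """One piecewise-exponential segment of the size trajectory.

    Parameters
    ----------
    t_start, t_end
        Generations before sampling; half-open interval ``[t_start, t_end)``.
        ``t_end = inf`` for the oldest epoch.
    size_start
        Diploid effective size at ``t_start``.
    rate
        Backward-time exponential rate; 0 for a constant epoch.
    """

    t_start: float
    t_end: float
    size_start: float
    rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(f"epoch requires t_start < t_end, got [{self.t_start}, {self.t_end})")
        if self.t_start < 0:
            raise ValueError("t_start must be >= 0")
        if not self.size_start > 0:
            raise ValueError("size_start must be positive")
        if not math.isfinite(self.rate):
            raise ValueError("rate must be finite")

    def size_at(self, t: float) -> float:
        """Ne at time ``t`` (must lie in this epoch)."""
        if self.rate == 0.0:
            return self.size_start
        return self.size_start * math.exp(self.rate * (t - self.t_start))


@dataclass(frozen=True)
class DemographicModel:
    """An ordered, contiguous list of epochs covering ``[0, inf)``."""

    name: str
    epochs: tuple[Epoch, ...]
    free_parameters: tuple[str, ...]
    fixed: dict[str, float] = field(
        default_factory=lambda: {
            "T_bot_start": T_BOTTLENECK_START,
            "T_bot_end": T_BOTTLENECK_END,
            "mu": DEFAULT_MU,
            "generation_time": GENERATION_TIME_YEARS,
        }
    )

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("model needs at least one epoch")
        if self.epochs[0].t_start != 0.0:
            raise ValueError("first epoch must start at t = 0")
        if not math.isinf(self.epochs[-1].t_end):
            raise ValueError("last epoch must extend to infinity")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if a.t_end != b.t_start:
                raise ValueError(f"epochs must tile time: gap/overlap at {a.t_end} vs {b.t_start}")

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_parameters)

    def size_at(self, t: float) -> float:
        """Evaluate Ne(t); left-continuous at epoch boundaries."""
        return size_at(self, t)

    # -- plain-text config round trip ------------------------------------

    def to_config(self) -> str:
        """Serialize to a YAML document (round-trips via :meth:`from_config`)."""
        doc = {
            "name": self.name,
            "free_parameters": list(self.free_parameters),
            "fixed": dict(self.fixed),
            "epochs": [
                {
                    "t_start": e.t_start,
                    "t_end": "inf" if math.isinf(e.t_end) else e.t_end,
                    "size_start": e.size_start,
                    "rate": e.rate,
                }
                for e in self.epochs
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_config(cls, text: str) -> "DemographicModel":
        doc = yaml.safe_load(text)
        epochs = tuple(
            Epoch(
                t_start=float(e["t_start"]),
                t_end=math.inf if e["t_end"] in ("inf", math.inf) else float(e["t_end"]),
                size_start=float(e["size_start"]),
                rate=float(e.get("rate", 0.0)),
            )
            for e in doc["epochs"]
        )
        return cls(
            name=doc["name"],
            epochs=epochs,
            free_parameters=tuple(doc.get("free_parameters", ())),
            fixed={k: float(v) for k, v in doc.get("fixed", {}).items()},
        )


@dataclass(frozen=True)
class SearchRange:
    """Starting-value range for one free parameter.

    The range constrains only where replicate starting values are drawn
    (uniformly or log-uniformly); the optimizer may move estimates above
    ``upper``.
    """

    parameter: str
    lower: float
    upper: float
    scale: str = "uniform"  # "uniform" | "log-uniform"

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError(f"need 0 < lower < upper, got ({self.lower}, {self.upper})")
        if self.scale not in ("uniform", "log-uniform"):
            raise ValueError(f"unknown scale {self.scale!r}")

    def draw(self, rng) -> float:
        if self.scale == "uniform":
            return float(rng.uniform(self.lower, self.upper))
        return float(math.exp(rng.uniform(math.log(self.lower), math.log(self.upper))))


def growth_rate(ne_bot: float, ne_post: float, duration: float = T_BOTTLENECK_END) -> float:
    """Backward-time exponential rate taking ``ne_post`` to ``ne_bot``.

    Returns the natural-log rate ``GR = log(ne_bot / ne_post) / duration``
    such that ``ne_post * exp(GR * duration) = ne_bot``; negative whenever
    the population grew (``ne_post > ne_bot``).
    """
    if not (ne_bot > 0 and ne_post > 0):
        raise ValueError("effective sizes must be positive")
    if not duration > 0:
        raise ValueError("duration must be positive")
    return math.log(ne_bot / ne_post) / duration


def build_bottleneck_model(ne_pre: float, ne_bot: float, ne_post: float) -> DemographicModel:
    """Three-epoch bottleneck-and-recovery model.

    Backward in time: exponential shrink from ``ne_post`` at sampling to
    ``ne_bot`` at 11 generations, constant ``ne_bot`` from 11 to 22
    generations, constant ``ne_pre`` beyond 22 generations.
    """
    for v, nm in ((ne_pre, "ne_pre"), (ne_bot, "ne_bot"), (ne_post, "ne_post")):
        if not v > 0:
            raise ValueError(f"{nm} must be positive, got {v}")
    duration = T_BOTTLENECK_END
    gr = growth_rate(ne_bot, ne_post, duration)
    epochs = (
        Epoch(0.0, T_BOTTLENECK_END, ne_post, gr),
        Epoch(T_BOTTLENECK_END, T_BOTTLENECK_START, ne_bot, 0.0),
        Epoch(T_BOTTLENECK_START, math.inf, ne_pre, 0.0),
    )
    return DemographicModel(
        name="bottleneck", epochs=epochs, free_parameters=("Ne_pre", "Ne_bot", "Ne_post")
    )


def build_null_model(ne_post: float) -> DemographicModel:
    """Single constant-size model (no growth, no decline)."""
    if not ne_post > 0:
        raise ValueError(f"ne_post must be positive, got {ne_post}")
    return DemographicModel(
        name="null", epochs=(Epoch(0.0, math.inf, ne_post, 0.0),), free_parameters=("Ne_post",)
    )


def size_at(model: DemographicModel, t: float) -> float:
    """Ne(t) for ``t >= 0`` generations before sampling."""
    if t < 0:
        raise ValueError("t must be >= 0")
    for e in model.epochs:
        if e.t_start <= t < e.t_end:
            return e.size_at(t)
    raise AssertionError("epochs do not tile [0, inf)")  # unreachable by construction


def default_search_ranges(model_family: str) -> tuple[SearchRange, ...]:
    """Starting-value ranges used for replicate initialisation.

    ``Ne_post`` is drawn log-uniformly on [5000, 50000]; for the bottleneck
    family ``Ne_pre`` is uniform on [5000, 50000] and ``Ne_bot`` uniform on
    [10, 250].
    """
    ne_post = SearchRange("Ne_post", 5_000.0, 50_000.0, "log-uniform")
    if model_family == "null":
        return (ne_post,)
    if model_family == "bottleneck":
        return (
            SearchRange("Ne_pre", 5_000.0, 50_000.0, "uniform"),
            SearchRange("Ne_bot", 10.0, 250.0, "uniform"),
            ne_post,
        )
    raise ValueError(f"unknown model family {model_family!r}")
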