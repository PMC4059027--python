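"""Seeded random-variate generation for the ED simulator.

All randomness flows through :class:`RandomStream` objects: one independent,
reproducible substream per stochastic purpose (arrivals, durations, waiting
tolerances, routing, boarding, travel).  Service and processing times are
Gamma random variables parameterized by their mean and variance, which is the
natural parameterization when only measures of central tendency (plus a
dispersion assumption) are available for each process step.  Patient arrivals
follow a non-homogeneous Poisson process with piecewise-constant (hourly)
intensity; provider room-to-room travel is exponential.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RandomStream",
    "GammaParams",
    "gamma_from_mean_var",
    "sample_nhpp",
    "sample_duration",
    "sample_travel",
]


class RandomStream:
    """An independent, labelled random substream.

    The same ``(seed, label)`` pair always yields the identical variate
    sequence; distinct labels yield statistically independent substreams of
    the same master seed.  Labels are hashed with CRC-32 so the mapping is
    stable across processes and Python versions.
    """

    def __init__(self, seed: int, label: str):
        if not isinstance(seed, (int, np.integer)):
            raise TypeError("seed must be an integer")
        self.seed = int(seed)
        self.label = str(label)
        key = zlib.crc32(self.label.encode("utf-8"))
        self._rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )

    @property
    def rng(self) -> np.random.Generator:
        return self._rng

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RandomStream(seed={self.seed}, label={self.label!r})"


@dataclass(frozen=True)
class GammaParams:
    """Shape/scale parameters of a Gamma distribution (scale in minutes)."""

    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2


def gamma_from_mean_var(mean: float, variance: float) -> GammaParams:
    """Convert a (mean, variance) pair to Gamma shape/scale.

    shape = mean^2 / variance, scale = variance / mean, so the returned
    parameters reproduce the requested moments exactly.
    """
    if not (mean > 0):
        raise ValueError(f"mean must be positive, got {mean}")
    if not (variance > 0):
        raise ValueError(f"variance must be positive, got {variance}")
    return GammaParams(shape=mean * mean / variance, scale=variance / mean)


def sample_nhpp(
    hourly_rate,
    horizon_hours: float,
    stream: RandomStream,
) -> np.ndarray:
    """Draw one realization of a non-homogeneous Poisson arrival process.

    ``hourly_rate`` is a 24-vector of arrivals/hour; the intensity is the
    step function that repeats this daily profile over ``horizon_hours``.
    Generation is interval-wise (per hourly step a Poisson count with
    uniformly scattered arrival times), which is exact for piecewise-constant
    intensity.  Returns strictly increasing arrival times in **minutes** on
    ``[0, horizon_hours * 60)``.
    """
    rate = np.asarray(hourly_rate, dtype=float)
    if rate.ndim != 1 or rate.size != 24:
        raise ValueError("hourly_rate must be a 24-vector")
    if np.any(rate < 0):
        raise ValueError("arrival rates must be nonnegative")
    if not (horizon_hours > 0):
        raise ValueError("horizon must be positive")

    rng = stream.rng
    times: list[np.ndarray] = []
    n_whole = int(np.floor(horizon_hours))
    # Whole hourly steps, then a possible fractional final step.
    for h in range(n_whole):
        lam = rate[h % 24]
        if lam <= 0:
            continue
        k = rng.poisson(lam)
        if k:
            times.append((h + rng.random(k)) * 60.0)
    frac = horizon_hours - n_whole
    if frac > 0:
        lam = rate[n_whole % 24] * frac
        if lam > 0:
            k = rng.poisson(lam)
            if k:
                times.append((n_whole + frac * rng.random(k)) * 60.0)

    if not times:
        return np.empty(0)
    out = np.sort(np.concatenate(times))
    # Ties have probability zero but would break strict ordering; nudge.
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = np.nextafter(out[i - 1], np.inf)
    return out


def sample_duration(spec, stream: RandomStream) -> float:
    """Draw one Gamma service/processing duration (minutes) from a spec.

    ``spec`` is any object with ``mean`` and ``variance`` attributes (see
    :class:`edsim.config.DurationSpec`).  A zero variance denotes a
    degenerate (deterministic) duration and returns the mean exactly.
    """
    mean = float(spec.mean)
    variance = float(spec.variance)
    if mean == 0.0:
        return 0.0
    if variance == 0.0:
        return mean
    p = gamma_from_mean_var(mean, variance)
    return float(stream.rng.gamma(p.shape, p.scale))


def sample_travel(
    mean: float,
    clock_time: float,
    provider_class: str,
    stream: RandomStream,
) -> float:
    """Draw an exponential provider travel time (minutes).

    Hook signature carries the clock time and provider class so travel means
    can be time/provider modulated; the default behaviour is a constant mean
    per provider class (time modulation off).  A zero mean returns exactly 0.
    """
    if mean < 0:
        raise ValueError("travel mean must be nonnegative")
    if mean == 0:
        return 0.0
    return float(stream.rng.exponential(mean))
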