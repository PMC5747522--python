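"""Periodic light/dark (LD) stimulation protocols.

An LD protocol is a whole-field luminance square wave: ``n_cycles``
repetitions of a light half-cycle (``light_s`` seconds at ``light_lux``)
followed by a dark half-cycle (``dark_s`` seconds at ``dark_lux``).
Stimulation always begins with the light half-cycle, which fixes the phase
convention for every downstream alignment. Time is 0-based seconds from
recording start and every epoch is half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "LDProtocol",
    "LuminanceTrace",
    "protocol_frequency",
    "protocol_duration",
    "luminance_trace",
]


class InvalidProtocolError(ValueError):
    """Raised when LD protocol parameters are physically meaningless."""


@dataclass(frozen=True)
class LDProtocol:
    """A periodic light/dark stimulus.

    Parameters
    ----------
    light_s, dark_s:
        Durations of the light and dark half-cycles in seconds. The tested
        range of full-cycle durations in the source experiments was
        2–480 s with equal halves.
    n_cycles:
        Number of LD cycles (5–25 in the source experiments).
    light_lux, dark_lux:
        Luminance of the two half-cycles; dark is 0 lux in routine use.
    onset_s:
        Time of the first light onset relative to recording start.
    """

    light_s: float
    dark_s: float
    n_cycles: int
    light_lux: float = 200.0
    dark_lux: float = 0.0
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        if not (self.light_s > 0 and self.dark_s > 0):
            raise InvalidProtocolError(
                f"half-cycle durations must be positive, got "
                f"light_s={self.light_s}, dark_s={self.dark_s}"
            )
        if int(self.n_cycles) != self.n_cycles or self.n_cycles < 1:
            raise InvalidProtocolError(f"n_cycles must be a positive integer, got {self.n_cycles}")
        if not (self.light_lux > self.dark_lux >= 0):
            raise InvalidProtocolError(
                f"need light_lux > dark_lux >= 0, got {self.light_lux}, {self.dark_lux}"
            )
        if self.onset_s < 0:
            raise InvalidProtocolError(f"onset_s must be >= 0, got {self.onset_s}")

    @property
    def cycle_s(self) -> float:
        """Duration of one full LD cycle in seconds."""
        return self.light_s + self.dark_s

    @property
    def offset_s(self) -> float:
        """Time of stimulation offset (end of the last dark half-cycle)."""
        return self.onset_s + protocol_duration(self)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LDProtocol":
        return cls(**d)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "LDProtocol":
        """Read a protocol from a JSON or YAML file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


@dataclass(frozen=True)
class LuminanceTrace:
    """Sampled luminance time course, piecewise constant on a uniform grid."""

    t: np.ndarray
    lux: np.ndarray

    def __post_init__(self) -> None:
        if self.t.shape != self.lux.shape:
            raise ValueError("t and lux must have the same shape")


def protocol_frequency(p: LDProtocol) -> float:
    """Temporal frequency of the LD stimulus in Hz.

    The reciprocal of the full LD-cycle duration, e.g. 0.5 Hz for
    L/D 1 s/1 s and ~0.002 Hz for L/D 240 s/240 s.
    """
    return 1.0 / p.cycle_s


def protocol_duration(p: LDProtocol) -> float:
    """Total stimulation duration in seconds (n_cycles full LD cycles)."""
    return p.n_cycles * p.cycle_s


def luminance_trace(
    p: LDProtocol,
    step_s: float,
    pre_s: float = 0.0,
    post_s: float = 0.0,
    post_condition: str = "dark",
) -> LuminanceTrace:
    """Sample the stimulus luminance on a uniform grid.

    The trace covers ``[onset - pre_s, offset + post_s)``; before onset the
    luminance is ``dark_lux``. After offset it is held at the constant test
    condition: ``"dark"`` (``dark_lux``, used for light-suppressed cells) or
    ``"light"`` (``light_lux``, used for light-activated cells). Sample k
    holds the luminance of the half-open interval containing its left edge,
    so boundaries that are not multiples of ``step_s`` snap to the grid.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    if step_s > min(p.light_s, p.dark_s):
        raise ValueError(
            f"step_s={step_s} larger than the shortest half-cycle "
            f"{min(p.light_s, p.dark_s)}"
        )
    if pre_s < 0 or post_s < 0:
        raise ValueError("paddings must be non-negative")
    if post_condition not in ("dark", "light"):
        raise ValueError(f"post_condition must be 'dark' or 'light', got {post_condition!r}")

    t0 = p.onset_s - pre_s
    n = int(round((pre_s + protocol_duration(p) + post_s) / step_s))
    t = t0 + step_s * np.arange(n)
    lux = np.full(n, p.dark_lux, dtype=float)
    rel = t - p.onset_s
    in_stim = (rel >= 0) & (rel < protocol_duration(p))
    phase = np.mod(rel[in_stim], p.cycle_s)
    lux[in_stim] = np.where(phase < p.light_s, p.light_lux, p.dark_lux)
    after = rel >= protocol_duration(p)
    lux[after] = p.light_lux if post_condition == "light" else p.dark_lux
    return LuminanceTrace(t=t, lux=lux)
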