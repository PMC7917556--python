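"""Voltage-command protocols.

Two stimulus families are used to probe inner-hair-cell (IHC) synapses:

* **step** — depolarizations from the holding potential (−87 mV) to a set of
  test potentials, presented in a pseudo-randomized order.  The dual-color
  experiments use 50-ms steps to −57, −49, −45, −41, −37, −33, −25 and
  −17 mV; pool-dynamics experiments vary the duration (2–100 ms) at a fixed
  potential.
* **ramp** — a linear ramp from −87 to +63 mV at 1 mV/ms (150 ms), used to
  map the Ca2+-channel fluorescence–voltage relation in a single sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InvalidProtocolError

HOLDING_MV = -87.0
#: Step potentials of the dual-color release protocol (mV).
RELEASE_STEP_LEVELS_MV = (-57.0, -49.0, -45.0, -41.0, -37.0, -33.0, -25.0, -17.0)
#: Ramp of the Ca2+ fluorescence-voltage protocol: start, stop (mV) at 1 mV/ms.
CA_RAMP_RANGE_MV = (-87.0, 63.0)
CA_RAMP_RATE_MV_PER_MS = 1.0


@dataclass(frozen=True)
class VoltageProtocol:
    """A step or ramp voltage-command protocol.

    ``order`` is the pseudo-randomized presentation order: a permutation of
    ``range(len(levels_mV))`` drawn deterministically from ``seed``.
    """

    kind: str
    holding_mV: float = HOLDING_MV
    levels_mV: tuple[float, ...] = ()
    duration_ms: float = 50.0
    ramp_range_mV: tuple[float, float] = CA_RAMP_RANGE_MV
    ramp_rate_mV_per_ms: float = CA_RAMP_RATE_MV_PER_MS
    order: tuple[int, ...] = ()
    seed: int = 0

    @property
    def ramp_duration_ms(self) -> float:
        start, stop = self.ramp_range_mV
        return (stop - start) / self.ramp_rate_mV_per_ms

    def ordered_levels(self) -> tuple[float, ...]:
        """Step levels in presentation order."""
        return tuple(self.levels_mV[i] for i in self.order)

    def ramp_voltage(self, t_ms: np.ndarray) -> np.ndarray:
        """Command voltage at time ``t_ms`` after ramp onset (clipped to ends)."""
        start, stop = self.ramp_range_mV
        v = start + self.ramp_rate_mV_per_ms * np.asarray(t_ms, dtype=float)
        return np.clip(v, min(start, stop), max(start, stop))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        d = dict(d)
        for key in ("levels_mV", "ramp_range_mV", "order"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def make_protocol(kind: str, *, levels_mV=None, duration_ms: float = 50.0,
                  ramp_range_mV=CA_RAMP_RANGE_MV,
                  ramp_rate_mV_per_ms: float = CA_RAMP_RATE_MV_PER_MS,
                  holding_mV: float = HOLDING_MV, seed: int = 0) -> VoltageProtocol:
    """Build a validated :class:`VoltageProtocol`.

    For ``kind="step"`` the presentation ``order`` is a seed-deterministic
    permutation of the level indices (identity for a single level).

    Raises
    ------
    InvalidProtocolError
        Empty level list, non-positive duration/rate, or levels outside
        the physiological command range [−90, +70] mV.
    """
    if kind == "step":
        if not levels_mV:
            raise InvalidProtocolError("step protocol needs at least one level")
        levels = tuple(float(v) for v in levels_mV)
        if any(v < -90.0 or v > 70.0 for v in levels):
            raise InvalidProtocolError(f"levels outside [-90, 70] mV: {levels}")
        if duration_ms <= 0:
            raise InvalidProtocolError("step duration must be positive")
        if len(levels) == 1:
            order = (0,)
        else:
            rng = np.random.default_rng(seed)
            order = tuple(int(i) for i in rng.permutation(len(levels)))
        return VoltageProtocol(kind="step", holding_mV=holding_mV,
                               levels_mV=levels, duration_ms=duration_ms,
                               order=order, seed=seed)
    if kind == "ramp":
        if ramp_rate_mV_per_ms <= 0:
            raise InvalidProtocolError("ramp rate must be positive")
        start, stop = (float(ramp_range_mV[0]), float(ramp_range_mV[1]))
        if stop <= start:
            raise InvalidProtocolError("ramp stop must exceed start")
        return VoltageProtocol(kind="ramp", holding_mV=holding_mV,
                               ramp_range_mV=(start, stop),
                               ramp_rate_mV_per_ms=float(ramp_rate_mV_per_ms),
                               seed=seed)
    raise InvalidProtocolError(f"unknown protocol kind: {kind!r}")
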