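"""Flat-punch indentation analysis of phantom-material samples.

A cylindrical punch of radius ``a`` cyclically indents a flat sample; the
compressive elastic modulus follows the classical flat-punch relation

    E = 2 * (1 - nu^2) * q * a / w

with ``q`` the mean contact pressure (force amplitude over the punch face
pi*a^2), ``a`` the punch radius and ``w`` the displacement amplitude.  The
quantity multiplying q is dimensionless (a/w), so E carries the units of q.
Note: ``a`` enters as the punch RADIUS; calling it a "loaded area" would be
dimensionally inconsistent with the classical solution this reproduces.

Elastic (in-phase) loading is verified via the phase angle between the
displacement and force fundamentals before the modulus is reported.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["IndentationTrace", "ModulusResult", "steady_state_cycles",
           "phase_shift", "elastic_modulus", "synthesize_trace"]


class InsufficientCyclesError(ValueError):
    """Trace too short for the requested skip/use cycle counts."""


@dataclass
class IndentationTrace:
    """Time / displacement / force samples plus test geometry.

    Units: seconds, mm, N.  Displacement is the indentation depth (positive
    into the sample), force the reaction (positive in compression).
    """

    t_s: np.ndarray
    displacement_mm: np.ndarray
    force_n: np.ndarray
    a_mm: float = 3.0
    thickness_mm: float = 6.0
    poisson: float = 0.495
    frequency_hz: float = 0.5
    precompression_strain: float = 0.02
    strain_amplitude: float = 0.05
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        if not (self.t_s.shape == self.displacement_mm.shape == self.force_n.shape):
            raise ValueError("time, displacement and force must have equal length")
        if self.t_s.size and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("time samples must be strictly increasing")
        if self.a_mm <= 0:
            raise ValueError("indenter radius must be > 0")
        if not 0.0 <= self.poisson < 0.5 + 1e-12:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if self.frequency_hz <= 0:
            raise ValueError("loading frequency must be > 0")

    @classmethod
    def from_csv(cls, csv_path, header_path=None, **kwargs) -> "IndentationTrace":
        """Read a (time, displacement, force) CSV plus optional JSON header."""
        df = pd.read_csv(csv_path)
        cols = list(df.columns[:3])
        geometry = {}
        if header_path is not None:
            geometry = json.loads(Path(header_path).read_text())
        geometry.update(kwargs)
        return cls(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(),
                   df[cols[2]].to_numpy(), **geometry)

    def to_csv(self, csv_path, header_path=None) -> None:
        pd.DataFrame({"t_s": self.t_s, "displacement_mm": self.displacement_mm,
                      "force_n": self.force_n}).to_csv(csv_path, index=False)
        if header_path is not None:
            Path(header_path).write_text(json.dumps({
                "a_mm": self.a_mm, "thickness_mm": self.thickness_mm,
                "poisson": self.poisson, "frequency_hz": self.frequency_hz,
                "precompression_strain": self.precompression_strain,
                "strain_amplitude": self.strain_amplitude,
            }, indent=2))


@dataclass
class ModulusResult:
    """Indentation modulus with the quantities entering its computation."""

    e_pa: float
    q_pa: float
    w_mm: float
    phase_deg: float
    cycles_used: int
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"e_pa": self.e_pa, "q_pa": self.q_pa, "w_mm": self.w_mm,
                "phase_deg": self.phase_deg, "cycles_used": self.cycles_used,
                "warnings": list(self.warnings)}


def _upcrossings(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Interpolated times where the detrended signal crosses zero upward."""
    d = x - x.mean()
    sign = d > 0
    idx = np.nonzero(~sign[:-1] & sign[1:])[0]
    frac = -d[idx] / (d[idx + 1] - d[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def steady_state_cycles(trace: IndentationTrace, skip_cycles: int = 10,
                        use_cycles: int = 20) -> IndentationTrace:
    """Trim a trace to its last ``use_cycles`` full loading periods.

    The trace must span at least ``skip_cycles + use_cycles`` periods of
    ``frequency_hz``; cycle boundaries are located by upward zero-crossings
    of the detrended displacement.
    """
    period = 1.0 / trace.frequency_hz
    duration = trace.t_s[-1] - trace.t_s[0]
    dt = float(np.median(np.diff(trace.t_s))) if trace.t_s.size > 1 else 0.0
    needed = (skip_cycles + use_cycles) * period
    if duration + 1.5 * dt < needed:
        raise InsufficientCyclesError(
            f"trace spans {duration:.3g} s but {needed:.3g} s "
            f"({skip_cycles}+{use_cycles} cycles at {trace.frequency_hz} Hz) are required"
        )
    crossings = _upcrossings(trace.t_s, trace.displacement_mm)
    if crossings.size < use_cycles + 1:
        raise InsufficientCyclesError("too few displacement cycles located in trace")
    t0, t1 = crossings[-(use_cycles + 1)], crossings[-1]
    sel = (trace.t_s >= t0) & (trace.t_s <= t1)
    meta = dict(trace.meta)
    meta["cycles_used"] = use_cycles
    return replace(trace, t_s=trace.t_s[sel], displacement_mm=trace.displacement_mm[sel],
                   force_n=trace.force_n[sel], meta=meta)


def phase_shift(trace: IndentationTrace) -> float:
    """Phase lag of force behind displacement, in degrees.

    Both signals are projected onto the loading-frequency fundamental; the
    returned angle is wrapped to (-180, 180] and is ~0 for elastic loading.
    """
    if trace.t_s.size < 4:
        raise ValueError("trace too short for a phase estimate")
    w = 2 * math.pi * trace.frequency_hz
    basis = np.exp(-1j * w * trace.t_s)
    x = trace.displacement_mm - trace.displacement_mm.mean()
    f = trace.force_n - trace.force_n.mean()
    cx = np.trapezoid(x * basis, trace.t_s)
    cf = np.trapezoid(f * basis, trace.t_s)
    if abs(cx) < 1e-15 or abs(cf) < 1e-15:
        raise ValueError("zero-amplitude signal; cannot estimate phase")
    phi = np.angle(cx) - np.angle(cf)  # positive = force lags displacement
    return float(np.degrees(np.angle(np.exp(1j * phi))))


def _amplitude(x: np.ndarray, t: np.ndarray, frequency_hz: float, mode: str) -> float:
    if mode == "peak":
        return float(x.max() - x.min()) / 2.0
    if mode == "fourier":
        w = 2 * math.pi * frequency_hz
        c = np.trapezoid((x - x.mean()) * np.exp(-1j * w * t), t)
        return float(2.0 * abs(c) / (t[-1] - t[0]))
    raise ValueError("amplitude mode must be 'peak' or 'fourier'")


def elastic_modulus(trace: IndentationTrace, skip_cycles: int = 10,
                    use_cycles: int = 20, mode: str = "peak",
                    phase_threshold_deg: float = 5.0,
                    pretrimmed: bool = False) -> ModulusResult:
    """Compute the flat-punch modulus from a cyclic indentation trace.

    Amplitudes default to half the steady-state peak-to-peak range
    (``mode="peak"``); ``mode="fourier"`` uses the fundamental's magnitude,
    which is robust under additive noise.  A phase shift above
    ``phase_threshold_deg`` attaches a warning (loading not purely elastic)
    instead of raising.
    """
    steady = trace if pretrimmed else steady_state_cycles(trace, skip_cycles, use_cycles)
    phi = phase_shift(steady)
    w_mm = _amplitude(steady.displacement_mm, steady.t_s, steady.frequency_hz, mode)
    f_amp = _amplitude(steady.force_n, steady.t_s, steady.frequency_hz, mode)
    if w_mm <= 0:
        raise ValueError("zero displacement amplitude; modulus undefined")
    area_mm2 = math.pi * steady.a_mm ** 2
    q_pa = f_amp / area_mm2 * 1e6  # N/mm^2 -> Pa
    e_pa = 2.0 * (1.0 - steady.poisson ** 2) * q_pa * steady.a_mm / w_mm
    notes = []
    if abs(phi) > phase_threshold_deg:
        msg = (f"phase shift {phi:.2f} deg exceeds the elastic threshold "
               f"{phase_threshold_deg} deg; loading may be viscoelastic")
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)
    return ModulusResult(e_pa=float(e_pa), q_pa=float(q_pa), w_mm=float(w_mm),
                         phase_deg=float(phi),
                         cycles_used=int(steady.meta.get("cycles_used", use_cycles)),
                         warnings=notes)


def synthesize_trace(e_pa: float, a_mm: float = 3.0, thickness_mm: float = 6.0,
                     poisson: float = 0.495, frequency_hz: float = 0.5,
                     precompression_strain: float = 0.02,
                     strain_amplitude: float = 0.05, n_cycles: int = 30,
                     samples_per_cycle: int = 200, phase_lag_deg: float = 0.0,
                     snr_db: float | None = None, seed: int = 0) -> IndentationTrace:
    """Generate a cyclic trace whose modulus analysis should recover ``e_pa``.

    The force is derived from the displacement by inverting the flat-punch
    relation, optionally lagged by ``phase_lag_deg`` and corrupted with
    white Gaussian noise at the given signal-to-noise ratio (dB, applied to
    both channels).
    """
    w_amp_mm = strain_amplitude * thickness_mm
    offset_mm = precompression_strain * thickness_mm
    n = n_cycles * samples_per_cycle
    t = np.arange(n) / (samples_per_cycle * frequency_hz)
    omega = 2 * math.pi * frequency_hz
    disp = offset_mm + w_amp_mm * np.sin(omega * t)
    q_pa = e_pa * w_amp_mm / (2.0 * (1.0 - poisson ** 2) * a_mm)
    f_amp_n = q_pa * math.pi * a_mm ** 2 * 1e-6
    f_offset = q_pa * math.pi * a_mm ** 2 * 1e-6 * offset_mm / w_amp_mm
    force = f_offset + f_amp_n * np.sin(omega * t - math.radians(phase_lag_deg))
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        for sig in (disp, force):
            power = np.var(sig - sig.mean())
            sig += rng.normal(0.0, math.sqrt(power / 10 ** (snr_db / 10.0)), size=n)
    return IndentationTrace(t, disp, force, a_mm=a_mm, thickness_mm=thickness_mm,
                            poisson=poisson, frequency_hz=frequency_hz,
                            precompression_strain=precompression_strain,
                            strain_amplitude=strain_amplitude,
                            meta={"synth_e_pa": e_pa, "phase_lag_deg": phase_lag_deg,
                                  "snr_db": snr_db, "seed": seed})
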