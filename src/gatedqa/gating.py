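"""Breathing waveforms and gating protocols.

A gating protocol reduces a breathing waveform to a *displacement kernel*:
the discrete distribution of superior-inferior platform positions over the
accepted acquisition time, plus the duty cycle (accepted / total time).
Convolving the static activity map with that kernel is the forward model of
a gated acquisition.

Prospective protocols accept a window starting a fixed delay (default
280 ms) after each cycle's end-inhale or end-exhale extremum, with a width
given as a fraction of the cycle duration.  Retrospective protocols keep
everything and split each cycle (maximum to maximum) into N equal time
phases, one kernel per phase.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

DEFAULT_TRIGGER_DELAY_S = 0.28
DEFAULT_DT_S = 0.01
DEFAULT_BIN_MM = 1.0


@dataclass
class BreathingWaveform:
    t: np.ndarray        # s, strictly increasing, uniform step
    z: np.ndarray        # mm, superior-inferior displacement
    y_hyst: np.ndarray   # mm, secondary-axis hysteresis loop
    period: float        # s, nominal cycle length
    pattern_id: str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.y_hyst = np.asarray(self.y_hyst, dtype=float)
        dt = np.diff(self.t)
        if len(dt) == 0 or dt.min() <= 0:
            raise ValueError("time samples must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time step must be uniform")
        if dt[0] > 0.02 + 1e-12:
            raise ValueError("time step must be <= 0.02 s")

    @property
    def amplitude(self) -> float:
        return float(self.z.max() - self.z.min())


@dataclass
class GatingProtocol:
    kind: str  # prospective_inhale | prospective_exhale | retrospective
    window_fraction: float | None = None
    trigger_delay: float = DEFAULT_TRIGGER_DELAY_S
    n_phases: int | None = None
    reject_irregular: bool = False
    irregular_tolerance: float = 0.25
    protocol_id: str = ""

    def __post_init__(self) -> None:
        if self.kind in ("prospective_inhale", "prospective_exhale"):
            if self.window_fraction is None or not 0 < self.window_fraction < 1:
                raise ValueError("prospective protocols need 0 < window_fraction < 1")
        elif self.kind == "retrospective":
            if self.n_phases is None or self.n_phases < 1:
                raise ValueError("retrospective protocols need n_phases >= 1")
        else:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.trigger_delay < 0:
            raise ValueError("trigger_delay must be >= 0")
        if not self.protocol_id:
            if self.kind == "retrospective":
                self.protocol_id = f"{self.n_phases}_phases"
            else:
                side = "exhale" if self.kind.endswith("exhale") else "inhale"
                self.protocol_id = f"{side}_{int(round(self.window_fraction * 100))}"


@dataclass
class DisplacementKernel:
    offsets: np.ndarray   # mm, bin centers
    weights: np.ndarray   # probabilities, sum to 1
    duty_cycle: float

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("kernel weights must be >= 0")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("kernel weights must sum to 1")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError("duty cycle must be in (0, 1]")

    @classmethod
    def delta(cls, offset_mm: float = 0.0, duty_cycle: float = 1.0) -> "DisplacementKernel":
        return cls(np.array([offset_mm]), np.array([1.0]), duty_cycle)

    @property
    def mean_offset(self) -> float:
        return float(np.dot(self.offsets, self.weights))

    @property
    def spread(self) -> float:
        """Weighted standard deviation of the displacement (mm)."""
        mu = self.mean_offset
        return float(np.sqrt(np.dot(self.weights, (self.offsets - mu) ** 2)))


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

def make_waveform(
    pattern: str,
    peak_to_peak: float = 28.0,
    period: float = 4.0,
    hysteresis: float = 0.0,
    n_cycles: int = 20,
    seed: int | None = None,
    dt: float = DEFAULT_DT_S,
) -> BreathingWaveform:
    """Synthesize a breathing trace.

    ``sinusoidal``: z = (A/2) cos(2 pi t / T), the usual clinical surrogate.
    ``typical``: z = A (cos^4(pi t / T) - 1/2) - a regular patient-like
    pattern whose flat valley reproduces the end-exhale dwell (patients
    spend much longer at end-exhale than end-inhale).
    ``irregular``: sinusoidal cycles with lognormal per-cycle jitter of
    period and amplitude (seeded).
    Hysteresis traces a loop of width ``hysteresis`` mm on a secondary
    in-plane axis, 90 degrees out of phase with z.
    """
    if peak_to_peak < 0 or period <= 0:
        raise ValueError("peak_to_peak must be >= 0 and period > 0")
    amp = peak_to_peak
    if pattern == "sinusoidal":
        t = np.arange(0.0, n_cycles * period + dt / 2, dt)
        phase = 2 * np.pi * t / period
        z = (amp / 2.0) * np.cos(phase)
    elif pattern == "typical":
        t = np.arange(0.0, n_cycles * period + dt / 2, dt)
        phase = 2 * np.pi * t / period
        z = amp * (np.cos(np.pi * t / period) ** 4 - 0.5)
    elif pattern == "irregular":
        rng = np.random.default_rng(seed)
        t_parts, z_parts, ph_parts = [], [], []
        t0 = 0.0
        for _ in range(n_cycles):
            t_i = period * float(rng.lognormal(0.0, 0.15))
            a_i = amp * float(rng.lognormal(0.0, 0.15))
            tt = np.arange(0.0, t_i, dt)
            ph = 2 * np.pi * tt / t_i
            t_parts.append(t0 + tt)
            z_parts.append((a_i / 2.0) * np.cos(ph))
            ph_parts.append(ph)
            t0 += len(tt) * dt
        t = np.concatenate(t_parts)
        z = np.concatenate(z_parts)
        phase = np.concatenate(ph_parts)
        # resample onto a uniform grid (cycle stitching leaves tiny gaps)
        tu = np.arange(0.0, t[-1] + dt / 2, dt)
        z = np.interp(tu, t, z)
        phase = np.interp(tu, t, phase)
        t = tu
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    y = (hysteresis / 2.0) * np.sin(phase) if hysteresis > 0 else np.zeros_like(t)
    return BreathingWaveform(t=t, z=z, y_hyst=y, period=period, pattern_id=pattern)


def waveform_to_csv(w: BreathingWaveform, path: str) -> None:
    cols = np.column_stack([w.t, w.z, w.y_hyst])
    np.savetxt(path, cols, delimiter=",", header="time_s,z_mm,y_mm", comments="")


def waveform_from_csv(path: str, period: float, pattern_id: str = "csv") -> BreathingWaveform:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    y = data[:, 2] if data.shape[1] > 2 else np.zeros(len(data))
    return BreathingWaveform(t=data[:, 0], z=data[:, 1], y_hyst=y, period=period, pattern_id=pattern_id)


# ---------------------------------------------------------------------------
# Cycle detection and gating
# ---------------------------------------------------------------------------

def detect_cycles(w: BreathingWaveform) -> list[tuple[float, float]]:
    """Breathing cycles as (max_time, next_max_time) between consecutive
    interior local maxima (prominence > 10% of the trace amplitude)."""
    amp = w.amplitude
    if amp <= 0:
        raise ValueError("flat waveform: no cycles detectable")
    peaks, _ = find_peaks(w.z, prominence=0.1 * amp)
    if len(peaks) < 2:
        raise ValueError("need at least 2 maxima to define a cycle")
    times = w.t[peaks]
    return [(float(times[i]), float(times[i + 1])) for i in range(len(times) - 1)]


def accept_cycles(
    cycles: list[tuple[float, float]], tolerance: float
) -> list[tuple[float, float]]:
    """Drop irregular cycles: those whose duration deviates from the mean
    duration by more than ``tolerance`` (relative)."""
    if not cycles:
        raise ValueError("need at least one cycle")
    durations = np.array([c1 - c0 for c0, c1 in cycles])
    mean = durations.mean()
    keep = np.abs(durations - mean) / mean <= tolerance
    return [c for c, k in zip(cycles, keep) if k]


def prospective_windows(
    w: BreathingWaveform, p: GatingProtocol, cycles: list[tuple[float, float]] | None = None
) -> list[tuple[float, float, float]]:
    """(trigger_time, window_start, window_end) per accepted cycle.

    The trigger is the cycle's end-inhale maximum or end-exhale minimum;
    the window runs [trigger + delay, trigger + delay + fraction * T_cycle],
    truncated (with a warning) at the cycle end.
    """
    if p.kind not in ("prospective_inhale", "prospective_exhale"):
        raise ValueError("windows are defined for prospective protocols only")
    if cycles is None:
        cycles = detect_cycles(w)
        if p.reject_irregular:
            cycles = accept_cycles(cycles, p.irregular_tolerance)
    out = []
    for t0, t1 in cycles:
        if p.kind == "prospective_inhale":
            trigger = t0
        else:
            sel = (w.t >= t0) & (w.t < t1)
            trigger = float(w.t[sel][np.argmin(w.z[sel])])
        start = trigger + p.trigger_delay
        end = start + p.window_fraction * (t1 - t0)
        if end > t1:
            warnings.warn(
                f"gating window truncated at cycle end ({end - t1:.3f} s beyond)",
                stacklevel=2,
            )
            end = t1
        if start < t1:
            out.append((trigger, start, end))
    if not out:
        raise ValueError("no accepted gating windows")
    return out


def gate(
    w: BreathingWaveform, p: GatingProtocol, bin_mm: float = DEFAULT_BIN_MM
) -> list[DisplacementKernel]:
    """Reduce a waveform to displacement kernels: one for a prospective
    protocol, ``n_phases`` for a retrospective one.

    Duty cycles are measured against the total time spanned by the detected
    cycles, so retrospective phase duties partition to 1 when no cycle is
    rejected.  A zero-amplitude (static) waveform yields delta kernels at 0.
    """
    if w.amplitude <= 1e-12:
        if p.kind == "retrospective":
            return [
                DisplacementKernel.delta(0.0, duty_cycle=1.0 / p.n_phases)
                for _ in range(p.n_phases)
            ]
        return [DisplacementKernel.delta(0.0, duty_cycle=p.window_fraction)]

    all_cycles = detect_cycles(w)
    cycles = (
        accept_cycles(all_cycles, p.irregular_tolerance)
        if p.reject_irregular
        else all_cycles
    )
    if not cycles:
        raise ValueError("all cycles rejected as irregular")
    span = (w.t >= all_cycles[0][0]) & (w.t < all_cycles[-1][1])
    n_total = int(span.sum())

    def kernel_from(mask: np.ndarray) -> DisplacementKernel:
        zsel = w.z[mask]
        if len(zsel) == 0:
            raise ValueError("empty gating window: no samples accepted")
        # bin edges at half-multiples so centers land on multiples of bin_mm
        lo = (np.floor(zsel.min() / bin_mm + 0.5) - 0.5) * bin_mm
        hi = (np.ceil(zsel.max() / bin_mm - 0.5) + 0.5) * bin_mm
        edges = np.arange(lo, hi + bin_mm / 2, bin_mm)
        hist, _ = np.histogram(zsel, bins=edges)
        centers = (edges[:-1] + edges[1:]) / 2.0
        keep = hist > 0
        weights = hist[keep] / hist.sum()
        weights = weights / weights.sum()
        return DisplacementKernel(centers[keep], weights, len(zsel) / n_total)

    if p.kind in ("prospective_inhale", "prospective_exhale"):
        windows = prospective_windows(w, p, cycles)
        mask = np.zeros(len(w.t), dtype=bool)
        for _, start, end in windows:
            mask |= (w.t >= start) & (w.t <= end)
        return [kernel_from(mask)]

    kernels = []
    for k in range(p.n_phases):
        mask = np.zeros(len(w.t), dtype=bool)
        for t0, t1 in cycles:
            tc = t1 - t0
            s = t0 + k * tc / p.n_phases
            e = t0 + (k + 1) * tc / p.n_phases
            mask |= (w.t >= s) & (w.t < e)
        kernels.append(kernel_from(mask))
    return kernels
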