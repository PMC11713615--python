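"""Binarization of activity data and information-optimal time-bin selection.

Fluorescence traces are turned into spike events with a Schmitt trigger
(hysteresis detector with separate on/off thresholds), events are binned into
a ±1 raster, and the bin width τ is chosen to maximise the total delayed
pairwise mutual information

    objective(τ) = (T_rec/τ − 1) · Σ_{i≠j} I_τ(s_i, s_j),

where I_τ(s_i, s_j) is the plug-in mutual information (bits) between the
activity of i in bin t and of j in bin t−1, and T_rec is the recording
duration in seconds. The maximiser τ* is interpretable as the effective
synaptic reaction time of the culture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SpikeRaster

__all__ = [
    "FluorescenceTraces",
    "SpikeEvents",
    "schmitt_binarize",
    "detect_events",
    "detrend_traces",
    "bin_spikes",
    "delayed_mutual_information",
    "total_delayed_information",
    "optimal_time_bin",
    "default_tau_grid",
]


@dataclass
class FluorescenceTraces:
    """Real-valued traces, ``values[t, u]`` for frame t and unit u."""

    values: np.ndarray
    frame_rate: float
    unit_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("traces must be 2-D with >= 2 frames")
        if not np.isfinite(self.values).all():
            raise ValueError("traces must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not self.unit_ids:
            self.unit_ids = [f"u{i}" for i in range(self.values.shape[1])]


@dataclass
class SpikeEvents:
    """Per-unit sorted spike/activation times in seconds, within a recording
    of duration ``duration`` seconds."""

    times: list[np.ndarray]
    duration: float
    unit_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        for t in self.times:
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError("event outside [0, duration]")
            if np.any(np.diff(t) < 0):
                raise ValueError("event times must be sorted")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not self.unit_ids:
            self.unit_ids = [f"u{i}" for i in range(len(self.times))]

    @property
    def n_units(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def schmitt_binarize(trace: np.ndarray, high: float, low: float) -> np.ndarray:
    """Hysteresis (Schmitt-trigger) event detector.

    The unit turns "active" (1) at the first sample ≥ ``high`` and stays
    active until the first subsequent sample ≤ ``low``; between the two
    thresholds the previous state persists, which suppresses re-triggering
    on noise. Returns a 0/1 array of the trace's length.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.isfinite(trace).all():
        raise ValueError("trace must be finite")
    if low >= high:
        raise ValueError("low threshold must be strictly below high")
    out = np.zeros(trace.shape[0], dtype=np.int8)
    active = False
    for t, x in enumerate(trace):
        if not active and x >= high:
            active = True
        elif active and x <= low:
            active = False
        out[t] = active
    return out


def detrend_traces(values: np.ndarray, window: int = 201, percentile: float = 10.0) -> np.ndarray:
    """Subtract a sliding-percentile baseline from each column (slow drift
    removal). ``window`` is in frames and is clipped to the trace length."""
    values = np.asarray(values, dtype=float)
    T = values.shape[0]
    w = int(min(window, T))
    half = w // 2
    out = np.empty_like(values)
    for u in range(values.shape[1]):
        col = values[:, u]
        base = np.empty(T)
        for t in range(T):
            lo, hi = max(0, t - half), min(T, t + half + 1)
            base[t] = np.percentile(col[lo:hi], percentile)
        out[:, u] = col - base
    return out


def detect_events(
    traces: FluorescenceTraces,
    high_sd: float = 3.0,
    low_sd: float = 1.0,
    detrend: bool = False,
) -> SpikeEvents:
    """Schmitt-trigger events from traces; per-trace thresholds
    mean + ``high_sd``·SD (on) and mean + ``low_sd``·SD (off). Each active
    run contributes one event at its onset time."""
    if low_sd >= high_sd:
        raise ValueError("low_sd must be below high_sd")
    values = detrend_traces(traces.values) if detrend else traces.values
    times: list[np.ndarray] = []
    dt = 1.0 / traces.frame_rate
    for u in range(values.shape[1]):
        col = values[:, u]
        mu, sd = col.mean(), col.std()
        if sd == 0:
            times.append(np.empty(0))
            continue
        act = schmitt_binarize(col, mu + high_sd * sd, mu + low_sd * sd)
        onsets = np.flatnonzero(np.diff(np.concatenate(([0], act))) == 1)
        times.append(onsets * dt)
    return SpikeEvents(times=times, duration=values.shape[0] * dt,
                       unit_ids=list(traces.unit_ids))


# ---------------------------------------------------------------------------
# binning and mutual information
# ---------------------------------------------------------------------------

def bin_spikes(events: SpikeEvents, tau: float) -> SpikeRaster:
    """Bin events into a ±1 raster with half-open bins [t·τ, (t+1)·τ).

    A bin is +1 iff it contains at least one event (saturating), −1 otherwise;
    the number of bins is ``ceil(duration/τ)``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    T = int(np.ceil(events.duration / tau))
    T = max(T, 1)
    states = -np.ones((events.n_units, T), dtype=np.int8)
    for u, t in enumerate(events.times):
        if t.size:
            idx = np.minimum((t / tau).astype(int), T - 1)
            states[u, idx] = 1
    return SpikeRaster(states=states, tau=tau, unit_ids=list(events.unit_ids))


def _joint_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """2x2 table of (x, y) ∈ {+1,−1}² counts, rows x=+1,−1 / cols y=+1,−1."""
    xp, yp = x > 0, y > 0
    npp = int(np.sum(xp & yp))
    npm = int(np.sum(xp & ~yp))
    nmp = int(np.sum(~xp & yp))
    nmm = int(np.sum(~xp & ~yp))
    return np.array([[npp, npm], [nmp, nmm]], dtype=float)


def _mi_from_counts(n: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a 2x2 contingency table."""
    tot = n.sum()
    if tot == 0:
        return 0.0
    p = n / tot
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def delayed_mutual_information(raster: SpikeRaster, i: int, j: int) -> float:
    """Plug-in mutual information I(s_i^t ; s_j^{t−1}) in bits (t ≥ 2)."""
    if i == j:
        raise ValueError("delayed MI is defined for distinct units (i != j)")
    if raster.n_bins < 2:
        raise ValueError("need at least 2 bins")
    x = raster.states[i, 1:]
    y = raster.states[j, :-1]
    return _mi_from_counts(_joint_counts(x, y))


def _total_mi(states: np.ndarray) -> float:
    """Σ_{i≠j} I(s_i^t ; s_j^{t−1}) in bits, via matrix joint counts."""
    A = (states[:, 1:] > 0).astype(np.float64)   # target at t
    B = (states[:, :-1] > 0).astype(np.float64)  # source at t-1
    Tm1 = A.shape[1]
    npp = A @ B.T
    na = A.sum(axis=1)[:, None]          # x=+1 count per target
    nb = B.sum(axis=1)[None, :]          # y=+1 count per source
    npm = na - npp
    nmp = nb - npp
    nmm = Tm1 - na - nb + npp
    total = 0.0
    # pairwise MI from the four count matrices, 0 log 0 := 0
    p = np.stack([npp, npm, nmp, nmm]) / Tm1
    px = np.stack([na, na, Tm1 - na, Tm1 - na]) / Tm1
    py = np.stack([nb, Tm1 - nb, nb, Tm1 - nb]) / Tm1
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    mi = np.nansum(terms, axis=0)
    np.fill_diagonal(mi, 0.0)
    total = float(mi.sum())
    return total


def total_delayed_information(raster: SpikeRaster, duration: float) -> float:
    """The bin-selection objective (T_rec/τ − 1) · Σ_{i≠j} I_τ(s_i, s_j)."""
    n_trans = duration / raster.tau - 1.0
    return max(n_trans, 0.0) * _total_mi(raster.states)


def default_tau_grid(frame_rate: float = 33.0, tau_max: float = 2.0, n: int = 20) -> np.ndarray:
    """Geometric τ grid from one frame to ``tau_max`` seconds in ``n`` steps."""
    return np.geomspace(1.0 / frame_rate, tau_max, n)


def optimal_time_bin(
    events: SpikeEvents, tau_grid: np.ndarray
) -> tuple[float, np.ndarray, bool]:
    """Pick the bin width maximising the total delayed-information objective.

    Returns ``(tau_star, objective_per_tau, degenerate)``; ties and the
    all-silent degenerate case resolve toward the smallest τ (finest temporal
    resolution), with ``degenerate=True`` flagging an all-zero objective.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("tau_grid must be non-empty")
    if np.any(tau_grid <= 0) or np.any(tau_grid >= events.duration):
        raise ValueError("all tau must satisfy 0 < tau < duration")
    order = np.argsort(tau_grid)
    obj = np.empty(tau_grid.size)
    for k in range(tau_grid.size):
        raster = bin_spikes(events, tau_grid[k])
        obj[k] = total_delayed_information(raster, events.duration)
    degenerate = bool(np.all(obj <= 0))
    if degenerate:
        tau_star = float(tau_grid[order[0]])
    else:
        # argmax with ties broken toward the smallest tau
        best = order[int(np.argmax(obj[order]))]
        tau_star = float(tau_grid[best])
    return tau_star, obj, degenerate


def fluorescence_from_spikes(
    events: SpikeEvents,
    frame_rate: float = 33.0,
    decay_s: float = 0.8,
    amplitude: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> FluorescenceTraces:
    """Cosmetic calcium-like traces: exponential-kernel convolution of the
    spike trains plus white noise. For display only; inference consumes
    rasters, not rendered traces."""
    T = int(np.ceil(events.duration * frame_rate))
    rng = np.random.default_rng(seed)
    vals = rng.normal(0.0, noise_sd, size=(T, events.n_units))
    decay = np.exp(-1.0 / (frame_rate * decay_s))
    for u, times in enumerate(events.times):
        tr = np.zeros(T)
        idx = np.minimum((times * frame_rate).astype(int), T - 1)
        np.add.at(tr, idx, amplitude)
        for t in range(1, T):
            tr[t] += tr[t - 1] * decay
        vals[:, u] += tr
    return FluorescenceTraces(values=vals, frame_rate=frame_rate,
                              unit_ids=list(events.unit_ids))
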