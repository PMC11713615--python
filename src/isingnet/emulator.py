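"""In silico neuronal-culture emulator.

Generates ground-truth networks and spontaneous spiking activity the way
developing cultures do: somata are scattered without overlap on a flat or
stripe-patterned substrate, axons grow as jittered random walks of line
segments and synapse onto somata they pass, and the resulting weighted
directed network is simulated with Izhikevich neurons augmented with
synaptic-resource dynamics,

    dP_i/dt = −P_i/τ_P + β R_i δ(v_i − v_th),
    dR_i/dt = (1 − R_i)/τ_R − γ_R R_i δ(v_i − v_th),

where P_i gates the postsynaptic drive Σ_j W_ij P_j onto target i and R_i is
the presynaptic neurotransmitter reserve (short-term depression terminates
network bursts). 20% of neurons are inhibitory: their outgoing weights are
negative with magnitudes drawn around Ω_I; excitatory magnitudes around Ω_E.

The Izhikevich constants, noise drive and synapse time constants are not
dictated by the inference method; the defaults here (regular-spiking /
fast-spiking parameter sets, white-noise drive producing sparse spontaneous
firing punctuated by network bursts) are this package's documented choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .binarize import SpikeEvents

__all__ = [
    "Substrate",
    "GrowthParams",
    "IzhikevichParams",
    "EmulatorGroundTruth",
    "place_neurons",
    "grow_connectivity",
    "simulate_izhikevich",
    "make_dataset",
    "patterned_substrate",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class Substrate:
    """Culture geometry. ``stripes`` substrates hold neurons on parallel
    bands; axons crossing between bands connect with a per-boundary penalty."""

    kind: str = "flat"
    width: float = 1800.0        # µm, x extent
    height: float = 150.0        # µm, y extent
    n_stripes: int = 4
    stripe_width: float = 300.0  # µm
    stripe_gap: float = 200.0    # µm
    crossing_penalty: float = 0.1
    wall_crossing: float = 0.5   # P(axon climbs a stripe-edge wall)

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "stripes"):
            raise ValueError("kind must be 'flat' or 'stripes'")
        if self.kind == "stripes" and (self.stripe_width <= 0 or self.stripe_gap < 0):
            raise ValueError("stripe dimensions must be positive")
        if not 0.0 <= self.crossing_penalty <= 1.0:
            raise ValueError("crossing_penalty must be in [0, 1]")

    def wall_positions(self) -> np.ndarray:
        """x coordinates of the stripe-edge walls (empty for flat)."""
        if self.kind == "flat":
            return np.empty(0)
        period = self.stripe_width + self.stripe_gap
        edges = []
        for k in range(self.n_stripes):
            edges.append(k * period)
            edges.append(k * period + self.stripe_width)
        return np.asarray(edges[1:-1])  # outer culture walls handled separately

    def extent(self) -> tuple[float, float]:
        if self.kind == "flat":
            return self.width, self.height
        period = self.stripe_width + self.stripe_gap
        return (self.n_stripes - 1) * period + self.stripe_width, self.height

    def stripe_of(self, x: np.ndarray) -> np.ndarray:
        """Stripe index from the x coordinate (flat substrate ⇒ all zeros)."""
        if self.kind == "flat":
            return np.zeros(np.shape(x), dtype=int)
        period = self.stripe_width + self.stripe_gap
        return np.minimum((np.asarray(x) // period).astype(int), self.n_stripes - 1)


def patterned_substrate() -> Substrate:
    """Four 300 µm stripes separated by 200 µm gaps (PDMS-track layout)."""
    return Substrate(kind="stripes")


@dataclass
class GrowthParams:
    """Axon-growth and synaptic-weight parameters.

    Axons are chains of ``n_segments`` segments of ``segment_length`` µm,
    each rotated by σφ·N(0,1) from its predecessor; a segment passing within
    ``r_soma`` of another soma creates a connection with probability ``alpha``
    (times the substrate crossing penalty per stripe boundary). Weight
    magnitudes are Normal(Ω_type, weight_variance) truncated positive; the
    strong-coupling regime uses (Ω_E, Ω_I) = (6, 12)."""

    n_neurons: int = 156
    inhibitory_fraction: float = 0.2
    r_soma: float = 7.5          # µm
    segment_length: float = 10.0  # µm
    sigma_phi: float = 0.15      # rad
    alpha: float = 0.33
    n_segments: int = 400
    Omega_E: float = 6.0
    Omega_I: float = 12.0
    weight_variance: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.inhibitory_fraction <= 1.0:
            raise ValueError("inhibitory_fraction must be in [0, 1]")
        for name in ("r_soma", "segment_length", "weight_variance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_segments < 0 or self.sigma_phi < 0:
            raise ValueError("n_segments and sigma_phi must be non-negative")


@dataclass
class IzhikevichParams:
    """Per-type Izhikevich constants (excitatory = regular spiking,
    inhibitory = fast spiking), integration step, synapse dynamics and the
    white-noise drive that elicits spontaneous activity."""

    a_exc: float = 0.02
    b_exc: float = 0.2
    c_exc: float = -65.0
    d_exc: float = 8.0
    a_inh: float = 0.1
    b_inh: float = 0.2
    c_inh: float = -65.0
    d_inh: float = 2.0
    v_th: float = 30.0           # mV
    dt: float = 0.5              # ms
    tau_P: float = 30.0          # ms, postsynaptic decay
    tau_R: float = 3000.0        # ms, reserve recovery
    beta: float = 1.0            # release increment
    gamma_R: float = 0.5         # reserve fraction depleted per spike
    noise_exc: float = 3.0       # mV/√ms drive amplitude
    noise_inh: float = 1.2
    I_bias: float = 0.0          # constant external current (all neurons)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > 0.5:
            raise ValueError("dt must be in (0, 0.5] ms to resolve spikes")
        if self.tau_P <= 0 or self.tau_R <= 0:
            raise ValueError("synaptic time constants must be positive")


@dataclass
class EmulatorGroundTruth:
    positions: np.ndarray        # (N, 2) µm
    stripe_id: np.ndarray        # (N,)
    W: np.ndarray                # (N, N), W[i, j] = weight j -> i
    types: np.ndarray            # (N,) ±1
    spike_times: list[np.ndarray] = field(default_factory=list)
    mean_out_degree: float = 0.0


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def place_neurons(params: GrowthParams, substrate: Substrate,
                  seed: int | np.random.Generator,
                  max_attempts: int = 200_000) -> tuple[np.ndarray, np.ndarray]:
    """Uniform rejection sampling of non-overlapping somata (pairwise centre
    distance ≥ 2·r_soma); on striped substrates only the stripes are
    populated. Returns (positions, stripe_id)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_neurons
    pos = np.empty((n, 2))
    placed = 0
    attempts = 0
    period = substrate.stripe_width + substrate.stripe_gap
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping somata "
                f"(placed {placed} after {attempts} attempts); lower the density")
        attempts += 1
        if substrate.kind == "stripes":
            s = rng.integers(substrate.n_stripes)
            x = s * period + rng.uniform(0.0, substrate.stripe_width)
        else:
            x = rng.uniform(0.0, substrate.width)
        y = rng.uniform(0.0, substrate.height)
        p = np.array([x, y])
        if placed and np.min(np.linalg.norm(pos[:placed] - p, axis=1)) < 2 * params.r_soma:
            continue
        pos[placed] = p
        placed += 1
    return pos, substrate.stripe_of(pos[:, 0])


def _segment_point_dist(p0: np.ndarray, p1: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Distance from points ``q`` (N, 2) to the segment p0–p1."""
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0.0:
        return np.linalg.norm(q - p0, axis=1)
    t = np.clip((q - p0) @ d / L2, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(q - proj, axis=1)


def grow_connectivity(positions: np.ndarray, stripe_id: np.ndarray,
                      substrate: Substrate, growth: GrowthParams,
                      seed: int | np.random.Generator,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Grow one axon per neuron and form the weighted directed network.

    Each axon is a segment-chain random walk; every segment of source j that
    passes within r_soma of soma i gives an independent Bernoulli
    (α·penalty^md) chance of forming the synapse (md = stripe boundaries
    between i and j); once a pair is connected, later encounters do not
    create duplicate links. Weight signs follow the source type (inhibitory
    columns negative); magnitudes are sign-truncated
    Normal(Ω_type, weight_variance). Returns (W, types)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = positions.shape[0]
    types = np.where(rng.random(n) < growth.inhibitory_fraction, -1, 1)
    W = np.zeros((n, n))
    sd = float(np.sqrt(growth.weight_variance))
    walls = substrate.wall_positions()
    xmax, ymax = substrate.extent()
    for j in range(n):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        p = positions[j].copy()
        done = np.zeros(n, dtype=bool)
        done[j] = True  # no self-synapse
        for _ in range(growth.n_segments):
            phi += growth.sigma_phi * rng.normal()
            p_new = p + growth.segment_length * np.array([np.cos(phi), np.sin(phi)])
            # culture edges always reflect the growth cone
            if p_new[1] < 0.0 or p_new[1] > ymax:
                phi = -phi
                p_new[1] = -p_new[1] if p_new[1] < 0.0 else 2.0 * ymax - p_new[1]
            if p_new[0] < 0.0 or p_new[0] > xmax:
                phi = np.pi - phi
                p_new[0] = -p_new[0] if p_new[0] < 0.0 else 2.0 * xmax - p_new[0]
            # stripe-edge walls deflect unless the axon climbs over
            if walls.size:
                crossed = walls[(walls > min(p[0], p_new[0]))
                                & (walls < max(p[0], p_new[0]))]
                if crossed.size and rng.random() >= substrate.wall_crossing:
                    b = crossed[np.argmin(np.abs(crossed - p[0]))]
                    phi = np.pi - phi
                    p_new[0] = 2.0 * b - p_new[0]
            dist = _segment_point_dist(p, p_new, positions)
            hits = np.flatnonzero((dist <= growth.r_soma) & ~done)
            for i in hits:
                prob = growth.alpha
                if substrate.kind == "stripes":
                    md = abs(int(stripe_id[i]) - int(stripe_id[j]))
                    prob *= substrate.crossing_penalty ** md
                if rng.random() < prob:
                    done[i] = True
                    omega = growth.Omega_E if types[j] > 0 else growth.Omega_I
                    mag = omega + sd * rng.normal()
                    while mag <= 0:
                        mag = omega + sd * rng.normal()
                    W[i, j] = types[j] * mag
            p = p_new
    return W, types


# ---------------------------------------------------------------------------
# spiking dynamics
# ---------------------------------------------------------------------------

@njit(cache=True)
def _izh_loop(W, a, b, c, d, noise_amp, I_bias, v_th, dt, tau_P, tau_R, beta,
              gamma_R, n_steps, seed):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    N = W.shape[0]
    v = np.full(N, -65.0)
    u = b * v
    P = np.zeros(N)
    R = np.ones(N)
    spikes_unit = []
    spikes_time = []
    sq = noise_amp / np.sqrt(dt)
    for step in range(n_steps):
        I = W @ P
        for i in range(N):
            I[i] += I_bias + sq[i] * np.random.normal()
        for i in range(N):
            v[i] += dt * (0.04 * v[i] * v[i] + 5.0 * v[i] + 140.0 - u[i] + I[i])
            u[i] += dt * a[i] * (b[i] * v[i] - u[i])
            P[i] += dt * (-P[i] / tau_P)
            R[i] += dt * ((1.0 - R[i]) / tau_R)
            if R[i] > 1.0:
                R[i] = 1.0
            if v[i] >= v_th:
                v[i] = c[i]
                u[i] += d[i]
                P[i] += beta * R[i]
                R[i] -= gamma_R * R[i]
                spikes_unit.append(i)
                spikes_time.append((step + 1) * dt)
        if not np.isfinite(v).all():
            raise FloatingPointError("non-finite membrane potential during integration")
    return spikes_unit, spikes_time


def simulate_izhikevich(W: np.ndarray, types: np.ndarray,
                        izh: IzhikevichParams, duration: float,
                        seed: int) -> list[np.ndarray]:
    """Euler-integrate the Izhikevich network with synapse dynamics for
    ``duration`` seconds; returns per-neuron sorted spike times (s).
    δ-function synaptic jumps are applied as discrete increments at the
    integration step of each spike."""
    W = np.ascontiguousarray(W, dtype=np.float64)
    n = W.shape[0]
    exc = np.asarray(types) > 0
    a = np.where(exc, izh.a_exc, izh.a_inh).astype(np.float64)
    b = np.where(exc, izh.b_exc, izh.b_inh).astype(np.float64)
    c = np.where(exc, izh.c_exc, izh.c_inh).astype(np.float64)
    d = np.where(exc, izh.d_exc, izh.d_inh).astype(np.float64)
    noise = np.where(exc, izh.noise_exc, izh.noise_inh).astype(np.float64)
    n_steps = int(round(duration * 1000.0 / izh.dt))
    units, times = _izh_loop(W, a, b, c, d, noise, izh.I_bias, izh.v_th,
                             izh.dt, izh.tau_P, izh.tau_R, izh.beta,
                             izh.gamma_R, n_steps, int(seed) % (2 ** 31))
    units = np.asarray(units, dtype=int) if len(units) else np.empty(0, dtype=int)
    times = np.asarray(times) / 1000.0
    out = []
    for i in range(n):
        ti = np.sort(times[units == i]) if times.size else np.empty(0)
        out.append(np.minimum(ti, duration))
    return out


def synapse_state_trace(W: np.ndarray, types: np.ndarray, izh: IzhikevichParams,
                        duration: float, seed: int,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Pure-python integration that records the (P, R) trajectories; used to
    check the synaptic state invariants (R ∈ [0, 1], P ≥ 0) and closed-form
    decay on small instances."""
    rng = np.random.default_rng(seed)
    n = W.shape[0]
    exc = np.asarray(types) > 0
    a = np.where(exc, izh.a_exc, izh.a_inh)
    b = np.where(exc, izh.b_exc, izh.b_inh)
    c = np.where(exc, izh.c_exc, izh.c_inh)
    d = np.where(exc, izh.d_exc, izh.d_inh)
    noise = np.where(exc, izh.noise_exc, izh.noise_inh) / np.sqrt(izh.dt)
    n_steps = int(round(duration * 1000.0 / izh.dt))
    v = np.full(n, -65.0)
    u = b * v
    P = np.zeros(n)
    R = np.ones(n)
    P_hist = np.empty((n_steps, n))
    R_hist = np.empty((n_steps, n))
    for step in range(n_steps):
        I = W @ P + izh.I_bias + noise * rng.normal(size=n)
        v += izh.dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
        u += izh.dt * a * (b * v - u)
        P *= 1.0 - izh.dt / izh.tau_P
        R = np.minimum(R + izh.dt * (1.0 - R) / izh.tau_R, 1.0)
        fired = v >= izh.v_th
        v[fired] = c[fired]
        u[fired] += d[fired]
        P[fired] += izh.beta * R[fired]
        R[fired] -= izh.gamma_R * R[fired]
        P_hist[step] = P
        R_hist[step] = R
    return P_hist, R_hist


# ---------------------------------------------------------------------------
# end-to-end generation
# ---------------------------------------------------------------------------

def make_dataset(growth: GrowthParams | None = None,
                 substrate: Substrate | None = None,
                 izh: IzhikevichParams | None = None,
                 duration: float = 600.0,
                 seed: int = 0) -> tuple[EmulatorGroundTruth, SpikeEvents]:
    """Generate a full ground-truth culture and its spontaneous activity.

    Deterministic per seed: placement, growth and dynamics each consume an
    independent stream spawned from ``seed``.
    """
    growth = growth or GrowthParams()
    substrate = substrate or patterned_substrate()
    izh = izh or IzhikevichParams()
    ss = np.random.SeedSequence(seed)
    s_place, s_grow, s_dyn = ss.spawn(3)
    pos, stripe = place_neurons(growth, substrate, np.random.default_rng(s_place))
    W, types = grow_connectivity(pos, stripe, substrate, growth,
                                 np.random.default_rng(s_grow))
    dyn_seed = int(s_dyn.generate_state(1)[0] % (2 ** 31))
    spikes = simulate_izhikevich(W, types, izh, duration, dyn_seed)
    truth = EmulatorGroundTruth(
        positions=pos, stripe_id=stripe, W=W, types=types, spike_times=spikes,
        mean_out_degree=float((W != 0).sum() / growth.n_neurons))
    events = SpikeEvents(times=[np.asarray(t) for t in spikes], duration=duration,
                         unit_ids=[f"n{i}" for i in range(growth.n_neurons)])
    return truth, events
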