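"""Kinetic Ising model: likelihood, gradients, simulation, covariances.

The model describes N binary units s_i = ±1 (spiking / silent) evolving in
discrete time. Given the state vector ``s^{t-1}`` of the whole network at the
previous time bin, unit i flips to state ``s_i^t`` with probability

    P(s_i^t | s^{t-1}) = exp(h_i s_i^t) / (2 cosh h_i),
    h_i = H_i + sum_j J_ij s_j^{t-1},

where ``J_ij`` is the directed effective coupling from source j to target i
and ``H_i`` the intrinsic field (activeness) of i. Units update synchronously:
there is no same-bin interdependence, so the joint transition probability
factorises over targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeRaster",
    "EffectiveNetwork",
    "CovariancePair",
    "transition_probability",
    "log_likelihood",
    "likelihood_gradients",
    "simulate",
    "covariances",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SpikeRaster:
    """Binary activity raster: ``states[i, t]`` ∈ {−1, +1}, bin width ``tau`` s.

    Rows are units, columns are time bins; +1 marks a bin containing at least
    one spike, −1 a silent bin.
    """

    states: np.ndarray
    tau: float
    unit_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2:
            raise ValueError("raster must be 2-D (units x bins)")
        if self.states.shape[1] < 2:
            raise ValueError("raster needs at least 2 bins")
        if not np.isin(self.states, (-1, 1)).all():
            raise ValueError("raster entries must be -1 or +1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not self.unit_ids:
            self.unit_ids = [f"u{i}" for i in range(self.states.shape[0])]
        if len(self.unit_ids) != self.states.shape[0]:
            raise ValueError("unit_ids length mismatch")

    @property
    def n_units(self) -> int:
        return self.states.shape[0]

    @property
    def n_bins(self) -> int:
        return self.states.shape[1]


@dataclass
class EffectiveNetwork:
    """Inferred effective structure: couplings ``J`` (j→i in ``J[i, j]``) and
    local fields ``H``. Dimensionless, tied to the bin width of the raster
    they were fitted on."""

    J: np.ndarray
    H: np.ndarray
    unit_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValueError("J must be square")
        if self.H.shape != (self.J.shape[0],):
            raise ValueError("H length must match J")
        if not (np.isfinite(self.J).all() and np.isfinite(self.H).all()):
            raise ValueError("J and H must be finite")
        if not self.unit_ids:
            self.unit_ids = [f"u{i}" for i in range(self.J.shape[0])]

    @property
    def n_units(self) -> int:
        return self.J.shape[0]


@dataclass
class CovariancePair:
    """Uncentred second moments of a ±1 raster: equal-time ``C`` and
    one-step-delayed ``D`` (``D[i, j] = <s_i^t s_j^{t-1}>``)."""

    C: np.ndarray
    D: np.ndarray


# ---------------------------------------------------------------------------
# probability model
# ---------------------------------------------------------------------------

def _log2cosh(x: np.ndarray) -> np.ndarray:
    # log(2 cosh x) = |x| + log1p(exp(-2|x|)), overflow-safe
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax))


def transition_probability(
    s_prev: np.ndarray, net: EffectiveNetwork, i: int, s_i: int
) -> float:
    """Probability that unit ``i`` takes state ``s_i`` given the previous
    network state ``s_prev``."""
    s_prev = np.asarray(s_prev, dtype=float)
    if s_prev.shape != (net.n_units,):
        raise ValueError("s_prev length must match the network")
    if s_i not in (-1, 1):
        raise ValueError("s_i must be -1 or +1")
    h = net.H[i] + net.J[i] @ s_prev
    if not np.isfinite(h):
        raise ValueError("non-finite field")
    return float(np.exp(s_i * h - _log2cosh(h)))


def _fields(states: np.ndarray, net: EffectiveNetwork) -> np.ndarray:
    """(T-1, N) matrix of fields h_i^t = H_i + sum_j J_ij s_j^{t-1}."""
    s_prev = states[:, :-1].T.astype(float)  # (T-1, N)
    return s_prev @ net.J.T + net.H


def log_likelihood(raster: SpikeRaster, net: EffectiveNetwork) -> float:
    """Total log-likelihood of all observed transitions, ``sum_{t>=2} sum_i
    ln P(s_i^t | s^{t-1})``. Always ≤ 0."""
    if raster.n_units != net.n_units:
        raise ValueError("raster/network size mismatch")
    if raster.n_bins < 2:
        raise ValueError("need at least 2 bins (one transition)")
    h = _fields(raster.states, net)
    s_next = raster.states[:, 1:].T.astype(float)
    return float(np.sum(s_next * h - _log2cosh(h)))


def likelihood_gradients(
    raster: SpikeRaster, net: EffectiveNetwork
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of :func:`log_likelihood` in (J, H).

    dH_i = sum_t [s_i^t − tanh h_i^t];  dJ_ij = sum_t s_j^{t-1} [s_i^t − tanh h_i^t].
    """
    if raster.n_bins < 2:
        raise ValueError("need at least 2 bins (one transition)")
    h = _fields(raster.states, net)
    s_prev = raster.states[:, :-1].T.astype(float)
    resid = raster.states[:, 1:].T.astype(float) - np.tanh(h)  # (T-1, N)
    dH = resid.sum(axis=0)
    dJ = resid.T @ s_prev
    return dJ, dH


def simulate(
    net: EffectiveNetwork,
    T: int,
    seed: int | np.random.Generator,
    s_init: np.ndarray | str = "silent",
    tau: float = 1.0,
    burn_in: int = 0,
) -> SpikeRaster:
    """Monte-Carlo simulate ``T`` bins of network activity.

    All units are updated synchronously from the previous state. ``s_init``
    may be a ±1 vector, ``"silent"`` (all −1, the default) or ``"random"``.
    The first ``burn_in`` additional steps are simulated and discarded so the
    returned raster samples the stationary regime. Identical seed ⇒ identical
    raster.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = net.n_units
    if isinstance(s_init, str):
        if s_init == "silent":
            s = -np.ones(N)
        elif s_init == "random":
            s = rng.choice([-1.0, 1.0], size=N)
        else:
            raise ValueError(f"unknown s_init {s_init!r}")
    else:
        s = np.asarray(s_init, dtype=float)
        if s.shape != (N,) or not np.isin(s, (-1, 1)).all():
            raise ValueError("s_init must be a ±1 vector of length N")
    for _ in range(burn_in):
        h = net.H + net.J @ s
        p_plus = 1.0 / (1.0 + np.exp(-2.0 * h))
        s = np.where(rng.random(N) < p_plus, 1.0, -1.0)
    states = np.empty((N, T), dtype=np.int8)
    states[:, 0] = s
    for t in range(1, T):
        h = net.H + net.J @ s
        # P(s=+1) = e^h / 2cosh(h) = logistic(2h)
        p_plus = 1.0 / (1.0 + np.exp(-2.0 * h))
        s = np.where(rng.random(N) < p_plus, 1.0, -1.0)
        states[:, t] = s
    return SpikeRaster(states=states, tau=tau, unit_ids=list(net.unit_ids))


def covariances(raster: SpikeRaster) -> CovariancePair:
    """Equal-time and one-step-delayed second moments of the raster.

    ``C_ij = (1/T) sum_t s_i^t s_j^t`` (symmetric, unit diagonal) and
    ``D_ij = (1/(T-1)) sum_{t>=2} s_i^t s_j^{t-1}`` (generally asymmetric).
    """
    if raster.n_bins < 2:
        raise ValueError("need at least 2 bins")
    s = raster.states.astype(float)
    T = raster.n_bins
    C = (s @ s.T) / T
    D = (s[:, 1:] @ s[:, :-1].T) / (T - 1)
    return CovariancePair(C=C, D=D)
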