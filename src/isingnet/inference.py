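"""Priors and estimators for effective-network inference.

Three estimators of increasing sophistication operate on a ±1 raster:

* **MLE** — plain gradient-based maximisation of the kinetic Ising
  log-likelihood. No structural assumptions.
* **MAP** — maximises the evidence objective (log-likelihood plus structured
  log-priors) at fixed hyperparameters.
* **GML** (generalised maximum likelihood / evidence approximation) — a
  two-layer EM that alternates MAP-style optimisation of (J, H) with
  re-estimation of the hyperparameters themselves via an inner (micro) EM
  over the latent neuron types z_j and link indicators φ_ij.

The structural priors encode biology: each neuron is excitatory (z_j = +1,
all outgoing couplings positive) or inhibitory (z_j = −1, all negative) with
prior excitatory fraction γ; a link j→i exists with probability
θ_ij·exp(−a·l_ij), decaying with inter-soma distance l_ij; an existing
coupling has log-normal magnitude (separate location/scale per type) while an
absent one is pinned near zero by a narrow Gaussian "spike" of variance ε.
Fields H_i are Gaussian (μ_H, v_H).

Self-couplings J_jj model refractoriness, not anatomy: they carry a flat
prior, are excluded from the type-posterior product and from the coupling
hyperparameter updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .model import EffectiveNetwork, SpikeRaster, log_likelihood

__all__ = [
    "Hyperparameters",
    "NetworkGeometry",
    "LatentPosteriors",
    "InferenceResult",
    "OptimizerConfig",
    "log_prior_H",
    "coupling_log_density",
    "link_prior",
    "evidence_objective",
    "mle_fit",
    "map_fit",
    "gml_fit",
    "posterior_z",
    "posterior_phi",
    "posteriors_all",
    "update_hyperparameters",
    "micro_em_objective",
    "hyperparameters_from_mle",
    "classify",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_V_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Hyperparameters:
    """Prior hyperparameters ρ.

    gamma: prior excitatory fraction; a: distance-decay rate (1/µm);
    (mu_H, v_H): Gaussian field prior; (mu_Jp, v_Jp) / (mu_Jm, v_Jm):
    log-normal location/scale for excitatory / inhibitory coupling
    magnitudes; epsilon: variance of the near-zero "no link" Gaussian.
    """

    gamma: float = 0.8
    a: float = 0.1
    mu_H: float = 0.0
    v_H: float = 1.0
    mu_Jp: float = -1.5
    v_Jp: float = 0.5
    mu_Jm: float = -1.5
    v_Jm: float = 0.5
    epsilon: float = 1e-4

    def validate(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.a < 0:
            raise ValueError("a must be >= 0")
        for name in ("v_H", "v_Jp", "v_Jm", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in (
            "gamma", "a", "mu_H", "v_H", "mu_Jp", "v_Jp", "mu_Jm", "v_Jm", "epsilon")}


@dataclass
class NetworkGeometry:
    """Pairwise Euclidean distances ``l`` (µm) and prior link probabilities
    ``theta`` for the distance/substrate-aware link prior."""

    l: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.l.shape != self.theta.shape or self.l.ndim != 2:
            raise ValueError("l and theta must be matching square matrices")
        if not np.allclose(self.l, self.l.T) or np.any(self.l < 0):
            raise ValueError("l must be symmetric non-negative")
        if np.any((self.theta < 0) | (self.theta > 1)):
            raise ValueError("theta entries must be in [0, 1]")

    @classmethod
    def uniform(cls, n: int, theta: float = 1.0) -> "NetworkGeometry":
        """No positional information: zero distances, constant θ."""
        return cls(l=np.zeros((n, n)), theta=np.full((n, n), float(theta)))

    @classmethod
    def from_positions(
        cls,
        positions: np.ndarray,
        stripe_id: np.ndarray | None = None,
        theta_base: float = 0.5,
    ) -> "NetworkGeometry":
        """Distances from (x, y) coordinates; with a stripe layout,
        θ_ij = theta_base^md where md is the number of stripe boundaries
        between the stripes of i and j (same stripe ⇒ θ = 1)."""
        positions = np.asarray(positions, dtype=float)
        diff = positions[:, None, :] - positions[None, :, :]
        l = np.sqrt((diff ** 2).sum(axis=-1))
        n = positions.shape[0]
        if stripe_id is None:
            theta = np.ones((n, n))
        else:
            stripe_id = np.asarray(stripe_id)
            md = np.abs(stripe_id[:, None] - stripe_id[None, :]).astype(float)
            theta = float(theta_base) ** md
        return cls(l=l, theta=theta)


@dataclass
class LatentPosteriors:
    """Posterior beliefs: ``pz[j] = P(z_j = +1)`` and
    ``pphi[i, j] = P(φ_ij = 1)``. The per-type conditionals
    ``pphi_pos/pphi_neg`` (= P(φ_ij = 1 | z_j = ±1)) are kept for the
    hyperparameter M-step."""

    pz: np.ndarray
    pphi: np.ndarray
    pphi_pos: np.ndarray | None = None
    pphi_neg: np.ndarray | None = None


@dataclass
class OptimizerConfig:
    """L-BFGS settings for the (J, H) maximisations."""

    max_iter: int = 1000
    tol: float = 1e-5          # projected-gradient max-norm, per-transition scale
    H_max: float = 20.0
    # GML loop controls
    max_macro_iters: int = 10
    macro_tol: float = 1e-3
    max_micro_iters: int = 50
    micro_tol: float = 1e-5
    phi_threshold: float = 0.5
    update_H_prior: bool = True
    update_a: bool = True


@dataclass
class InferenceResult:
    net: EffectiveNetwork
    latents: LatentPosteriors
    rho: Hyperparameters
    z_hat: np.ndarray
    phi_hat: np.ndarray
    trace: list[float]
    converged: bool = True
    method: str = "gml"


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def log_prior_H(H: np.ndarray, rho: Hyperparameters) -> float:
    """Gaussian log-prior of the fields, summed over units."""
    rho.validate()
    H = np.asarray(H, dtype=float)
    return float(np.sum(-0.5 * _LOG2PI - 0.5 * np.log(rho.v_H)
                        - (H - rho.mu_H) ** 2 / (2.0 * rho.v_H)))


def coupling_log_density(Jij: float, phi: int, z: int, rho: Hyperparameters) -> float:
    """Log-density of a single coupling given link indicator and source type.

    φ=0: Gaussian spike N(0, ε). φ=1: log-normal on z·J (−inf when the sign
    of J contradicts z — an existing link must match its source's type).
    """
    rho.validate()
    if phi == 0:
        return float(-0.5 * (_LOG2PI + np.log(rho.epsilon)) - Jij ** 2 / (2.0 * rho.epsilon))
    x = z * Jij
    if x <= 0:
        return -np.inf
    mu, v = (rho.mu_Jp, rho.v_Jp) if z > 0 else (rho.mu_Jm, rho.v_Jm)
    lx = np.log(x)
    return float(-lx - 0.5 * (_LOG2PI + np.log(v)) - (lx - mu) ** 2 / (2.0 * v))


def link_prior(phi: int, i: int, j: int, geometry: NetworkGeometry,
               rho: Hyperparameters) -> float:
    """P(φ_ij = φ) = θ_ij e^{−a l_ij} for φ=1, complement for φ=0."""
    q = geometry.theta[i, j] * np.exp(-rho.a * geometry.l[i, j])
    return float(q if phi == 1 else 1.0 - q)


# -- vectorised building blocks ---------------------------------------------

def _link_prob_matrix(geometry: NetworkGeometry, rho: Hyperparameters) -> np.ndarray:
    return geometry.theta * np.exp(-rho.a * geometry.l)


def _log_spike(J: np.ndarray, rho: Hyperparameters) -> np.ndarray:
    return -0.5 * (_LOG2PI + np.log(rho.epsilon)) - J ** 2 / (2.0 * rho.epsilon)


def _log_lognormal(J: np.ndarray, z: int, rho: Hyperparameters) -> np.ndarray:
    """Elementwise log-normal log-density of z·J; −inf off-support."""
    mu, v = (rho.mu_Jp, rho.v_Jp) if z > 0 else (rho.mu_Jm, rho.v_Jm)
    x = z * J
    out = np.full(J.shape, -np.inf)
    ok = x > 0
    lx = np.log(x[ok])
    out[ok] = -lx - 0.5 * (_LOG2PI + np.log(v)) - (lx - mu) ** 2 / (2.0 * v)
    return out


def _log_mixture(J: np.ndarray, geometry: NetworkGeometry, rho: Hyperparameters,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-entry log of the two-component (spike vs slab) mixture, for each
    source type. Returns (lm_pos, lm_neg, l0, l1p, l1m, q) where
    l0 = ln[(1−q)·spike], l1z = ln[q·slab_z] and lm_z = logaddexp(l0, l1z)."""
    # q is kept strictly below 1 so the spike component never loses support
    # entirely (the delta function is itself approximated by N(0, eps))
    q = np.clip(_link_prob_matrix(geometry, rho), 0.0, 1.0 - 1e-9)
    with np.errstate(divide="ignore"):
        lq = np.log(q)
        l1mq = np.log1p(-q)
    lspike = _log_spike(J, rho)
    l0 = l1mq + lspike
    l1p = lq + _log_lognormal(J, +1, rho)
    l1m = lq + _log_lognormal(J, -1, rho)
    lm_pos = np.logaddexp(l0, l1p)
    lm_neg = np.logaddexp(l0, l1m)
    return lm_pos, lm_neg, l0, l1p, l1m, q


def _offdiag_mask(n: int) -> np.ndarray:
    m = np.ones((n, n), dtype=bool)
    np.fill_diagonal(m, False)
    return m


def log_prior_J(J: np.ndarray, geometry: NetworkGeometry, rho: Hyperparameters) -> float:
    """Column-marginal log-prior ln p(J|ρ): the type z_j is shared along each
    column, so per column ln Σ_z p(z) Π_{i≠j} [mixture density]. Diagonals
    carry a flat prior and contribute nothing."""
    rho.validate()
    n = J.shape[0]
    lm_pos, lm_neg, *_ = _log_mixture(J, geometry, rho)
    np.fill_diagonal(lm_pos, 0.0)
    np.fill_diagonal(lm_neg, 0.0)
    with np.errstate(divide="ignore"):
        lg, l1mg = np.log(rho.gamma), np.log1p(-min(rho.gamma, 1.0 - 1e-300))
    col_pos = lg + lm_pos.sum(axis=0)
    col_neg = l1mg + lm_neg.sum(axis=0)
    return float(np.sum(np.logaddexp(col_pos, col_neg)))


def _grad_log_prior_J(J: np.ndarray, geometry: NetworkGeometry,
                      rho: Hyperparameters) -> np.ndarray:
    """Gradient of :func:`log_prior_J` in J (zero on the diagonal)."""
    n = J.shape[0]
    lm_pos, lm_neg, l0, l1p, l1m, _ = _log_mixture(J, geometry, rho)
    np.fill_diagonal(lm_pos, 0.0)
    np.fill_diagonal(lm_neg, 0.0)
    with np.errstate(divide="ignore"):
        lg, l1mg = np.log(rho.gamma), np.log1p(-min(rho.gamma, 1.0 - 1e-300))
    col_pos = lg + lm_pos.sum(axis=0)
    col_neg = l1mg + lm_neg.sum(axis=0)
    norm = np.logaddexp(col_pos, col_neg)
    rz_pos = np.exp(col_pos - norm)          # P(z_j = +1 | J)
    grad = np.zeros_like(J)
    for z, lm, l1, rz in ((+1, lm_pos, l1p, rz_pos), (-1, lm_neg, l1m, 1.0 - rz_pos)):
        with np.errstate(invalid="ignore"):
            r1 = np.exp(l1 - lm)             # slab responsibility within type z
        r1 = np.nan_to_num(r1, nan=0.0)
        r0 = 1.0 - r1
        dspike = -J / rho.epsilon
        mu, v = (rho.mu_Jp, rho.v_Jp) if z > 0 else (rho.mu_Jm, rho.v_Jm)
        dslab = np.zeros_like(J)
        ok = (z * J) > 0
        lx = np.log(z * J[ok])
        dslab[ok] = (-1.0 / J[ok]) * (1.0 + (lx - mu) / v)
        grad += rz[None, :] * (r0 * dspike + r1 * dslab)
    np.fill_diagonal(grad, 0.0)
    return grad


def evidence_objective(raster: SpikeRaster, net: EffectiveNetwork,
                       rho: Hyperparameters, geometry: NetworkGeometry) -> float:
    """Log-likelihood plus field and coupling log-priors."""
    val = (log_likelihood(raster, net)
           + log_prior_H(net.H, rho)
           + log_prior_J(net.J, geometry, rho))
    if not np.isfinite(val):
        raise FloatingPointError("non-finite evidence objective")
    return float(val)


# ---------------------------------------------------------------------------
# estimators: MLE and MAP
# ---------------------------------------------------------------------------

def _optimize(raster: SpikeRaster, init: EffectiveNetwork,
              config: OptimizerConfig,
              rho: Hyperparameters | None = None,
              geometry: NetworkGeometry | None = None) -> tuple[EffectiveNetwork, bool]:
    """L-BFGS maximisation of the per-transition objective in (J, H); with
    ``rho``/``geometry`` supplied the priors are included (MAP objective).

    The raster matrices are precomputed once and the dense (T × N) algebra
    runs in single precision (the per-transition objective is far above the
    float32 noise floor at the tolerances used); priors stay in double."""
    N = raster.n_units
    scale = 1.0 / max(raster.n_bins - 1, 1)
    dtype = np.float32 if raster.n_bins * N > 500_000 else np.float64
    S_prev = np.ascontiguousarray(raster.states[:, :-1].T, dtype=dtype)
    S_next = np.ascontiguousarray(raster.states[:, 1:].T, dtype=dtype)
    col_next = S_next.sum(axis=0).astype(np.float64)
    cross = (S_next.T @ S_prev).astype(np.float64)  # constant part of dJ

    def negobj(x: np.ndarray) -> tuple[float, np.ndarray]:
        J = x[: N * N].reshape(N, N)
        H = x[N * N:]
        h = S_prev @ J.T.astype(dtype) + H.astype(dtype)
        ah = np.abs(h)
        val = float((S_next * h).sum() - (ah + np.log1p(np.exp(-2.0 * ah))).sum())
        th = np.tanh(h)
        dH = col_next - th.sum(axis=0).astype(np.float64)
        dJ = cross - (th.T @ S_prev).astype(np.float64)
        if rho is not None:
            val += log_prior_H(H, rho) + log_prior_J(J, geometry, rho)
            dH = dH + (rho.mu_H - H) / rho.v_H
            dJ = dJ + _grad_log_prior_J(J, geometry, rho)
        g = -np.concatenate([dJ.ravel(), dH]) * scale
        return -val * scale, g

    x0 = np.concatenate([init.J.ravel(), init.H])
    bounds = [(None, None)] * (N * N) + [(-config.H_max, config.H_max)] * N
    res = minimize(negobj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": config.max_iter, "gtol": config.tol,
                            "maxfun": 10 * config.max_iter})
    J = res.x[: N * N].reshape(N, N)
    H = res.x[N * N:]
    converged = bool(res.success)
    net = EffectiveNetwork(J=J, H=H, unit_ids=list(raster.unit_ids))
    if np.any(np.abs(H) >= config.H_max - 1e-9):
        warnings.warn("field estimate hit the ±H_max cap (always/never-firing unit?)")
    return net, converged


def mle_fit(raster: SpikeRaster, config: OptimizerConfig | None = None) -> EffectiveNetwork:
    """Maximum-likelihood network estimate (no priors).

    The returned network carries a ``converged`` attribute; non-convergence
    within the iteration budget flags it False rather than raising.
    """
    config = config or OptimizerConfig()
    N = raster.n_units
    init = EffectiveNetwork(J=np.zeros((N, N)), H=np.zeros(N),
                            unit_ids=list(raster.unit_ids))
    net, converged = _optimize(raster, init, config)
    if not converged:
        warnings.warn("MLE did not converge within the iteration budget")
    # separable likelihood: a unit that always (never) spikes has its MLE
    # field at +inf (-inf); clip to the cap instead of chasing a flat ridge
    col_mean = raster.states[:, 1:].mean(axis=1)
    saturated = np.abs(col_mean) == 1.0
    if saturated.any():
        warnings.warn("always/never-firing unit(s): field clipped at the ±H_max cap")
        net.H[saturated] = np.sign(col_mean[saturated]) * config.H_max
    net.converged = converged
    return net


def map_fit(raster: SpikeRaster, rho: Hyperparameters,
            geometry: NetworkGeometry,
            config: OptimizerConfig | None = None,
            init: EffectiveNetwork | str = "mle") -> InferenceResult:
    """Maximum a posteriori fit: evidence objective maximised in (J, H) at
    fixed ρ, then latent type/link posteriors evaluated at the optimum.
    Equivalent to :func:`gml_fit` with ``max_macro_iters=1``."""
    config = config or OptimizerConfig()
    cfg1 = replace(config, max_macro_iters=1)
    return gml_fit(raster, geometry, rho_init=rho, config=cfg1, init=init,
                   method_name="map")


# ---------------------------------------------------------------------------
# latent posteriors (micro E-step)
# ---------------------------------------------------------------------------

def posteriors_all(net: EffectiveNetwork, rho: Hyperparameters,
                   geometry: NetworkGeometry) -> LatentPosteriors:
    """Vectorised type and link posteriors for the whole network.

    P(z_j=+1) ∝ γ Π_{l≠j} m_+(J_lj); P(φ_ij=1|z) ∝ q_ij·slab_z(J_ij); the
    marginal link belief mixes the conditionals over P(z_j). Diagonals use a
    sign-agnostic slab (type constraint does not apply to refractory
    self-couplings)."""
    rho.validate()
    J = net.J
    n = J.shape[0]
    lm_pos, lm_neg, l0, l1p, l1m, _ = _log_mixture(J, geometry, rho)
    od = _offdiag_mask(n)
    with np.errstate(divide="ignore"):
        lg, l1mg = np.log(rho.gamma) if rho.gamma > 0 else -np.inf, \
            np.log1p(-rho.gamma) if rho.gamma < 1 else -np.inf
    col_pos = lg + np.where(od, lm_pos, 0.0).sum(axis=0)
    col_neg = l1mg + np.where(od, lm_neg, 0.0).sum(axis=0)
    both = np.stack([col_pos, col_neg])
    if np.any(~np.isfinite(logsumexp(both, axis=0))):
        raise FloatingPointError("degenerate type posterior (both masses zero)")
    pz = np.exp(col_pos - logsumexp(both, axis=0))

    def _cond(l1: np.ndarray) -> np.ndarray:
        norm = np.logaddexp(l0, l1)
        with np.errstate(invalid="ignore"):
            c = np.exp(l1 - norm)
        return np.nan_to_num(c, nan=0.0)

    cond_pos = _cond(l1p)
    cond_neg = _cond(l1m)
    pphi = pz[None, :] * cond_pos + (1.0 - pz)[None, :] * cond_neg
    # diagonal: slab density of the matching sign, weight 1/2 per sign
    diag = np.arange(n)
    l1_diag = np.logaddexp(l1p[diag, diag], l1m[diag, diag]) + np.log(0.5)
    pphi[diag, diag] = _cond_scalarised(l0[diag, diag], l1_diag)
    return LatentPosteriors(pz=pz, pphi=pphi, pphi_pos=cond_pos, pphi_neg=cond_neg)


def _cond_scalarised(l0: np.ndarray, l1: np.ndarray) -> np.ndarray:
    norm = np.logaddexp(l0, l1)
    with np.errstate(invalid="ignore"):
        c = np.exp(l1 - norm)
    return np.nan_to_num(c, nan=0.0)


def posterior_z(net: EffectiveNetwork, rho: Hyperparameters,
                geometry: NetworkGeometry, j: int) -> float:
    """P(z_j = +1) given the fitted couplings of column j (diagonal excluded)."""
    return float(posteriors_all(net, rho, geometry).pz[j])


def posterior_phi(net: EffectiveNetwork, latents: LatentPosteriors,
                  rho: Hyperparameters, geometry: NetworkGeometry,
                  i: int, j: int) -> float:
    """P(φ_ij = 1), the type-marginal link belief for the ordered pair j→i."""
    if latents.pphi_pos is None:
        latents = posteriors_all(net, rho, geometry)
    if i == j:
        return float(latents.pphi[i, j])
    return float(latents.pz[j] * latents.pphi_pos[i, j]
                 + (1.0 - latents.pz[j]) * latents.pphi_neg[i, j])


# ---------------------------------------------------------------------------
# hyperparameter M-step and micro EM
# ---------------------------------------------------------------------------

def _a_objective_grad(a: float, pphi: np.ndarray, geometry: NetworkGeometry,
                      ) -> tuple[float, float]:
    """Expected link-prior term of Q as a function of a, with gradient.
    Entries with θ=0 are constants and excluded."""
    od = _offdiag_mask(pphi.shape[0])
    mask = od & (geometry.theta > 0)
    th = geometry.theta[mask]
    l = geometry.l[mask]
    p1 = pphi[mask]
    q = th * np.exp(-a * l)
    q = np.clip(q, 1e-300, 1.0 - 1e-12)
    val = float(np.sum(p1 * np.log(q) + (1.0 - p1) * np.log1p(-q)))
    grad = float(np.sum(-p1 * l + (1.0 - p1) * l * q / (1.0 - q)))
    return val, grad


def _update_a(a_old: float, pphi: np.ndarray, geometry: NetworkGeometry,
              a_max: float = 1.0, max_steps: int = 50) -> float:
    """Projected gradient ascent with backtracking on [0, a_max]; never
    decreases the objective."""
    a = a_old
    val, grad = _a_objective_grad(a, pphi, geometry)
    step = 1.0 / (1.0 + abs(grad))
    for _ in range(max_steps):
        a_new = float(np.clip(a + step * grad, 0.0, a_max))
        val_new, grad_new = _a_objective_grad(a_new, pphi, geometry)
        if val_new >= val and a_new != a:
            a, val, grad = a_new, val_new, grad_new
            step *= 1.5
        else:
            step *= 0.5
            if step * max(abs(grad), 1.0) < 1e-10:
                break
    return a


def update_hyperparameters(net: EffectiveNetwork, latents: LatentPosteriors,
                           geometry: NetworkGeometry, rho_old: Hyperparameters,
                           update_H: bool = True, update_a: bool = True,
                           ) -> Hyperparameters:
    """Closed-form micro M-step.

    γ ← mean type belief; μ_J±, v_J± ← responsibility-weighted moments of
    ln|J| over off-diagonal couplings with weight P(φ=1, z=±1); μ_H, v_H ←
    field moments; a ← projected gradient ascent on its Q terms. A class with
    zero total responsibility keeps its previous value (with a warning).
    """
    J, H = net.J, net.H
    n = J.shape[0]
    od = _offdiag_mask(n)
    if latents.pphi_pos is None or latents.pphi_neg is None:
        raise ValueError("latents must carry per-type link conditionals")
    new = {}
    new["gamma"] = float(np.mean(latents.pz))
    # couplings inside the spike's own support carry no information about the
    # slab moments; excluding them keeps the log-normal updates well-posed
    j_floor = 3.0 * np.sqrt(rho_old.epsilon)
    for label, cond, pz_w, sgn in (("p", latents.pphi_pos, latents.pz, +1),
                                   ("m", latents.pphi_neg, 1.0 - latents.pz, -1)):
        w = cond * pz_w[None, :]
        mask = od & ((sgn * J) > j_floor)
        wt = w[mask]
        tot = wt.sum()
        if tot <= 1e-12:
            warnings.warn(f"zero responsibility for class {label}; keeping previous value")
            new[f"mu_J{label}"] = getattr(rho_old, f"mu_J{label}")
            new[f"v_J{label}"] = getattr(rho_old, f"v_J{label}")
            continue
        lx = np.log(sgn * J[mask])
        mu = float(np.sum(wt * lx) / tot)
        v = float(np.sum(wt * (lx - mu) ** 2) / tot)
        new[f"mu_J{label}"] = mu
        new[f"v_J{label}"] = max(v, _V_FLOOR)
    if update_H:
        new["mu_H"] = float(np.mean(H))
        new["v_H"] = max(float(np.var(H)), _V_FLOOR)
    else:
        new["mu_H"], new["v_H"] = rho_old.mu_H, rho_old.v_H
    if update_a:
        new["a"] = _update_a(rho_old.a, latents.pphi, geometry)
    else:
        new["a"] = rho_old.a
    return Hyperparameters(epsilon=rho_old.epsilon, **new)


def micro_em_objective(net: EffectiveNetwork, rho: Hyperparameters,
                       geometry: NetworkGeometry) -> float:
    """The marginal objective the micro EM climbs: ln p(H|ρ) + ln p(J|ρ)
    (the data term is constant while (J, H) are held fixed)."""
    return log_prior_H(net.H, rho) + log_prior_J(net.J, geometry, rho)


def _micro_em(net: EffectiveNetwork, rho: Hyperparameters,
              geometry: NetworkGeometry, config: OptimizerConfig,
              ) -> tuple[Hyperparameters, LatentPosteriors, list[float]]:
    trace = [micro_em_objective(net, rho, geometry)]
    latents = posteriors_all(net, rho, geometry)
    for _ in range(config.max_micro_iters):
        rho_new = update_hyperparameters(
            net, latents, geometry, rho,
            update_H=config.update_H_prior, update_a=config.update_a)
        trace.append(micro_em_objective(net, rho_new, geometry))
        delta = max(abs(getattr(rho_new, k) - getattr(rho, k))
                    for k in ("gamma", "a", "mu_H", "v_H", "mu_Jp", "v_Jp",
                              "mu_Jm", "v_Jm"))
        rho = rho_new
        latents = posteriors_all(net, rho, geometry)
        if delta < config.micro_tol:
            break
    return rho, latents, trace


# ---------------------------------------------------------------------------
# GML: two-layer EM
# ---------------------------------------------------------------------------

def hyperparameters_from_mle(net: EffectiveNetwork, base: Hyperparameters,
                             j_floor: float = 1e-3) -> Hyperparameters:
    """Seed ρ from MLE moments: columns are provisionally typed by the sign
    of their summed off-diagonal couplings; log-normal locations/scales come
    from the matching-sign couplings above ``j_floor``; the field prior from
    the moments of H. γ, a, θ and ε are kept from ``base``."""
    J, H = net.J, net.H
    n = J.shape[0]
    od = _offdiag_mask(n)
    colsum = np.where(od, J, 0.0).sum(axis=0)
    out = base.as_dict()
    for label, sgn in (("p", +1), ("m", -1)):
        cols = colsum * sgn > 0
        vals = (sgn * J)[od & cols[None, :] & ((sgn * J) > j_floor)]
        if vals.size == 0:
            vals = (sgn * J)[od & ((sgn * J) > j_floor)]
        if vals.size >= 2:
            lv = np.log(vals)
            out[f"mu_J{label}"] = float(lv.mean())
            out[f"v_J{label}"] = max(float(lv.var()), _V_FLOOR)
    out["mu_H"] = float(H.mean())
    out["v_H"] = max(float(H.var()), _V_FLOOR)
    return Hyperparameters(**out)


def gml_fit(raster: SpikeRaster, geometry: NetworkGeometry,
            rho_init: Hyperparameters | str = "from-mle",
            config: OptimizerConfig | None = None,
            init: EffectiveNetwork | str = "mle",
            method_name: str = "gml") -> InferenceResult:
    """Generalised-maximum-likelihood fit: alternate macro-E (L-BFGS ascent
    of the evidence objective in (J, H) at fixed ρ) with macro-M (micro EM
    re-estimation of ρ from the latent posteriors) until both stabilise.

    ``rho_init="from-mle"`` seeds the hyperparameters from MLE moments, as
    does ``init="mle"`` for the network itself. ``max_macro_iters=1`` is
    exactly MAP estimation.
    """
    config = config or OptimizerConfig()
    if isinstance(init, str):
        if init != "mle":
            raise ValueError(f"unknown init {init!r}")
        net = mle_fit(raster, replace(config))
    else:
        net = init
    if isinstance(rho_init, str):
        if rho_init != "from-mle":
            raise ValueError(f"unknown rho_init {rho_init!r}")
        rho = hyperparameters_from_mle(net, Hyperparameters())
    else:
        rho = rho_init
    rho.validate()

    trace: list[float] = []
    converged = False
    for it in range(config.max_macro_iters):
        J_prev, H_prev, rho_prev = net.J.copy(), net.H.copy(), rho
        net, _ = _optimize(raster, net, config, rho=rho, geometry=geometry)
        trace.append(evidence_objective(raster, net, rho, geometry))
        if it == config.max_macro_iters - 1:
            break
        rho, _, _ = _micro_em(net, rho, geometry, config)
        d_net = max(np.max(np.abs(net.J - J_prev)), np.max(np.abs(net.H - H_prev)))
        d_rho = max(abs(getattr(rho, k) - getattr(rho_prev, k))
                    for k in ("gamma", "a", "mu_H", "v_H", "mu_Jp", "v_Jp",
                              "mu_Jm", "v_Jm"))
        if d_net < config.macro_tol and d_rho < config.macro_tol:
            converged = True
            break
    else:  # pragma: no cover - loop always breaks or exhausts above
        pass
    if config.max_macro_iters == 1:
        converged = True
    if not converged and config.max_macro_iters > 1:
        warnings.warn("GML macro loop hit max_macro_iters without convergence")
    latents = posteriors_all(net, rho, geometry)
    z_hat, phi_hat, _ = classify_arrays(net.J, latents, config.phi_threshold)
    return InferenceResult(net=net, latents=latents, rho=rho, z_hat=z_hat,
                           phi_hat=phi_hat, trace=trace, converged=converged,
                           method=method_name)


# ---------------------------------------------------------------------------
# final decisions
# ---------------------------------------------------------------------------

def classify_arrays(J: np.ndarray, latents: LatentPosteriors,
                    phi_threshold: float = 0.5,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z_hat = np.where(latents.pz >= 0.5, 1, -1)
    phi_hat = (latents.pphi >= phi_threshold).astype(int)
    return z_hat, phi_hat, J * phi_hat


def classify(result: InferenceResult, phi_threshold: float = 0.5,
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Highest-probability-state decisions: ẑ_j = +1 iff P(z_j=+1) ≥ 0.5
    (ties to the majority class), φ̂_ij = 1 iff P(φ_ij=1) ≥ threshold, and
    the coupling matrix masked to the retained links."""
    return classify_arrays(result.net.J, result.latents, phi_threshold)
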