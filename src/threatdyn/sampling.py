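"""No-U-Turn sampler with dual-averaging step size and diagonal mass matrix.

A small, self-contained NUTS implementation (slice-sampling variant with
dynamic termination) operating on a caller-supplied log-density-and-
gradient callable.  Warmup follows the usual three-phase schedule: an
initial step-size phase, doubling variance-estimation windows that update
the diagonal inverse mass matrix, and a terminal step-size phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class SamplerConfig:
    """Chain layout and adaptation settings."""

    chains: int = 4
    draws: int = 5000
    warmup: int = 1000
    seed: int = 0
    target_accept: float = 0.85
    max_treedepth: int = 10
    rhat_tol: float | None = 1.01  # None disables the convergence gate

    def to_dict(self) -> dict:
        return {
            "chains": self.chains,
            "draws": self.draws,
            "warmup": self.warmup,
            "seed": self.seed,
            "target_accept": self.target_accept,
            "max_treedepth": self.max_treedepth,
            "rhat_tol": self.rhat_tol,
        }


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman, 2014)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0
        self.gamma = 0.05
        self.t0 = 10.0
        self.kappa = 0.75

    def update(self, accept_prob: float) -> float:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        eta = self.t ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1 - eta) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    def restart(self) -> None:
        self.mu = np.log(10.0) + self.log_eps
        self.h_bar = 0.0
        self.t = 0

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # regularize toward unit scale as Stan does
        return (self.n / (self.n + 5.0)) * var + 1e-3 * (5.0 / (self.n + 5.0))


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p, inv_mass * p))


def find_reasonable_epsilon(logp_grad, q, inv_mass, rng) -> float:
    """Heuristic initial step size (Hoffman & Gelman, Algorithm 4)."""
    eps = 1.0
    logp, grad = logp_grad(q)
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p, inv_mass)
    q1, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
    h1 = logp1 - _kinetic(p1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        q1, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-10)


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "grad_minus",
        "q_plus", "p_plus", "grad_plus",
        "q_prop", "logp_prop", "grad_prop",
        "n_valid", "stop", "alpha", "n_alpha",
    )


def _build_tree(logp_grad, q, p, grad, log_u, direction, depth, eps, inv_mass, h0, rng):
    tree = _Tree()
    if depth == 0:
        q1, p1, logp1, grad1 = _leapfrog(logp_grad, q, p, grad, direction * eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        tree.q_minus = tree.q_plus = tree.q_prop = q1
        tree.p_minus = tree.p_plus = p1
        tree.grad_minus = tree.grad_plus = tree.grad_prop = grad1
        tree.logp_prop = logp1
        tree.n_valid = int(log_u <= h1)
        tree.stop = (h1 - h0) < -MAX_DELTA_H  # divergence
        tree.alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0))))
        tree.n_alpha = 1
        return tree

    left = _build_tree(logp_grad, q, p, grad, log_u, direction, depth - 1, eps, inv_mass, h0, rng)
    if left.stop:
        return left
    if direction == 1:
        right = _build_tree(
            logp_grad, left.q_plus, left.p_plus, left.grad_plus,
            log_u, direction, depth - 1, eps, inv_mass, h0, rng,
        )
        left.q_plus, left.p_plus, left.grad_plus = right.q_plus, right.p_plus, right.grad_plus
    else:
        right = _build_tree(
            logp_grad, left.q_minus, left.p_minus, left.grad_minus,
            log_u, direction, depth - 1, eps, inv_mass, h0, rng,
        )
        left.q_minus, left.p_minus, left.grad_minus = right.q_minus, right.p_minus, right.grad_minus

    total = left.n_valid + right.n_valid
    if total > 0 and rng.random() < right.n_valid / total:
        left.q_prop, left.logp_prop, left.grad_prop = right.q_prop, right.logp_prop, right.grad_prop
    left.alpha += right.alpha
    left.n_alpha += right.n_alpha
    left.n_valid = total
    dq = left.q_plus - left.q_minus
    no_uturn = (
        np.dot(dq, inv_mass * left.p_minus) >= 0
        and np.dot(dq, inv_mass * left.p_plus) >= 0
    )
    left.stop = right.stop or not no_uturn
    return left


def _nuts_step(logp_grad, q, logp, grad, eps, inv_mass, max_depth, rng):
    p0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p0, inv_mass)
    log_u = h0 + np.log(rng.random())
    q_minus = q_plus = q
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    q_new, logp_new, grad_new = q, logp, grad
    n_valid = 1
    alpha_sum, n_alpha = 0.0, 0
    depth = 0
    while depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            tree = _build_tree(
                logp_grad, q_plus, p_plus, grad_plus,
                log_u, 1, depth, eps, inv_mass, h0, rng,
            )
            q_plus, p_plus, grad_plus = tree.q_plus, tree.p_plus, tree.grad_plus
        else:
            tree = _build_tree(
                logp_grad, q_minus, p_minus, grad_minus,
                log_u, -1, depth, eps, inv_mass, h0, rng,
            )
            q_minus, p_minus, grad_minus = tree.q_minus, tree.p_minus, tree.grad_minus
        alpha_sum += tree.alpha
        n_alpha += tree.n_alpha
        if not tree.stop and tree.n_valid > 0:
            if rng.random() < tree.n_valid / n_valid:
                q_new, logp_new, grad_new = tree.q_prop, tree.logp_prop, tree.grad_prop
        n_valid += tree.n_valid
        if tree.stop:
            break
        dq = q_plus - q_minus
        if (
            np.dot(dq, inv_mass * p_minus) < 0
            or np.dot(dq, inv_mass * p_plus) < 0
        ):
            break
        depth += 1
    accept_prob = alpha_sum / max(n_alpha, 1)
    return q_new, logp_new, grad_new, accept_prob


def sample_chain(
    logp_grad: LogpGrad,
    init: np.ndarray,
    draws: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_treedepth: int = 10,
) -> np.ndarray:
    """Run one NUTS chain; returns post-warmup draws of shape (draws, dim)."""
    q = np.array(init, dtype=float)
    dim = q.size
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = find_reasonable_epsilon(logp_grad, q, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)

    # warmup schedule: 15% step size, doubling mass windows, 10% step size
    init_buffer = max(int(0.15 * warmup), 10)
    term_buffer = max(int(0.10 * warmup), 10)
    window_end = min(init_buffer + 25, warmup - term_buffer)
    window = _Welford(dim)

    out = np.empty((draws, dim))
    for i in range(warmup + draws):
        q, logp, grad, accept = _nuts_step(
            logp_grad, q, logp, grad, eps, inv_mass, max_treedepth, rng
        )
        if i < warmup:
            eps = da.update(accept)
            if init_buffer <= i < warmup - term_buffer:
                window.update(q)
                if i + 1 == window_end:
                    inv_mass = window.variance()
                    window = _Welford(dim)
                    next_size = 2 * (window_end - init_buffer)
                    window_end = window_end + next_size
                    if window_end + next_size > warmup - term_buffer:
                        window_end = warmup - term_buffer
                    eps = find_reasonable_epsilon(logp_grad, q, inv_mass, rng)
                    da = _DualAveraging(eps, target_accept)
            if i + 1 == warmup:
                eps = da.adapted
        else:
            out[i - warmup] = q
    return out


def sample_nuts(
    logp_grad: LogpGrad,
    dim: int,
    config: SamplerConfig,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Run ``config.chains`` chains; returns draws of shape (chains, draws, dim).

    Each chain gets an independent jittered start and its own RNG stream
    spawned deterministically from ``config.seed``.
    """
    base = np.zeros(dim) if init is None else np.asarray(init, dtype=float)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        start = base + 0.1 * rng.standard_normal(dim)
        chains.append(
            sample_chain(
                logp_grad,
                start,
                config.draws,
                config.warmup,
                rng,
                target_accept=config.target_accept,
                max_treedepth=config.max_treedepth,
            )
        )
    return np.stack(chains)
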