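"""Gradient-based MCMC: multinomial No-U-Turn sampling and chain diagnostics.

The hierarchical interval models expose an unconstrained log-posterior with
analytic gradients; this module samples from it with the No-U-Turn variant of
Hamiltonian Monte Carlo (recursive doubling, multinomial state selection,
dual-averaging step-size adaptation, diagonal mass-matrix estimation during
warm-up) and provides the split-chain rank-normalised potential scale
reduction factor (Rhat) used for convergence checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
import scipy.stats as ss
from scipy.special import ndtri

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

__all__ = ["nuts_sample", "split_rhat", "NUTSStats"]

_DELTA_MAX = 1000.0  # energy-error divergence threshold


@dataclass
class NUTSStats:
    """Per-chain sampler statistics."""

    step_size: float
    inv_mass: np.ndarray
    accept_stat: np.ndarray  # mean Metropolis acceptance per kept iteration
    tree_depth: np.ndarray
    divergences: int


class _State(NamedTuple):
    q: np.ndarray
    p: np.ndarray
    grad: np.ndarray
    logp: float


class _Tree(NamedTuple):
    left: _State
    right: _State
    prop_q: np.ndarray
    prop_logp: float
    prop_grad: np.ndarray
    log_sum_w: float
    sum_accept: float
    n_leapfrog: int
    ok: bool          # no u-turn inside, no divergence
    diverged: bool


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    def __init__(self, mu: float, target: float = 0.8, gamma: float = 0.05,
                 t0: float = 10.0, kappa: float = 0.75):
        self.mu = mu
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.count = 0
        self.h_bar = 0.0
        self.log_eps_bar = 0.0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_prob)
        log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** (-self.kappa)
        self.log_eps_bar = eta * log_eps + (1 - eta) * self.log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _NUTSChain:
    def __init__(self, logp_grad: LogpGrad, inv_mass: np.ndarray,
                 rng: np.random.Generator):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass
        self.rng = rng
        self.eps = 1.0

    def hamiltonian(self, state: _State) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            h = state.logp - 0.5 * float(
                np.dot(state.p * self.inv_mass, state.p)
            )
        return h if np.isfinite(h) else -np.inf

    def leapfrog(self, state: _State, direction: int) -> _State:
        # overflow inside a divergent excursion is expected: the energy
        # check rejects the state, so silence the transient warnings
        with np.errstate(over="ignore", invalid="ignore"):
            eps = direction * self.eps
            p = state.p + 0.5 * eps * state.grad
            q = state.q + eps * self.inv_mass * p
            logp, grad = self.logp_grad(q)
            p = p + 0.5 * eps * grad
        return _State(q, p, grad, logp)

    def _no_uturn(self, left: _State, right: _State) -> bool:
        dq = right.q - left.q
        return (np.dot(dq, self.inv_mass * left.p) >= 0
                and np.dot(dq, self.inv_mass * right.p) >= 0)

    def build_tree(self, state: _State, direction: int, depth: int,
                   h0: float) -> _Tree:
        if depth == 0:
            new = self.leapfrog(state, direction)
            h = self.hamiltonian(new)
            if not np.isfinite(h) or (h0 - h) > _DELTA_MAX:
                return _Tree(new, new, new.q, new.logp, new.grad,
                             -np.inf, 0.0, 1, False, True)
            accept = float(np.exp(min(h - h0, 0.0)))
            return _Tree(new, new, new.q, new.logp, new.grad,
                         h - h0, accept, 1, True, False)

        first = self.build_tree(state, direction, depth - 1, h0)
        if not first.ok:
            return first
        inner = first.right if direction == 1 else first.left
        second = self.build_tree(inner, direction, depth - 1, h0)

        n_leap = first.n_leapfrog + second.n_leapfrog
        sum_accept = first.sum_accept + second.sum_accept
        if not second.ok:
            return _Tree(first.left, first.right, first.prop_q, first.prop_logp,
                         first.prop_grad, first.log_sum_w, sum_accept, n_leap,
                         False, second.diverged)

        left = second.left if direction == -1 else first.left
        right = second.right if direction == 1 else first.right
        total = np.logaddexp(first.log_sum_w, second.log_sum_w)
        if np.log(self.rng.random() + 1e-300) < second.log_sum_w - total:
            prop = (second.prop_q, second.prop_logp, second.prop_grad)
        else:
            prop = (first.prop_q, first.prop_logp, first.prop_grad)
        ok = self._no_uturn(left, right)
        return _Tree(left, right, *prop, total, sum_accept, n_leap, ok, False)

    def step(self, q: np.ndarray, logp: float, grad: np.ndarray,
             max_treedepth: int):
        p0 = self.rng.standard_normal(q.size) / np.sqrt(self.inv_mass)
        current = _State(q, p0, grad, logp)
        h0 = self.hamiltonian(current)

        left = right = current
        prop_q, prop_logp, prop_grad = q, logp, grad
        log_sum_w = 0.0
        sum_accept, n_leap = 0.0, 0
        depth = 0
        diverged = False

        while depth < max_treedepth:
            direction = 1 if self.rng.random() < 0.5 else -1
            start = right if direction == 1 else left
            tree = self.build_tree(start, direction, depth, h0)
            sum_accept += tree.sum_accept
            n_leap += tree.n_leapfrog
            diverged = diverged or tree.diverged
            if not tree.ok:
                break
            if direction == 1:
                right = tree.right
            else:
                left = tree.left
            total = np.logaddexp(log_sum_w, tree.log_sum_w)
            # biased progressive sampling toward the new subtree
            if np.log(self.rng.random() + 1e-300) < tree.log_sum_w - log_sum_w:
                prop_q, prop_logp, prop_grad = (tree.prop_q, tree.prop_logp,
                                                tree.prop_grad)
            log_sum_w = total
            depth += 1
            if not self._no_uturn(left, right):
                break

        accept_prob = sum_accept / max(n_leap, 1)
        return prop_q, prop_logp, prop_grad, accept_prob, depth, diverged

    def find_initial_step(self, q: np.ndarray) -> float:
        """Double/halve the step until acceptance crosses 1/2."""
        self.eps = 1.0
        logp, grad = self.logp_grad(q)
        p = self.rng.standard_normal(q.size) / np.sqrt(self.inv_mass)
        state = _State(q, p, grad, logp)
        h0 = self.hamiltonian(state)

        def energy_gain() -> float:
            new = self.leapfrog(state, 1)
            h = self.hamiltonian(new)
            return h - h0 if np.isfinite(h) else -np.inf

        gain = energy_gain()
        while not np.isfinite(gain) and self.eps > 1e-10:
            self.eps *= 0.5
            gain = energy_gain()
        direction = 1 if gain > np.log(0.5) else -1
        for _ in range(100):
            self.eps *= 2.0 ** direction
            gain = energy_gain()
            if direction == 1 and gain <= np.log(0.5):
                break
            if direction == -1 and gain > np.log(0.5):
                break
            if not 1e-10 < self.eps < 1e7:
                break
        self.eps = float(np.clip(self.eps, 1e-8, 10.0))
        return self.eps


def nuts_sample(
    logp_grad: LogpGrad,
    init: np.ndarray,
    n_iter: int,
    n_warmup: int,
    rng: np.random.Generator,
    max_treedepth: int = 10,
    target_accept: float = 0.8,
) -> tuple[np.ndarray, NUTSStats]:
    """Run one NUTS chain; returns kept draws of shape (n_iter - n_warmup, dim).

    Warm-up adapts the step size by dual averaging throughout, and replaces
    the identity mass matrix once with regularised sample variances estimated
    from the middle portion of warm-up (a single-window version of the usual
    staged scheme).
    """
    if n_iter <= n_warmup:
        raise ValueError("n_iter must exceed n_warmup")
    q = np.asarray(init, dtype=float).copy()
    dim = q.size
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log probability")

    chain = _NUTSChain(logp_grad, np.ones(dim), rng)
    chain.find_initial_step(q)
    da = _DualAveraging(mu=np.log(10 * chain.eps), target=target_accept)

    draws = np.empty((n_iter - n_warmup, dim))
    accept_stats = np.empty(n_iter - n_warmup)
    depths = np.empty(n_iter - n_warmup, dtype=int)
    divergences = 0

    mass_lo, mass_hi = int(0.25 * n_warmup), int(0.8 * n_warmup)
    mass_buf = np.empty((max(mass_hi - mass_lo, 1), dim))

    for it in range(n_iter):
        q, logp, grad, accept_prob, depth, diverged = chain.step(
            q, logp, grad, max_treedepth
        )
        if it < n_warmup:
            chain.eps = da.update(accept_prob)
            if mass_lo <= it < mass_hi:
                mass_buf[it - mass_lo] = q
            if it == mass_hi - 1 and mass_hi - mass_lo >= 10:
                n = mass_hi - mass_lo
                var = np.var(mass_buf, axis=0, ddof=1)
                # shrink the variance estimate toward a small constant
                chain.inv_mass = np.clip(
                    (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0)), 1e-8, 1e8
                )
                chain.find_initial_step(q)
                da = _DualAveraging(mu=np.log(10 * chain.eps),
                                    target=target_accept)
            if it == n_warmup - 1:
                chain.eps = da.adapted
        else:
            if diverged:
                divergences += 1
            k = it - n_warmup
            draws[k] = q
            accept_stats[k] = accept_prob
            depths[k] = depth

    stats = NUTSStats(
        step_size=chain.eps,
        inv_mass=chain.inv_mass,
        accept_stat=accept_stats,
        tree_depth=depths,
        divergences=divergences,
    )
    return draws, stats


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain rank-normalised Rhat for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in half,
    all draws are replaced by their normal scores (mid-ranks, offset
    (r - 3/8)/(n + 1/4)), and the classic between/within-chain variance ratio
    is computed on the z-scores.  Values near 1 indicate agreement between
    chains; > 1.1 conventionally flags non-convergence.  Constant input
    returns NaN (degenerate parameter).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected shape (n_chains, n_draws)")
    n_draws = chains.shape[1]
    half = n_draws // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain for split Rhat")
    split = np.vstack([chains[:, :half], chains[:, half: 2 * half]])

    flat = split.ravel()
    if np.all(flat == flat[0]):
        return float("nan")
    ranks = ss.rankdata(flat)
    z = ndtri((ranks - 0.375) / (flat.size + 0.25)).reshape(split.shape)

    n = z.shape[1]
    b = n * z.mean(axis=1).var(ddof=1)
    w = z.var(axis=1, ddof=1).mean()
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))
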