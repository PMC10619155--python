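"""Adaptive Hamiltonian Monte Carlo (NUTS) for the multinomial models.

A self-contained dynamic-HMC implementation: multinomial sampling across the
doubling trajectory, dual-averaging step-size adaptation, and windowed
adaptation of a diagonal mass matrix. Draws are produced in the models'
unconstrained space; the pointwise log-likelihood of every retained draw is
evaluated and stored so that cross-validation never needs to touch the
sampler again.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .models import (
    ModelStructure,
    PriorConfig,
    loglik_for_draws,
    make_logp_grad,
    parameter_dim,
    parameter_names,
)

__all__ = ["SamplerConfig", "PosteriorDraws", "sample_posterior", "nuts"]

_DIVERGENCE_THRESHOLD = 1000.0  # energy error that flags a divergent transition
_INIT_JITTER = 0.1
_MAX_INIT_RETRIES = 10


@dataclass(frozen=True)
class SamplerConfig:
    """Run configuration; defaults to 4 chains x 2000 iterations with half
    used as warmup, i.e. 4000 retained draws."""

    n_chains: int = 4
    n_iterations_per_chain: int = 2000
    n_warmup: int = 1000
    target_acceptance: float = 0.9
    max_tree_depth: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required (split R-hat)")
        if not 0 < self.target_acceptance < 1:
            raise ValueError("target_acceptance must be in (0, 1)")
        if self.n_warmup >= self.n_iterations_per_chain:
            raise ValueError("n_warmup must be smaller than n_iterations_per_chain")

    @property
    def n_retained(self) -> int:
        return self.n_chains * (self.n_iterations_per_chain - self.n_warmup)


@dataclass
class PosteriorDraws:
    """Chain-structured draws plus sampler statistics and pointwise log-lik.

    ``draws`` has shape (chain, iteration, parameter) — post-warmup only —
    and ``log_lik`` (chain, iteration, observation).
    """

    draws: np.ndarray
    param_names: list[str]
    stats: dict[str, np.ndarray]
    log_lik: np.ndarray | None
    structure: ModelStructure
    priors: PriorConfig
    config: SamplerConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def stacked(self) -> np.ndarray:
        """All draws flattened to (n_draws, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def stacked_log_lik(self) -> np.ndarray:
        if self.log_lik is None:
            raise ValueError("fit carries no pointwise log-likelihood array")
        return self.log_lik.reshape(-1, self.log_lik.shape[-1])

    def divergence_count(self) -> int:
        """Total divergent transitions among retained iterations."""
        if "divergent" not in self.stats:
            raise ValueError("sampler statistics are missing from this fit")
        return int(self.stats["divergent"].sum())

    # -- serialization ---------------------------------------------------
    def save(self, fitdir: str | Path) -> None:
        fitdir = Path(fitdir)
        fitdir.mkdir(parents=True, exist_ok=True)
        np.save(fitdir / "draws.npy", self.draws)
        if self.log_lik is not None:
            np.save(fitdir / "log_lik.npy", self.log_lik)
        np.savez(fitdir / "stats.npz", **self.stats)
        meta = {
            "param_names": self.param_names,
            "structure": asdict(self.structure),
            "priors": asdict(self.priors),
            "config": asdict(self.config),
            "meta": self.meta,
        }
        (fitdir / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, fitdir: str | Path) -> "PosteriorDraws":
        fitdir = Path(fitdir)
        meta = json.loads((fitdir / "meta.json").read_text())
        log_lik_path = fitdir / "log_lik.npy"
        with np.load(fitdir / "stats.npz") as npz:
            stats = {k: npz[k] for k in npz.files}
        return cls(
            draws=np.load(fitdir / "draws.npy"),
            param_names=meta["param_names"],
            stats=stats,
            log_lik=np.load(log_lik_path) if log_lik_path.exists() else None,
            structure=ModelStructure(**meta["structure"]),
            priors=PriorConfig(**meta["priors"]),
            config=SamplerConfig(**meta["config"]),
            meta=meta.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# NUTS core
# ---------------------------------------------------------------------------


class _Tree:
    __slots__ = (
        "theta_prop",
        "grad_prop",
        "lp_prop",
        "log_sum_w",
        "rho",
        "diverged",
        "turned",
        "sum_accept",
        "n_leapfrog",
        "edge_back",  # (theta, r, grad) nearest the entry point
        "edge_fwd",  # (theta, r, grad) farthest along the integration direction
    )


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r_half = r + 0.5 * eps * grad
    theta_new = theta + eps * inv_mass * r_half
    lp_new, grad_new = logp_grad(theta_new)
    r_new = r_half + 0.5 * eps * grad_new
    return theta_new, r_new, lp_new, grad_new


def _kinetic(r, inv_mass):
    return 0.5 * float(np.dot(r * inv_mass, r))


def _uturn(rho, r_minus, r_plus, inv_mass) -> bool:
    return (
        np.dot(inv_mass * rho, r_minus) <= 0 or np.dot(inv_mass * rho, r_plus) <= 0
    )


def _build_tree(logp_grad, depth, theta, r, grad, direction, eps, inv_mass, h0, rng):
    """Recursively build a subtree starting one leapfrog step past (theta, r)."""
    tree = _Tree()
    if depth == 0:
        theta_n, r_n, lp_n, grad_n = _leapfrog(
            logp_grad, theta, r, grad, direction * eps, inv_mass
        )
        if np.isfinite(lp_n):
            delta_h = (-lp_n + _kinetic(r_n, inv_mass)) - h0
        else:
            delta_h = np.inf
        tree.diverged = not np.isfinite(delta_h) or delta_h > _DIVERGENCE_THRESHOLD
        tree.turned = False
        tree.theta_prop, tree.grad_prop, tree.lp_prop = theta_n, grad_n, lp_n
        tree.log_sum_w = -delta_h if not tree.diverged else -np.inf
        tree.rho = r_n.copy()
        tree.sum_accept = (
            float(min(1.0, np.exp(-delta_h))) if np.isfinite(delta_h) else 0.0
        )
        tree.n_leapfrog = 1
        tree.edge_back = tree.edge_fwd = (theta_n, r_n, grad_n)
        return tree

    first = _build_tree(
        logp_grad, depth - 1, theta, r, grad, direction, eps, inv_mass, h0, rng
    )
    if first.diverged or first.turned:
        return first
    theta_e, r_e, grad_e = first.edge_fwd
    second = _build_tree(
        logp_grad, depth - 1, theta_e, r_e, grad_e, direction, eps, inv_mass, h0, rng
    )

    tree.diverged = second.diverged
    tree.n_leapfrog = first.n_leapfrog + second.n_leapfrog
    tree.sum_accept = first.sum_accept + second.sum_accept
    tree.log_sum_w = np.logaddexp(first.log_sum_w, second.log_sum_w)
    tree.rho = first.rho + second.rho
    tree.edge_back = first.edge_back
    tree.edge_fwd = second.edge_fwd
    if second.diverged:
        tree.theta_prop = first.theta_prop
        tree.grad_prop, tree.lp_prop = first.grad_prop, first.lp_prop
        tree.turned = False
        return tree
    # multinomial choice between the two halves
    if np.log(rng.uniform()) < second.log_sum_w - tree.log_sum_w:
        tree.theta_prop = second.theta_prop
        tree.grad_prop, tree.lp_prop = second.grad_prop, second.lp_prop
    else:
        tree.theta_prop = first.theta_prop
        tree.grad_prop, tree.lp_prop = first.grad_prop, first.lp_prop
    # U-turn check across the combined subtree (momenta at its two ends)
    tree.turned = second.turned or _uturn(
        tree.rho, tree.edge_back[1], tree.edge_fwd[1], inv_mass
    )
    return tree


def _find_reasonable_eps(logp_grad, theta, lp, grad, inv_mass, rng) -> float:
    eps = 0.1
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = -lp + _kinetic(r, inv_mass)
    _, r_n, lp_n, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    log_a = (-(-lp_n + _kinetic(r_n, inv_mass))) + h0 if np.isfinite(lp_n) else -np.inf
    direction = 1.0 if log_a > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, r_n, lp_n, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        if np.isfinite(lp_n):
            log_a = h0 - (-lp_n + _kinetic(r_n, inv_mass))
        else:
            log_a = -np.inf
        if direction * log_a <= direction * np.log(0.5):
            break
    return float(np.clip(eps, 1e-8, 1e2))


def _adaptation_windows(n_warmup: int) -> list[int]:
    """Iteration indices (within warmup) at which to re-estimate the metric."""
    if n_warmup < 40:
        return []
    init_buffer = 75 if n_warmup >= 150 else max(10, n_warmup // 5)
    term_buffer = 50 if n_warmup >= 150 else max(10, n_warmup // 10)
    ends = []
    start, size = init_buffer, 25
    while start + size < n_warmup - term_buffer:
        next_size = size * 2
        if start + size + next_size >= n_warmup - term_buffer:
            ends.append(n_warmup - term_buffer)
            return ends
        ends.append(start + size)
        start += size
        size = next_size
    if not ends:
        ends.append(n_warmup - term_buffer)
    return ends


def _nuts_chain(logp_grad, dim, config: SamplerConfig, rng: np.random.Generator):
    n_iter, n_warmup = config.n_iterations_per_chain, config.n_warmup
    n_keep = n_iter - n_warmup

    # initialization with retries on a non-finite posterior
    theta = None
    for _ in range(_MAX_INIT_RETRIES):
        cand = rng.uniform(-_INIT_JITTER, _INIT_JITTER, dim)
        lp, grad = logp_grad(cand)
        if np.isfinite(lp):
            theta = cand
            break
    if theta is None:
        raise RuntimeError(
            "could not find an initial point with finite log-posterior after "
            f"{_MAX_INIT_RETRIES} retries; check the data/prior configuration"
        )

    inv_mass = np.ones(dim)
    eps = _find_reasonable_eps(logp_grad, theta, lp, grad, inv_mass, rng)

    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_iter = 0

    window_ends = _adaptation_windows(n_warmup)
    window_buffer: list[np.ndarray] = []

    draws = np.empty((n_keep, dim))
    divergent = np.zeros(n_keep, dtype=bool)
    energy = np.empty(n_keep)
    tree_depth = np.zeros(n_keep, dtype=np.int64)
    accept_stat = np.empty(n_keep)
    n_leapfrog_total = 0

    for it in range(n_iter):
        r = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = -lp + _kinetic(r, inv_mass)

        edges = {1: (theta, r, grad), -1: (theta, r, grad)}
        theta_prop, grad_prop, lp_prop = theta, grad, lp
        log_sum_w = 0.0
        rho = r.copy()
        sum_accept, n_leap = 0.0, 0
        diverged_this = False
        depth = 0
        while depth < config.max_tree_depth:
            direction = 1 if rng.uniform() < 0.5 else -1
            theta_e, r_e, grad_e = edges[direction]
            subtree = _build_tree(
                logp_grad,
                depth,
                theta_e,
                r_e,
                grad_e,
                direction,
                eps,
                inv_mass,
                h0,
                rng,
            )
            edges[direction] = subtree.edge_fwd
            sum_accept += subtree.sum_accept
            n_leap += subtree.n_leapfrog
            if subtree.diverged:
                diverged_this = True
                break
            if subtree.turned:
                break
            # biased progressive sampling toward the new subtree
            if np.log(rng.uniform()) < subtree.log_sum_w - log_sum_w:
                theta_prop = subtree.theta_prop
                grad_prop, lp_prop = subtree.grad_prop, subtree.lp_prop
            log_sum_w = np.logaddexp(log_sum_w, subtree.log_sum_w)
            rho += subtree.rho
            depth += 1
            if _uturn(rho, edges[-1][1], edges[1][1], inv_mass):
                break

        theta, grad, lp = theta_prop, grad_prop, lp_prop
        accept_prob = sum_accept / max(n_leap, 1)
        n_leapfrog_total += n_leap

        if it < n_warmup:
            # dual averaging step-size update
            da_iter += 1
            eta = 1.0 / (da_iter + t0)
            h_bar = (1 - eta) * h_bar + eta * (config.target_acceptance - accept_prob)
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))

            window_buffer.append(theta.copy())
            if (it + 1) in window_ends:
                samples = np.asarray(window_buffer)
                m = samples.shape[0]
                var = samples.var(axis=0, ddof=1) if m > 1 else np.ones(dim)
                inv_mass = (m / (m + 5.0)) * var + 1e-3 * (5.0 / (m + 5.0))
                window_buffer.clear()
                # restart step-size adaptation around a fresh reasonable eps
                eps = _find_reasonable_eps(logp_grad, theta, lp, grad, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            k = it - n_warmup
            draws[k] = theta
            divergent[k] = diverged_this
            energy[k] = h0
            tree_depth[k] = depth
            accept_stat[k] = accept_prob

    stats = {
        "divergent": divergent,
        "energy": energy,
        "tree_depth": tree_depth,
        "accept_stat": accept_stat,
        "step_size": np.full(n_keep, eps),
        "n_leapfrog_total": np.array([n_leapfrog_total]),
    }
    return draws, stats


def nuts(
    logp_grad,
    dim: int,
    config: SamplerConfig,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Run NUTS on an arbitrary unconstrained density with gradient.

    Returns draws of shape (chain, kept iteration, dim) and per-chain
    sampler statistics stacked along the chain axis.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws, all_stats = [], []
    for chain_seed in seeds:
        rng = np.random.default_rng(chain_seed)
        draws, stats = _nuts_chain(logp_grad, dim, config, rng)
        all_draws.append(draws)
        all_stats.append(stats)
    draws = np.stack(all_draws)
    stats = {
        k: np.stack([s[k] for s in all_stats]) for k in all_stats[0] if k != "n_leapfrog_total"
    }
    stats["n_leapfrog_total"] = np.array(
        [int(s["n_leapfrog_total"][0]) for s in all_stats]
    )
    return draws, stats


def sample_posterior(
    structure: ModelStructure,
    priors: PriorConfig,
    y: np.ndarray,
    x: np.ndarray,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
    config: SamplerConfig | None = None,
    meta: dict | None = None,
    store_log_lik: bool = True,
) -> PosteriorDraws:
    """Sample the posterior of one model structure on coded observation arrays.

    ``y`` codes the outcome (0=CN, 1=MCI, 2=AD); ``x`` is the normalized
    predictor; ``u``/``v`` are 0-based ROI and network codes. Deterministic
    given the configuration seed.
    """
    config = config or SamplerConfig()
    logp_grad = make_logp_grad(structure, priors, y, x, u, v)
    dim = parameter_dim(structure)
    draws, stats = nuts(logp_grad, dim, config)

    log_lik = None
    if store_log_lik:
        flat = draws.reshape(-1, dim)
        ll = loglik_for_draws(flat, structure, y, x, u, v)
        log_lik = ll.reshape(draws.shape[0], draws.shape[1], -1)

    return PosteriorDraws(
        draws=draws,
        param_names=parameter_names(structure),
        stats=stats,
        log_lik=log_lik,
        structure=structure,
        priors=priors,
        config=config,
        meta=meta or {},
    )
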