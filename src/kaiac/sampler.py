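"""Affine-invariant ensemble MCMC and the heuristic fit procedure.

The sampler evolves an ensemble of walkers with the Goodman-Weare stretch
move: to update walker theta_k, a partner theta_j is drawn from the rest
of the ensemble and a move along the line through both is proposed,

    eta = theta_j + z * (theta_k - theta_j),

with z drawn from the stretch distribution on [1/alpha, alpha] and the
proposal accepted with probability min(1, z^(N-1) * p(eta)/p(theta_k)).
The default stretch density is g(z) proportional to 1/sqrt(z), the form
for which the z^(N-1) acceptance factor makes the move reversible (and the
form implemented by the reference ensemble samplers); a 1/z variant is
available behind a flag for comparison, since both forms appear in the
literature.

Tempering raises only the likelihood to the power beta; the prior is never
flattened.  The fit procedure wraps the sampler in a genetic-algorithm-like
loop: draw walkers from the prior, anneal through an increasing beta
ladder, locally optimize a stratified selection of the best sampled points
with Powell's method, reseed the ensemble around the optima, sample at
beta = 1, and terminate when sampling stops escaping to better local
maxima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

DEFAULT_ALPHA = 1.1


# --- stretch move ----------------------------------------------------------

def draw_z(alpha: float, rng: np.random.Generator, dist: str = "sqrt") -> float:
    """Draw a stretch factor z on [1/alpha, alpha].

    dist='sqrt': g(z) ~ 1/sqrt(z) (default, Goodman-Weare form);
    dist='inv' : g(z) ~ 1/z.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    u = rng.random()
    if dist == "sqrt":
        sa = math.sqrt(alpha)
        return ((sa - 1.0 / sa) * u + 1.0 / sa) ** 2
    if dist == "inv":
        return alpha ** (2.0 * u - 1.0)
    raise ValueError(f"unknown stretch density {dist!r}")


def stretch_move(
    theta_k: np.ndarray,
    theta_j: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    dist: str = "sqrt",
) -> tuple[np.ndarray, float]:
    """Propose eta = theta_j + z (theta_k - theta_j); returns (eta, z)."""
    z = draw_z(alpha, rng, dist)
    return theta_j + z * (np.asarray(theta_k) - np.asarray(theta_j)), z


def accept(
    z: float,
    n_dims: int,
    logpost_new: float,
    logpost_old: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis test with the stretch-move volume factor z^(N-1)."""
    if not math.isfinite(logpost_old):
        raise ValueError("current walker must have finite log-posterior")
    if not math.isfinite(logpost_new):
        return False
    ln_q = (n_dims - 1) * math.log(z) + logpost_new - logpost_old
    return ln_q >= 0 or rng.random() < math.exp(ln_q)


# --- ensemble --------------------------------------------------------------

def _as_components(fn):
    """Accept either fn(theta)->(loglike, logprior) or fn(theta)->float."""

    def wrapped(theta):
        out = fn(theta)
        if isinstance(out, tuple):
            return out
        return float(out), 0.0

    return wrapped


@dataclass
class WalkerEnsemble:
    """Positions and cached log-likelihood / log-prior of every walker."""

    positions: np.ndarray  # (n_walkers, n_dims)
    loglike: np.ndarray
    logprior: np.ndarray
    rng: np.random.Generator
    step_counter: int = 0

    @property
    def n_walkers(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dims(self) -> int:
        return self.positions.shape[1]

    def log_posterior(self, beta: float = 1.0) -> np.ndarray:
        return beta * self.loglike + self.logprior

    @classmethod
    def from_positions(cls, positions, log_prob_fn, rng) -> "WalkerEnsemble":
        fn = _as_components(log_prob_fn)
        positions = np.atleast_2d(np.asarray(positions, float))
        ll = np.empty(len(positions))
        lp = np.empty(len(positions))
        for i, th in enumerate(positions):
            ll[i], lp[i] = fn(th)
        return cls(positions=positions.copy(), loglike=ll, logprior=lp, rng=rng)


@dataclass
class ChainRecord:
    """Thinned chain: (n_records, n_walkers, n_dims) plus log components."""

    positions: np.ndarray
    loglike: np.ndarray
    logprior: np.ndarray

    def flat(self) -> np.ndarray:
        return self.positions.reshape(-1, self.positions.shape[-1])

    def flat_logpost(self, beta: float = 1.0) -> np.ndarray:
        return (beta * self.loglike + self.logprior).reshape(-1)


def run_ensemble(
    log_prob_fn,
    ensemble: WalkerEnsemble,
    n_steps: int,
    alpha: float = DEFAULT_ALPHA,
    beta: float = 1.0,
    thin: int = 1,
    dist: str = "sqrt",
) -> tuple[WalkerEnsemble, ChainRecord]:
    """Run the stretch-move sampler on the tempered target L^beta * prior.

    Walkers are updated sequentially; partners are drawn uniformly from
    the rest of the current ensemble.  Returns the evolved ensemble and
    the thinned chain (one record every `thin` steps).
    """
    fn = _as_components(log_prob_fn)
    if ensemble.n_walkers < 2:
        raise ValueError("need at least two walkers")
    if not np.all(np.isfinite(ensemble.log_posterior(beta))):
        raise ValueError("all initial walkers must have finite log-posterior")
    if np.allclose(np.ptp(ensemble.positions, axis=0), 0.0):
        raise ValueError("degenerate ensemble: all walkers identical")

    n, d = ensemble.positions.shape
    rng = ensemble.rng
    pos = ensemble.positions
    ll, lp = ensemble.loglike, ensemble.logprior
    rec_pos, rec_ll, rec_lp = [], [], []
    accepted = 0
    for step in range(n_steps):
        for k in range(n):
            j = rng.integers(n - 1)
            if j >= k:
                j += 1
            eta, z = stretch_move(pos[k], pos[j], alpha, rng, dist)
            ll_new, lp_new = fn(eta)
            new = beta * ll_new + lp_new
            old = beta * ll[k] + lp[k]
            if accept(z, d, new, old, rng):
                pos[k] = eta
                ll[k], lp[k] = ll_new, lp_new
                accepted += 1
        ensemble.step_counter += 1
        if (step + 1) % thin == 0:
            rec_pos.append(pos.copy())
            rec_ll.append(ll.copy())
            rec_lp.append(lp.copy())
    ensemble.acceptance_fraction = accepted / max(1, n_steps * n)
    chain = ChainRecord(
        positions=np.array(rec_pos) if rec_pos else np.empty((0, n, d)),
        loglike=np.array(rec_ll) if rec_ll else np.empty((0, n)),
        logprior=np.array(rec_lp) if rec_lp else np.empty((0, n)),
    )
    return ensemble, chain


# --- local optimization ----------------------------------------------------

def local_optimize(
    log_prob_fn,
    start: np.ndarray,
    method: str = "Powell",
    maxiter: int | None = None,
    xtol: float = 1e-6,
    ftol: float = 1e-6,
):
    """Derivative-free maximization of the log-posterior from `start`.

    Uses Powell's method (modified line-search version) by default,
    Nelder-Mead as the alternative.  The returned point never has a lower
    log-posterior than the start.
    """
    fn = _as_components(log_prob_fn)
    start = np.asarray(start, float)
    f0 = sum(fn(start))
    if not math.isfinite(f0):
        raise ValueError("start point has non-finite log-posterior")

    def neg(theta):
        v = sum(fn(theta))
        return -v if math.isfinite(v) else 1e300

    options = {"xtol": xtol, "ftol": ftol} if method == "Powell" else {
        "xatol": xtol, "fatol": ftol}
    if maxiter is not None:
        options["maxiter"] = maxiter
    res = minimize(neg, start, method=method, options=options)
    if -res.fun >= f0:
        return res.x, -res.fun
    return start, f0


# --- fit procedure ---------------------------------------------------------

@dataclass
class AnnealSchedule:
    betas: tuple = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    steps_per_beta: int = 20_000

    def __post_init__(self):
        b = np.asarray(self.betas)
        if not (np.all(np.diff(b) > 0) and b[-1] == 1.0):
            raise ValueError("betas must increase strictly and end at 1.0")


@dataclass
class FitConfig:
    """Counts and tolerances of the four-step fit heuristic.

    Defaults are the full-scale settings (224 walkers, 8 x 20,000 anneal
    steps, 50,000-step sampling runs); `test_scale` returns a profile with
    all chain lengths cut by two orders of magnitude for test-size
    problems.
    """

    n_walkers: int = 224
    anneal: AnnealSchedule = field(default_factory=AnnealSchedule)
    sample_steps: int = 50_000
    extra_steps: int = 50_000
    alpha: float = DEFAULT_ALPHA
    n_select: int = 10
    pool_size: int = 300
    reseed_sigma: float = 0.001
    reseed_beta: float = 0.6
    improvement_tol: float = 1.0  # nats
    max_generations: int = 10
    thin: int = 100
    keep_last: int = 30_000
    optimizer_maxiter: int | None = None

    @classmethod
    def test_scale(cls, n_walkers: int = 16) -> "FitConfig":
        return cls(
            n_walkers=n_walkers,
            anneal=AnnealSchedule(steps_per_beta=50),
            sample_steps=200,
            extra_steps=200,
            n_select=4,
            pool_size=40,
            max_generations=3,
            thin=2,
            keep_last=120,
            optimizer_maxiter=4,
        )


def allocate_walkers(logposts: np.ndarray, n_total: int, beta: float) -> np.ndarray:
    """Number of reseeded walkers per optimized point, proportional to the
    tempered posterior weight p_j^beta (largest-remainder rounding; every
    point receives at least one walker)."""
    lw = beta * (np.asarray(logposts) - np.max(logposts))
    w = np.exp(lw)
    w /= w.sum()
    raw = w * n_total
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > n_total:
        counts[np.argmax(counts)] -= 1
    rem = raw - np.floor(raw)
    while counts.sum() < n_total:
        i = int(np.argmax(rem))
        counts[i] += 1
        rem[i] = -1
    return counts


def _select_stratified(pool_pos, pool_lp, n_select, pool_size):
    """Rank the pooled samples, de-duplicate, keep the best `pool_size`,
    and pick `n_select` by stratified rank (best plus evenly spread)."""
    order = np.argsort(pool_lp)[::-1]
    seen = set()
    top_idx = []
    for i in order:
        key = pool_pos[i].tobytes()
        if key not in seen:
            seen.add(key)
            top_idx.append(i)
        if len(top_idx) >= pool_size:
            break
    top_idx = np.asarray(top_idx)
    k = min(n_select, len(top_idx))
    picks = np.unique(np.round(np.linspace(0, len(top_idx) - 1, k)).astype(int))
    return pool_pos[top_idx[picks]], pool_lp[top_idx[picks]]


@dataclass
class FitResult:
    best_vector: np.ndarray
    best_logpost: float
    chain: ChainRecord
    ensemble: WalkerEnsemble
    generations: int
    converged: bool
    acceptance_fraction: float


def fit_procedure(
    log_prob_fn,
    prior_sampler,
    config: FitConfig,
    rng: np.random.Generator,
) -> FitResult:
    """Initialization -> annealing -> selection/optimization -> reseeded
    sampling -> termination, looping while sampling finds better maxima.

    `log_prob_fn(theta) -> (loglike, logprior)`; `prior_sampler(rng) ->
    theta` draws one coordinate vector from the prior.
    """
    fn = _as_components(log_prob_fn)

    # 1. initialization: walkers from the prior with finite posterior
    pos, ll, lp = [], [], []
    attempts = 0
    while len(pos) < config.n_walkers:
        th = prior_sampler(rng)
        l, p = fn(th)
        attempts += 1
        if math.isfinite(l + p):
            pos.append(th)
            ll.append(l)
            lp.append(p)
        if attempts > 200 * config.n_walkers:
            raise RuntimeError("could not initialize walkers with finite posterior")
    ens = WalkerEnsemble(np.array(pos), np.array(ll), np.array(lp), rng)

    # 2. simulated annealing over the beta ladder, pooling all samples
    pool_pos, pool_lp = [], []
    for beta in config.anneal.betas:
        ens, chain = run_ensemble(
            fn, ens, config.anneal.steps_per_beta, config.alpha, beta, thin=1
        )
        pool_pos.append(chain.flat())
        pool_lp.append(chain.flat_logpost(beta=1.0))  # rank by the true posterior
    pool_pos = np.concatenate(pool_pos)
    pool_lp = np.concatenate(pool_lp)

    best_vec, best_lp = None, -math.inf
    chain = None
    converged = False
    generations = 0
    for generations in range(1, config.max_generations + 1):
        # 3. selection + local optimization
        sel_pos, _ = _select_stratified(
            pool_pos, pool_lp, config.n_select, config.pool_size
        )
        opt_pos, opt_lp = [], []
        for th in sel_pos:
            x, f = local_optimize(fn, th, maxiter=config.optimizer_maxiter)
            opt_pos.append(x)
            opt_lp.append(f)
        opt_pos, opt_lp = np.array(opt_pos), np.array(opt_lp)
        i_best = int(np.argmax(opt_lp))
        if opt_lp[i_best] > best_lp:
            best_vec, best_lp = opt_pos[i_best].copy(), float(opt_lp[i_best])

        # 4. reseed: Gaussian noise around the optimized walkers; the best
        # optimized walker is always retained verbatim (elitism)
        counts = allocate_walkers(opt_lp, config.n_walkers, config.reseed_beta)
        seeds, sll, slp = [], [], []
        for j, c in enumerate(counts):
            for m in range(c):
                th = opt_pos[j].copy()
                if not (j == i_best and m == 0):
                    th = th + rng.normal(0.0, config.reseed_sigma, size=th.shape)
                l, p = fn(th)
                if not math.isfinite(l + p):
                    th, (l, p) = opt_pos[j].copy(), fn(opt_pos[j])
                seeds.append(th)
                sll.append(l)
                slp.append(p)
        ens = WalkerEnsemble(np.array(seeds), np.array(sll), np.array(slp), rng)

        # 5. sampling run at beta = 1
        ens, chain = run_ensemble(
            fn, ens, config.sample_steps, config.alpha, 1.0, thin=config.thin
        )
        sampled_best = float(chain.flat_logpost().max()) if chain.positions.size else -math.inf

        if sampled_best <= best_lp + config.improvement_tol:
            # terminate after an additional sampling stretch
            ens, extra = run_ensemble(
                fn, ens, config.extra_steps, config.alpha, 1.0, thin=config.thin
            )
            chain = ChainRecord(
                positions=np.concatenate([chain.positions, extra.positions]),
                loglike=np.concatenate([chain.loglike, extra.loglike]),
                logprior=np.concatenate([chain.logprior, extra.logprior]),
            )
            converged = True
            break
        pool_pos = chain.flat()
        pool_lp = chain.flat_logpost()

    # keep only the tail used for post-analysis
    keep = max(1, config.keep_last // config.thin)
    chain = ChainRecord(
        positions=chain.positions[-keep:],
        loglike=chain.loglike[-keep:],
        logprior=chain.logprior[-keep:],
    )
    flat_lp = chain.flat_logpost()
    if flat_lp.size and flat_lp.max() > best_lp:
        i = int(np.argmax(flat_lp))
        best_vec = chain.flat()[i].copy()
        best_lp = float(flat_lp[i])
    return FitResult(
        best_vector=best_vec,
        best_logpost=best_lp,
        chain=chain,
        ensemble=ens,
        generations=generations,
        converged=converged,
        acceptance_fraction=getattr(ens, "acceptance_fraction", float("nan")),
    )
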