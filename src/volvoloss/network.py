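"""Discrete gene-regulatory-network model of gene deletion and duplication.

Implements a Wagner-type Boolean threshold network: ``N`` genes with states in
{-1, +1} (0 reserved for deleted genes) updated synchronously by

    S_i(t+1) = sigma( sum_j w_ij S_j(t) )

where ``w`` is an ``N x N`` real interaction matrix and ``sigma`` is the sign
function (``sigma(0) = +1`` by convention).  Phenotypes are stable fixed
points; trajectories that fail to reach a fixed point within ``max_iters``
synchronous updates (limit cycles) are treated as non-viable.

The module supports the full perturbation experiment: sample viable network
sets ``(S(0), w, S_eq)`` by rejection, delete or duplicate ``k`` genes, relax
the perturbed network to its new equilibrium, and score whether the new
equilibrium is a *novel stable state* — for deletion, Hamming distance
``d_h(S_eq_perturbed, S_eq) > k`` (the ``k`` zeroed positions always differ,
so novelty requires change among the surviving genes); for duplication,
``d_h > 0`` restricted to the original ``N`` genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RegulatoryNetwork",
    "ViableNetworkSet",
    "EnsembleResult",
    "SimulationConfig",
    "FixedPointResult",
    "NoViableNetworkError",
    "sign_threshold",
    "sample_state",
    "sample_network",
    "sample_modular_adjacency",
    "update_state",
    "find_fixed_point",
    "sample_viable_network",
    "delete_genes",
    "duplicate_genes",
    "hamming",
    "run_ensemble",
    "connectivity_sweep",
]


class NoViableNetworkError(RuntimeError):
    """Raised when rejection sampling exhausts its attempt budget.

    Carries ``attempts_used`` so callers can account for the failed draws.
    """

    def __init__(self, attempts_used: int):
        self.attempts_used = attempts_used
        super().__init__(
            f"no viable network found after {attempts_used} attempts"
        )


@dataclass
class RegulatoryNetwork:
    """Square interaction-weight matrix with its nominal connectivity ``c``."""

    weights: np.ndarray
    connectivity: float = 1.0
    topology: str = "dense"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not 0.0 < self.connectivity <= 1.0:
            raise ValueError("connectivity must be in (0, 1]")

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]


@dataclass
class ViableNetworkSet:
    """An accepted triple (initial state, network, equilibrium)."""

    initial: np.ndarray
    network: RegulatoryNetwork
    equilibrium: np.ndarray
    attempts_used: int = 1


@dataclass
class FixedPointResult:
    converged: bool
    equilibrium: np.ndarray | None
    steps: int


@dataclass
class EnsembleResult:
    """Outcome of one ensemble of perturbation trials at a single ``k``."""

    mode: str
    k: int
    connectivity: float
    trials: int
    proportion_novel_stable: float
    variance: float
    n_nonconverged: int
    seed: int
    n_rejected_networks: int = 0

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "k": self.k,
            "c": self.connectivity,
            "trials": self.trials,
            "proportion_novel_stable": self.proportion_novel_stable,
            "variance": self.variance,
            "n_nonconverged": self.n_nonconverged,
            "seed": self.seed,
        }


@dataclass
class SimulationConfig:
    """Parameters of the perturbation experiment.

    Defaults follow the published setup: networks of ``N = 10`` genes at full
    connectivity, ``k`` swept over 1..9, 1000 trials per ``k``, and 100
    synchronous updates allowed for convergence.
    """

    n_genes: int = 10
    connectivity: float = 1.0
    k_values: tuple[int, ...] = tuple(range(1, 10))
    trials_per_k: int = 1000
    max_iters: int = 100
    max_rejection_attempts: int = 10_000
    topology: str = "dense"
    module_count: int = 2
    module_overlap: float = 0.0
    deleted_state: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 < self.connectivity <= 1.0:
            raise ValueError("connectivity must be in (0, 1]")
        if self.trials_per_k < 1:
            raise ValueError("trials_per_k must be >= 1")
        if self.topology not in ("dense", "modular"):
            raise ValueError("topology must be 'dense' or 'modular'")
        if self.deleted_state not in (0, -1):
            raise ValueError("deleted_state must be 0 or -1")
        for k in self.k_values:
            if not 1 <= k < self.n_genes:
                raise ValueError("each k must satisfy 1 <= k < n_genes")


# ---------------------------------------------------------------------------
# elementary operations


def sign_threshold(x: float) -> int:
    """Sign function with the tie convention sigma(0) = +1."""
    if not math.isfinite(x):
        raise ValueError("sign_threshold requires a finite input")
    return -1 if x < 0 else 1


def sample_state(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a random expression state: each gene on/off with probability 1/2."""
    if n < 1:
        raise ValueError("state length must be >= 1")
    return rng.choice(np.array([-1, 1], dtype=np.int8), size=n)


def sample_modular_adjacency(
    n: int,
    module_count: int,
    overlap: float = 0.0,
    rng: np.random.Generator | None = None,
    p_in: float = 0.8,
    p_out: float = 0.05,
) -> np.ndarray:
    """Binary adjacency with block (module) structure.

    Genes are split into ``module_count`` near-equal contiguous modules; with
    probability ``overlap`` a gene additionally joins one other module.  An
    edge i->j is present with probability ``p_in`` when i and j share a module
    and ``p_out`` otherwise.  Symmetry is not imposed.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 1 <= module_count <= n:
        raise ValueError("module_count must be in [1, n]")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    membership = np.zeros((n, module_count), dtype=bool)
    for m, block in enumerate(np.array_split(np.arange(n), module_count)):
        membership[block, m] = True
    if module_count > 1 and overlap > 0:
        extra = rng.random(n) < overlap
        for g in np.nonzero(extra)[0]:
            others = [m for m in range(module_count) if not membership[g, m]]
            membership[g, rng.integers(len(others))] = True
    shared = membership @ membership.T > 0
    p = np.where(shared, p_in, p_out)
    return (rng.random((n, n)) < p).astype(np.int8)


def sample_network(
    n: int,
    c: float = 1.0,
    topology: str = "dense",
    rng: np.random.Generator | None = None,
    exact_count: bool = False,
    module_count: int = 2,
    overlap: float = 0.0,
) -> RegulatoryNetwork:
    """Draw a random interaction matrix with standard-normal nonzero weights.

    ``dense`` topology: each entry is nonzero independently with probability
    ``c`` (``exact_count=True`` instead places exactly ``round(c * n * n)``
    nonzero entries).  ``modular`` topology: the sparsity pattern comes from
    :func:`sample_modular_adjacency` scaled entrywise by N(0, 1) weights.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0.0 < c <= 1.0:
        raise ValueError("connectivity c must be in (0, 1]")
    weights = rng.standard_normal((n, n))
    if topology == "dense":
        if c < 1.0:
            if exact_count:
                mask = np.zeros(n * n, dtype=bool)
                k = int(round(c * n * n))
                mask[rng.choice(n * n, size=k, replace=False)] = True
                weights = weights * mask.reshape(n, n)
            else:
                weights = weights * (rng.random((n, n)) < c)
    elif topology == "modular":
        adj = sample_modular_adjacency(n, module_count, overlap, rng)
        weights = weights * adj
    else:
        raise ValueError("topology must be 'dense' or 'modular'")
    return RegulatoryNetwork(weights, connectivity=c, topology=topology)


def _as_weights(network) -> np.ndarray:
    if isinstance(network, RegulatoryNetwork):
        return network.weights
    return np.asarray(network, dtype=float)


def update_state(
    state: np.ndarray,
    network,
    deleted: np.ndarray | None = None,
) -> np.ndarray:
    """One synchronous update: S_i <- sigma(sum_j w_ij S_j).

    ``deleted`` marks frozen genes (zeroed rows/columns): they keep their
    current value and are excluded from the threshold update.
    """
    w = _as_weights(network)
    s = np.asarray(state)
    if s.shape[0] != w.shape[0]:
        raise ValueError("state length does not match network size")
    h = w @ s.astype(float)
    nxt = np.where(h < 0, -1, 1).astype(np.int8)
    if deleted is not None:
        nxt = np.where(deleted, s, nxt)
    return nxt


def find_fixed_point(
    initial: np.ndarray,
    network,
    max_iters: int = 100,
    deleted: np.ndarray | None = None,
) -> FixedPointResult:
    """Iterate the synchronous update until a fixed point or ``max_iters``.

    Convergence is declared at the first t with S(t+1) = S(t); the returned
    ``steps`` is that t.  Limit cycles exhaust the budget and return
    ``converged=False`` (such trajectories are treated as non-viable).
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    cur = np.asarray(initial, dtype=np.int8)
    for t in range(max_iters):
        nxt = update_state(cur, network, deleted=deleted)
        if np.array_equal(nxt, cur):
            return FixedPointResult(True, cur, t)
        cur = nxt
    return FixedPointResult(False, None, max_iters)


def sample_viable_network(
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ViableNetworkSet:
    """Rejection-sample a viable network set (S(0), w, S_eq).

    S(0) and S_eq are drawn once, uniformly; candidate matrices ``w`` are
    redrawn until the trajectory from S(0) reaches a fixed point exactly equal
    to S_eq within ``max_iters`` updates.  Raises
    :class:`NoViableNetworkError` after ``max_rejection_attempts`` draws —
    some (S(0), S_eq) targets are unreachable (e.g. N = 1 with
    S(0) = +1, S_eq = -1).
    """
    s0 = sample_state(config.n_genes, rng)
    seq = sample_state(config.n_genes, rng)
    for attempt in range(1, config.max_rejection_attempts + 1):
        net = sample_network(
            config.n_genes,
            config.connectivity,
            topology=config.topology,
            rng=rng,
            module_count=config.module_count,
            overlap=config.module_overlap,
        )
        res = find_fixed_point(s0, net, config.max_iters)
        if res.converged and np.array_equal(res.equilibrium, seq):
            return ViableNetworkSet(s0, net, seq, attempts_used=attempt)
    raise NoViableNetworkError(config.max_rejection_attempts)


def delete_genes(
    viable: ViableNetworkSet,
    k: int,
    rng: np.random.Generator,
    deleted_state: int = 0,
) -> tuple[np.ndarray, RegulatoryNetwork, np.ndarray]:
    """Delete ``k`` uniformly chosen genes from a viable network set.

    The deleted genes' rows and columns of ``w`` are zeroed and their entries
    in the initial state set to ``deleted_state`` (0 by default; the frozen
    value only affects Hamming bookkeeping because the zeroed columns remove
    all influence on other genes).  Returns
    ``(perturbed_initial, perturbed_network, deleted_indices)``.
    """
    n = viable.network.n_genes
    if not 1 <= k <= n:
        raise ValueError("k must be in [1, N]")
    idx = rng.choice(n, size=k, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[idx] = False
    w = viable.network.weights.copy()
    w[idx, :] = 0.0
    w[:, idx] = 0.0
    s0 = viable.initial.copy()
    s0[idx] = deleted_state
    net = RegulatoryNetwork(
        w,
        connectivity=viable.network.connectivity,
        topology=viable.network.topology,
    )
    return s0, net, np.sort(idx)


def duplicate_genes(
    viable: ViableNetworkSet,
    k: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, RegulatoryNetwork, np.ndarray]:
    """Duplicate ``k`` distinct genes, appending indistinguishable copies.

    Each copy i' of gene i inherits i's input row and output column, with
    w_{i'i'} = w_{i'i} = w_{ii'} = w_{ii}; cross-terms among several copies
    replicate the originals' cross-terms, and S_{i'}(0) = S_i(0).  This is the
    principal-submatrix expansion w'[a, b] = w[source(a), source(b)] under the
    index map source = (1..N, duplicated indices).
    """
    n = viable.network.n_genes
    if not 1 <= k <= n:
        raise ValueError("k must be in [1, N]")
    idx = np.sort(rng.choice(n, size=k, replace=False))
    ext = np.concatenate([np.arange(n), idx])
    w = viable.network.weights[np.ix_(ext, ext)]
    s0 = viable.initial[ext]
    net = RegulatoryNetwork(
        w,
        connectivity=viable.network.connectivity,
        topology=viable.network.topology,
    )
    return s0, net, idx


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of positions at which two expression states differ.

    A 0-vs-nonzero position (deleted gene against an expressed one) counts as
    a difference.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("states must have equal length")
    return int(np.count_nonzero(a != b))


# ---------------------------------------------------------------------------
# vectorized ensemble engine
#
# Viability sampling is vectorized by a stratified equivalence. Two symmetries
# of the model — gauge conjugation w -> GwG with G = diag(g), g in {-1,+1}^N,
# which maps the trajectory of (S0, w) to (gS0, GwG) with states g*S(t), and
# simultaneous row/column permutation — leave the iid N(0,1) weight law
# invariant. Hence the probability Z(S0, S_eq) that a random w carries S0 to a
# prescribed fixed point S_eq depends only on m = hamming(S0, S_eq). The
# sequential scheme (draw S0, S_eq uniformly; redraw w until the trajectory
# hits S_eq) therefore induces: m ~ Binomial(N, 1/2), and, conditional on m,
# triples distributed exactly like converged free-running draws (S0, w,
# eq(S0, w)) conditioned on hamming(S0, eq) = m. The engine draws the
# per-trial m targets first, then fills each m-stratum from batched
# free-running draws — identical in law, ~2^N cheaper. Strata that stay
# unfilled past the per-trial rejection budget have their (S0, S_eq) pair
# redrawn (a new m), mirroring the stall rule of the sequential sampler.


def _batch_fixed_points(
    s0: np.ndarray,
    w: np.ndarray,
    max_iters: int,
    frozen: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-point search for a batch: s0 (B,N) int8, w (B,N,N) float."""
    batch = s0.shape[0]
    conv = np.zeros(batch, dtype=bool)
    eq = s0.copy()
    steps = np.full(batch, max_iters, dtype=np.int64)
    active = np.arange(batch)
    cur = s0.copy()
    for t in range(max_iters):
        h = np.einsum("bij,bj->bi", w[active], cur[active].astype(float))
        nxt = np.where(h < 0, -1, 1).astype(np.int8)
        if frozen is not None:
            nxt = np.where(frozen[active], cur[active], nxt)
        same = np.all(nxt == cur[active], axis=1)
        done = active[same]
        conv[done] = True
        eq[done] = cur[done]
        steps[done] = t
        cur[active[~same]] = nxt[~same]
        active = active[~same]
        if active.size == 0:
            break
    return conv, eq, steps


def _sample_viable_batch(
    config: SimulationConfig,
    n_needed: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Accumulate ``n_needed`` viable (S(0), w, S_eq) triples; returns
    (S0 (T,N), W (T,N,N), Seq (T,N), n_rejected).

    Exactly emulates per-trial rejection toward a uniformly drawn target
    equilibrium via the m-stratified equivalence described above.
    """
    n = config.n_genes
    demanded = np.bincount(rng.binomial(n, 0.5, size=n_needed), minlength=n + 1)
    strata: list[list] = [[] for _ in range(n + 1)]
    rejected = 0
    batch = max(256, min(8192, 4 * n_needed))
    draws_since_progress = 0
    while True:
        missing = np.array(
            [max(0, demanded[j] - len(strata[j])) for j in range(n + 1)]
        )
        if missing.sum() == 0:
            break
        if draws_since_progress > config.max_rejection_attempts:
            # outstanding targets are (practically) unreachable: redraw their
            # (S0, S_eq) pairs, i.e. re-assign their m
            n_redraw = int(missing.sum())
            demanded -= missing
            demanded += np.bincount(
                rng.binomial(n, 0.5, size=n_redraw), minlength=n + 1
            )
            draws_since_progress = 0
            continue
        s0 = rng.choice(np.array([-1, 1], dtype=np.int8), size=(batch, n))
        w = rng.standard_normal((batch, n, n))
        if config.topology == "dense":
            if config.connectivity < 1.0:
                w *= rng.random((batch, n, n)) < config.connectivity
        else:
            adj = np.stack(
                [
                    sample_modular_adjacency(
                        n, config.module_count, config.module_overlap, rng
                    )
                    for _ in range(batch)
                ]
            )
            w *= adj
        conv, eq, _ = _batch_fixed_points(s0, w, config.max_iters)
        rejected += int(np.count_nonzero(~conv))
        m_all = np.count_nonzero(s0 != eq, axis=1)
        progressed = False
        for i in np.nonzero(conv)[0]:
            j = m_all[i]
            if len(strata[j]) < demanded[j]:
                strata[j].append((s0[i], w[i], eq[i]))
                progressed = True
        draws_since_progress = 0 if progressed else draws_since_progress + batch
    triples = [t for j in range(n + 1) for t in strata[j][: demanded[j]]]
    # shuffle so trial order is exchangeable rather than sorted by m
    order = rng.permutation(len(triples))
    s0 = np.stack([triples[i][0] for i in order])
    w = np.stack([triples[i][1] for i in order])
    eq = np.stack([triples[i][2] for i in order])
    return s0, w, eq, rejected


def _choose_indices(rng, trials: int, n: int, k: int) -> np.ndarray:
    """(trials, k) matrix of distinct uniform gene indices per trial."""
    return np.argpartition(rng.random((trials, n)), k - 1, axis=1)[:, :k]


def _ensemble_at_k(
    config: SimulationConfig,
    mode: str,
    k: int,
    seed_seq: np.random.SeedSequence,
    return_trials: bool = False,
):
    rng = np.random.default_rng(seed_seq)
    trials = config.trials_per_k
    n = config.n_genes
    s0, w, eq, rejected = _sample_viable_batch(config, trials, rng)
    idx = _choose_indices(rng, trials, n, k)
    rows = np.arange(trials)[:, None]
    if mode == "deletion":
        wp = w.copy()
        frozen = np.zeros((trials, n), dtype=bool)
        frozen[rows, idx] = True
        wp[frozen[:, :, None] | frozen[:, None, :]] = 0.0
        s0p = s0.copy()
        s0p[frozen] = config.deleted_state
        conv, eqp, _ = _batch_fixed_points(s0p, wp, config.max_iters, frozen)
        d_h = np.count_nonzero(eqp != eq, axis=1)
        novel = conv & (d_h > k)
    elif mode == "duplication":
        ext = np.concatenate([np.tile(np.arange(n), (trials, 1)), idx], axis=1)
        wp = w[rows[:, :, None], ext[:, :, None], ext[:, None, :]]
        s0p = s0[rows, ext]
        conv, eqp, _ = _batch_fixed_points(s0p, wp, config.max_iters)
        d_h = np.count_nonzero(eqp[:, :n] != eq, axis=1)
        novel = conv & (d_h > 0)
    else:
        raise ValueError("mode must be 'deletion' or 'duplication'")
    indicator = novel.astype(float)
    result = EnsembleResult(
        mode=mode,
        k=k,
        connectivity=config.connectivity,
        trials=trials,
        proportion_novel_stable=float(indicator.mean()),
        variance=float(indicator.var(ddof=1)) if trials > 1 else 0.0,
        n_nonconverged=int(np.count_nonzero(~conv)),
        seed=config.seed,
        n_rejected_networks=rejected,
    )
    if return_trials:
        return result, {"converged": conv, "d_h": d_h, "novel": novel}
    return result


_MODE_CODE = {"deletion": 0, "duplication": 1}


def _substream(config: SimulationConfig, mode: str, k: int) -> np.random.SeedSequence:
    # keyed by (mode, k, connectivity) so k-sweeps and c-sweeps are
    # independently reproducible under one master seed
    c_key = int(round(config.connectivity * 10_000))
    return np.random.SeedSequence(
        config.seed, spawn_key=(_MODE_CODE[mode], k, c_key)
    )


def run_ensemble(
    config: SimulationConfig,
    mode: str,
    return_trials: bool = False,
) -> list[EnsembleResult]:
    """Run the perturbation experiment for every ``k`` in the config.

    Per trial: sample a viable network set, perturb it (deletion or
    duplication of ``k`` genes), relax to the perturbed equilibrium, and score
    novelty.  Non-converged perturbed trials count in the denominator and are
    reported via ``n_nonconverged``.
    """
    if mode not in _MODE_CODE:
        raise ValueError("mode must be 'deletion' or 'duplication'")
    out = []
    for k in config.k_values:
        out.append(
            _ensemble_at_k(config, mode, k, _substream(config, mode, k),
                           return_trials=return_trials)
        )
    return out


def connectivity_sweep(
    config: SimulationConfig,
    c_values: list[float],
    fixed_k: int,
) -> list[EnsembleResult]:
    """Run deletion ensembles at a fixed ``k`` across connectivity values."""
    out = []
    for c in c_values:
        if not 0.0 < c <= 1.0:
            raise ValueError("connectivity values must be in (0, 1]")
        cfg = replace(config, connectivity=c, k_values=(fixed_k,))
        out.extend(run_ensemble(cfg, "deletion"))
    return out
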