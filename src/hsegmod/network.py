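"""Adaptive-learning-rate backpropagation network (stage 2).

A one-hidden-layer network maps the scalar vertex parameter t in [0, 1] to
two outputs (g_x, g_y) in (-1, 1):

    h_i = sigmoid(t * omega_i - T_i),   i = 1..q
    g_k = tanh(sum_i h_i * a_{i,k} - b_k),   k = 1, 2

Training is full-batch gradient descent on the squared error between the
mapped outputs (1 + g)/2 and min-max-scaled vertex coordinates, with a
multiplicative learning-rate adaptation per epoch: the rate grows by alpha
when the error fell, shrinks by beta when it rose, and is otherwise kept.
The initial weights/thresholds come from an IAMCDE search over the flat
(4q + 2)-dimensional parameter vector, which is what makes the final
closed-form contour expression both smooth and reachable by backprop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ccps import VertexSequence
from .de import DEConfig, minimize

__all__ = [
    "ABPNNParams",
    "TrainConfig",
    "TrainingTrace",
    "forward",
    "sse",
    "backprop_epoch",
    "adapt_learning_rate",
    "flatten",
    "unflatten",
    "train",
]

ETA_CAP = 10.0
ETA_FLOOR = 1e-8


@dataclass(frozen=True)
class ABPNNParams:
    """Network weights and thresholds.

    omega: (q,) input->hidden weights; T: (q,) hidden thresholds;
    A: (q, 2) hidden->output weights; b: (2,) output thresholds.
    The flat vector has length 4q + 2.
    """

    omega: np.ndarray
    T: np.ndarray
    A: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        T = np.asarray(self.T, dtype=float)
        A = np.asarray(self.A, dtype=float)
        b = np.asarray(self.b, dtype=float)
        q = omega.size
        if q < 1:
            raise ValueError("need at least one hidden neuron")
        if T.shape != (q,) or A.shape != (q, 2) or b.shape != (2,):
            raise ValueError("inconsistent parameter shapes")
        for arr in (omega, T, A, b):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)

    @property
    def q(self) -> int:
        return self.omega.size


@dataclass(frozen=True)
class TrainConfig:
    """Training settings: hidden width q, epoch count, initial learning
    rate eta0, adaptation factors alpha (growth) and beta_lr (decay), and
    the DE configuration for the initialization search."""

    q: int = 10
    epochs: int = 20000
    eta0: float = 0.5
    alpha: float = 1.5
    beta_lr: float = 0.5
    de_config: DEConfig = field(
        default_factory=lambda: DEConfig(S=50, GMax=500)
    )
    n_restarts: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 < self.alpha < 2:
            raise ValueError("alpha must lie in (1, 2)")
        if not 0 < self.beta_lr < 1:
            raise ValueError("beta_lr must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class TrainingTrace:
    """Winning run's record: ``errors[k]`` is the error of epoch k's
    proposed step, ``etas[k]`` the rate that produced it.  The rate trace
    replays exactly: eta_0 = eta0 and
    eta_{k+1} = adapt_learning_rate(eta_k, errors[k], errors[k-1])
    with errors[-1] read as ``init_fitness``."""

    errors: np.ndarray
    etas: np.ndarray
    init_fitness: float  # best IAMCDE fitness (error of the initial params)
    best_epoch: int
    final_error: float


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def forward(params: ABPNNParams, t) -> np.ndarray:
    """Evaluate the network; t may be a scalar or a 1-D array.

    Returns shape (2,) for a scalar t, else (len(t), 2); outputs lie
    strictly inside (-1, 1).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    z = t_arr[:, None] * params.omega[None, :] - params.T[None, :]
    h = _sigmoid(z)
    g = np.tanh(h @ params.A - params.b[None, :])
    return g[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else g


def flatten(params: ABPNNParams) -> np.ndarray:
    """Pack parameters as [omega, T, A[:,0], A[:,1], b]."""
    return np.concatenate(
        [params.omega, params.T, params.A[:, 0], params.A[:, 1], params.b]
    )


def unflatten(vector: np.ndarray, q: int) -> ABPNNParams:
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (4 * q + 2,):
        raise ValueError(f"expected length {4 * q + 2}, got {vector.shape}")
    omega = vector[:q]
    T = vector[q : 2 * q]
    A = np.column_stack([vector[2 * q : 3 * q], vector[3 * q : 4 * q]])
    b = vector[4 * q :]
    return ABPNNParams(omega, T, A, b)


def _targets(seq: VertexSequence, scaler) -> np.ndarray:
    return scaler.scale(seq.xy)


def sse(params: ABPNNParams, seq: VertexSequence, scaler) -> float:
    """Sum of squared errors between the mapped network outputs and the
    scaled sequence coordinates, over all entries and both axes."""
    g = forward(params, seq.t)
    mapped = 0.5 * (1.0 + g)
    err = mapped - _targets(seq, scaler)
    return float(np.sum(err * err))


def backprop_epoch(
    params: ABPNNParams, seq: VertexSequence, scaler, eta: float
) -> tuple[ABPNNParams, float]:
    """One full-batch gradient step; returns the new parameters and the
    *pre-step* error."""
    if eta <= 0:
        raise ValueError("learning rate must be positive")
    t = seq.t
    y = _targets(seq, scaler)
    z = t[:, None] * params.omega[None, :] - params.T[None, :]  # (n, q)
    h = _sigmoid(z)
    u = h @ params.A - params.b[None, :]  # (n, 2)
    g = np.tanh(u)
    mapped = 0.5 * (1.0 + g)
    err = mapped - y
    E = float(np.sum(err * err))

    # dE/du_k = 2*err * d(mapped)/dg * dg/du = err * (1 - g^2)
    d_u = err * (1.0 - g * g)  # (n, 2)
    grad_A = h.T @ d_u  # (q, 2)
    grad_b = -d_u.sum(axis=0)  # (2,)
    d_h = d_u @ params.A.T  # (n, q)
    d_z = d_h * h * (1.0 - h)  # (n, q)
    grad_omega = (d_z * t[:, None]).sum(axis=0)
    grad_T = -d_z.sum(axis=0)

    for grad in (grad_A, grad_b, grad_omega, grad_T):
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite gradient")

    new = ABPNNParams(
        params.omega - eta * grad_omega,
        params.T - eta * grad_T,
        params.A - eta * grad_A,
        params.b - eta * grad_b,
    )
    return new, E


def adapt_learning_rate(
    eta_prev: float, E_k: float, E_prev: float, alpha: float, beta_lr: float
) -> float:
    """Multiplicative learning-rate adaptation: grow on error decrease,
    shrink on increase, keep on a tie; clamped to [1e-8, 10] to avoid
    overflow/underflow under repeated multiplication."""
    if eta_prev <= 0:
        raise ValueError("eta_prev must be positive")
    if E_k < E_prev:
        eta = alpha * eta_prev
    elif E_k > E_prev:
        eta = beta_lr * eta_prev
    else:
        eta = eta_prev
    return float(min(max(eta, ETA_FLOOR), ETA_CAP))


def train(
    seq: VertexSequence,
    config: TrainConfig | None = None,
    rng: np.random.Generator | int | None = None,
    scaler=None,
) -> tuple[ABPNNParams, TrainingTrace]:
    """Two-phase training with independent restarts.

    Each restart runs phase 1 — IAMCDE minimizing the sum of squared errors
    over the flat (4q + 2)-vector within the DE search box — followed by
    phase 2, ``epochs`` epochs of full-batch backprop with the adaptive
    learning rate.  The objective is multimodal, so ``n_restarts``
    independent runs are taken and the one with the lowest final error wins.
    Within a run the best parameter snapshot (including the phase-1 result)
    is kept, so the final error never exceeds the initialization error.
    Deterministic for a fixed seed.
    """
    config = config or TrainConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if scaler is None:
        from .contour import CoordinateScaler

        scaler = CoordinateScaler.from_sequence(seq)

    best: tuple[ABPNNParams, TrainingTrace] | None = None
    for _ in range(config.n_restarts):
        params, trace = _train_once(seq, config, rng, scaler)
        if best is None or trace.final_error < best[1].final_error:
            best = (params, trace)
    return best


def _train_once(
    seq: VertexSequence,
    config: TrainConfig,
    rng: np.random.Generator,
    scaler,
) -> tuple[ABPNNParams, TrainingTrace]:
    q = config.q
    dim = 4 * q + 2

    def objective(vec: np.ndarray) -> float:
        return sse(unflatten(vec, q), seq, scaler)

    de_config = config.de_config
    if np.isscalar(de_config.U_min) and np.isscalar(de_config.U_max) and (
        de_config.U_min, de_config.U_max
    ) == (-1.0, 1.0):
        # Default search box, scaled to the natural parameter ranges: over a
        # unit parameter interval a sigmoid transition at position T/omega
        # with width ~1/omega needs |omega| up to about the number of
        # sequence entries, and |T| up to |omega|; the output layer works on
        # (0, 1) activations, so its weights and thresholds stay order 1.
        w_scale = float(seq.n_entries)
        lo = np.concatenate(
            [-w_scale * np.ones(2 * q), -np.ones(2 * q + 2)]
        )
        de_config = replace(de_config, U_min=lo, U_max=-lo)
    result = minimize(objective, dim, de_config, rng)
    params = unflatten(result.x, q)

    errors = np.empty(config.epochs)
    etas = np.empty(config.epochs)
    eta = config.eta0
    E_acc = result.fun  # error of the accepted (current) parameters
    E_prev = E_acc  # previous epoch's recorded (proposal) error
    best_params = params
    best_epoch = 0
    for k in range(config.epochs):
        proposal, _ = backprop_epoch(params, seq, scaler, eta)
        E_k = sse(proposal, seq, scaler)
        # a proposal is kept only when it improves on the accepted error;
        # the learning rate follows the error trend either way
        if E_k < E_acc:
            params = proposal
            E_acc = E_k
            best_params = proposal
            best_epoch = k + 1
        errors[k] = E_k
        etas[k] = eta
        eta = adapt_learning_rate(eta, E_k, E_prev, config.alpha, config.beta_lr)
        E_prev = E_k

    trace = TrainingTrace(errors, etas, result.fun, best_epoch, E_acc)
    return best_params, trace
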