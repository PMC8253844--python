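"""Backpropagation-through-time training under connectome constraints.

The network is unrolled over the full simulation horizon and the exact
gradient of the evaluation function

    E = (1/T) (1/U) sum_t sum_u (1/2) (y_u(t) - d_u(t))^2

is propagated through the coupled neuron/muscle recursion, including
the gap-junction difference currents, the shared neuron-muscle gap
matrix (which appears in both update equations), and the lag constants.
Gap conductances are tied symmetric parameters: the gradient of a pair
sums the contributions of both directions.  After every update the
parameters are projected back onto the feasible set — cholinergic
synaptic columns nonnegative, GABAergic nonpositive, conductances and
lag constants nonnegative, structurally absent entries exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .connectome import ConnectomeMask
from .dynamics import (CommandSchedule, ModelParameters, ModelState,
                       command_matrix, sigmoid)

GradientSet = dict


@dataclass
class TrainingConfig:
    """Hyper-parameters and initialization ranges for BPTT training.

    The initialization ranges are the model's standing conditions:
    excitatory synaptic entries U[0, 1], inhibitory U[-1, 0],
    muscle-to-neuron / command / bias entries U[-1, 1], gap conductances
    U[0, 1], lag constants U[0, 0.01].  Training stops when
    ``E <= tolerance`` (default 0.005) or after ``max_iterations``.
    """

    tolerance: float = 0.005
    max_iterations: int = 8000
    learning_rate: float = 0.05
    optimizer: str = "adam"          # "adam" | "gd"
    momentum: float = 0.9            # used by "gd"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    init_excitatory: tuple[float, float] = (0.0, 1.0)
    init_inhibitory: tuple[float, float] = (-1.0, 0.0)
    init_free: tuple[float, float] = (-1.0, 1.0)
    init_gap: tuple[float, float] = (0.0, 1.0)
    init_tau: tuple[float, float] = (0.0, 0.01)
    grad_clip_norm: float | None = 1.0   # global gradient-norm ceiling
    backtrack_factor: float = 1.3    # undo a step when E jumps by this much
    lr_shrink: float = 0.5           # step-size cut after a backtrack
    lr_grow: float = 1.02            # slow recovery toward learning_rate
    divergence_patience: int = 100   # consecutive iterations above guard
    divergence_factor: float = 5.0   # ... with E > factor * best E so far

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.optimizer not in ("adam", "gd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


class TrainingDivergence(RuntimeError):
    """Raised when the evaluation function blows up; carries the curve."""

    def __init__(self, message: str, learning_curve):
        super().__init__(message)
        self.learning_curve = np.asarray(learning_curve)


@dataclass
class TrainResult:
    """Outcome of one training trial."""

    params: ModelParameters
    mask: ConnectomeMask
    learning_curve: np.ndarray
    converged: bool
    residuals: dict = field(default_factory=dict)
    config: TrainingConfig | None = None

    @property
    def final_e(self) -> float:
        return float(self.learning_curve[-1])

    @property
    def iterations_used(self) -> int:
        return len(self.learning_curve) - 1


# ---------------------------------------------------------------------------
# Evaluation function
# ---------------------------------------------------------------------------

def evaluate(y_m_series: np.ndarray, teacher_d: np.ndarray) -> float:
    """Mean over steps and muscles of half the squared output error."""
    y = np.asarray(y_m_series, dtype=float)
    d = np.asarray(teacher_d, dtype=float)
    if y.shape != d.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {d.shape}")
    return float(0.5 * np.mean((y - d) ** 2))


# ---------------------------------------------------------------------------
# Unrolled forward pass
# ---------------------------------------------------------------------------

def _unroll(params: ModelParameters, schedule: CommandSchedule,
            x0: ModelState | None = None) -> dict:
    """Forward pass storing everything the backward pass needs.

    Neurons and muscles are stacked into one state vector of length
    J + M; the chemical weights form one block matrix W, the gap
    conductances one *symmetric* block matrix G (the shared
    neuron-muscle conductance appears in both off-diagonal blocks).
    The update then reads

        x(t+1) = A x(t) + B { W y(t) + G x(t) - (G 1) x(t) + cst(t) }

    with A, B the stacked lag factors and cst the command drive plus
    biases.  Returned arrays are indexed by state time t = 0..K.
    """
    imap = params.index_map
    J, M = imap.n_neurons, imap.n_muscles
    Z = J + M
    dt = params.fs
    K = round(schedule.total_time / dt)
    L = command_matrix(schedule, K, dt, imap.n_forward, imap.n_backward)

    p = params
    W = np.zeros((Z, Z))
    W[:J, :J] = p.w_nn; W[:J, J:] = p.w_mn; W[J:, :J] = p.w_nm
    G = np.zeros((Z, Z))
    G[:J, :J] = p.g_nn; G[:J, J:] = p.g_mn
    G[J:, :J] = p.g_mn.T; G[J:, J:] = p.g_mm
    s = G.sum(axis=1)
    tau = np.concatenate([p.tau_n, p.tau_m])
    A = 1.0 / (1.0 + p.fs * tau)
    B = 1.0 - A
    cst = np.empty((K, Z))
    cst[:, :J] = L @ p.w_in.T + p.bias_n
    cst[:, J:] = p.bias_m

    x = np.empty((K + 1, Z))
    y = np.empty((K + 1, Z))
    drive = np.empty((K, Z))
    if x0 is None:
        x[0] = 0.0
    else:
        x[0, :J], x[0, J:] = x0.x_n, x0.x_m
    y[0] = sigmoid(x[0])
    for t in range(K):
        drive[t] = W @ y[t] + G @ x[t] - s * x[t] + cst[t]
        x[t + 1] = A * x[t] + B * drive[t]
        y[t + 1] = sigmoid(x[t + 1])
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite currents during unrolled forward pass")
    return {"x": x, "y": y, "drive": drive, "L": L, "K": K, "J": J, "M": M,
            "W": W, "G": G, "s": s, "A": A, "B": B}


def forward_error(params: ModelParameters, schedule: CommandSchedule,
                  teacher_d: np.ndarray, x0: ModelState | None = None
                  ) -> tuple[float, dict]:
    """Run the unrolled forward pass and evaluate E against the teacher."""
    cache = _unroll(params, schedule, x0)
    return evaluate(cache["y"][1:, cache["J"]:], teacher_d), cache


# ---------------------------------------------------------------------------
# Exact BPTT gradients
# ---------------------------------------------------------------------------

def bptt_gradients(params: ModelParameters, schedule: CommandSchedule,
                   teacher_d: np.ndarray, x0: ModelState | None = None,
                   mask: ConnectomeMask | None = None,
                   cache: dict | None = None) -> tuple[GradientSet, float]:
    """Exact gradient of E through the full unrolled recursion.

    Returns a dict congruent to ``ModelParameters.ARRAY_FIELDS`` and the
    evaluation-function value.  Gap gradients are the tied-pair
    derivatives (both directions summed, stored symmetrically); entries
    outside the mask are exactly zero.
    """
    if cache is None:
        cache = _unroll(params, schedule, x0)
    x, y, drive = cache["x"], cache["y"], cache["drive"]
    L, K, J, M = cache["L"], cache["K"], cache["J"], cache["M"]
    W, G, s, A, B = (cache[k] for k in ("W", "G", "s", "A", "B"))
    d = np.asarray(teacher_d, dtype=float)
    if d.shape != (K, M):
        raise ValueError(f"teacher shape {d.shape} != outputs {(K, M)}")

    c = 1.0 / (K * M)
    E = evaluate(y[1:, J:], d)

    # adjoints lam = dE/dx at every recorded state (stacked neuron+muscle)
    lam = np.zeros((K + 1, J + M))
    sig = y * (1.0 - y)
    Wt = W.T
    for t in range(K, 0, -1):
        l = np.zeros(J + M)
        l[J:] = c * (y[t, J:] - d[t - 1]) * sig[t, J:]
        if t < K:
            mu = B * lam[t + 1]
            l += A * lam[t + 1] + G @ mu - s * mu + sig[t] * (Wt @ mu)
        lam[t] = l
    if not np.all(np.isfinite(lam)):
        raise FloatingPointError("non-finite adjoint during backward pass")

    # vectorized accumulation over the K transitions
    MU = B * lam[1:]                  # (K, Z), mu at t = 1..K
    Y0, X0 = y[:-1], x[:-1]           # states at t = 0..K-1

    gW = MU.T @ Y0
    g = {
        "w_nn": gW[:J, :J],
        "w_mn": gW[:J, J:],
        "w_nm": gW[J:, :J],
        "w_in": MU[:, :J].T @ L,
        "bias_n": MU[:, :J].sum(axis=0),
        "bias_m": MU[:, J:].sum(axis=0),
    }

    # gap junctions: raw[i, j] = sum_t mu_i(t) (x_j(t-1) - x_i(t-1));
    # tied symmetric parameters => gradient = raw + raw^T, whose blocks
    # give the neuron-neuron, muscle-muscle, and shared neuron-muscle
    # conductance gradients (the latter summing both equations' parts)
    raw = MU.T @ X0 - (MU * X0).sum(axis=0)[:, None]
    gG = raw + raw.T
    g["g_nn"] = gG[:J, :J]
    g["g_mm"] = gG[J:, J:]
    g["g_mn"] = gG[:J, J:]

    # lag constants: dx(t)/dtau = Fs/(1+Fs*tau)^2 (drive - x(t-1))
    gtau = (params.fs * A ** 2) * (lam[1:] * (drive - X0)).sum(axis=0)
    g["tau_n"] = gtau[:J]
    g["tau_m"] = gtau[J:]

    if mask is not None:
        g["w_nn"] *= mask.syn_nn
        g["w_nm"] *= mask.syn_nm
        g["w_mn"] *= mask.syn_mn
        g["w_in"] *= mask.syn_in
        g["g_nn"] *= mask.gap_nn
        g["g_mn"] *= mask.gap_mn
        g["g_mm"] *= mask.gap_mm
    return g, E


# ---------------------------------------------------------------------------
# Constraints and initialization
# ---------------------------------------------------------------------------

def project_constraints(params: ModelParameters, mask: ConnectomeMask,
                        copy: bool = True) -> ModelParameters:
    """Project parameters onto the feasible set.

    Clips synaptic columns to the presynaptic class sign (cholinergic
    >= 0, GABAergic <= 0), conductances and lag constants to >= 0,
    re-symmetrizes the gap matrices by averaging, and zeroes every entry
    outside the structural mask.  Idempotent.
    """
    p = params.copy() if copy else params
    exc = p.index_map.excitatory
    p.w_nn[:, exc] = np.maximum(p.w_nn[:, exc], 0.0)
    p.w_nn[:, ~exc] = np.minimum(p.w_nn[:, ~exc], 0.0)
    p.w_nm[:, exc] = np.maximum(p.w_nm[:, exc], 0.0)
    p.w_nm[:, ~exc] = np.minimum(p.w_nm[:, ~exc], 0.0)
    p.g_nn = np.maximum(0.5 * (p.g_nn + p.g_nn.T), 0.0)
    p.g_mm = np.maximum(0.5 * (p.g_mm + p.g_mm.T), 0.0)
    p.g_mn = np.maximum(p.g_mn, 0.0)
    p.tau_n = np.maximum(p.tau_n, 0.0)
    p.tau_m = np.maximum(p.tau_m, 0.0)
    p.w_nn *= mask.syn_nn
    p.w_nm *= mask.syn_nm
    p.w_mn *= mask.syn_mn
    p.w_in *= mask.syn_in
    p.g_nn *= mask.gap_nn
    p.g_mn *= mask.gap_mn
    p.g_mm *= mask.gap_mm
    return p


def initialize(mask: ConnectomeMask, config: TrainingConfig | None = None,
               seed: int | None = None) -> ModelParameters:
    """Draw initial parameters uniformly within the class-appropriate ranges.

    Only structurally allowed entries are drawn (the rest are exactly
    zero); gap matrices are drawn on the upper triangle and mirrored.
    Reproducible: the same seed gives identical parameters.
    """
    cfg = config or TrainingConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    imap = mask.index_map
    J, M, P = imap.n_neurons, imap.n_muscles, imap.n_commands
    p = ModelParameters.zeros(imap)
    exc = imap.excitatory

    def draw(shape, lo, hi):
        return rng.uniform(lo, hi, shape)

    for w, m in ((p.w_nn, mask.syn_nn), (p.w_nm, mask.syn_nm)):
        w[:] = draw(w.shape, *cfg.init_excitatory)
        w[:, ~exc] = draw((w.shape[0], int((~exc).sum())), *cfg.init_inhibitory)
        w *= m
    p.w_mn = draw((J, M), *cfg.init_free) * mask.syn_mn
    p.w_in = draw((J, P), *cfg.init_free) * mask.syn_in
    p.bias_n = draw(J, *cfg.init_free)
    p.bias_m = draw(M, *cfg.init_free)

    up = np.triu(draw((J, J), *cfg.init_gap), 1)
    p.g_nn = (up + up.T) * mask.gap_nn
    p.g_mn = draw((J, M), *cfg.init_gap) * mask.gap_mn
    up = np.triu(draw((M, M), *cfg.init_gap), 1)
    p.g_mm = (up + up.T) * mask.gap_mm
    p.tau_n = draw(J, *cfg.init_tau)
    p.tau_m = draw(M, *cfg.init_tau)
    return p


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

def _clip_gradients(grads: GradientSet, max_norm: float | None) -> GradientSet:
    """Scale the whole gradient down to a global L2 norm ceiling."""
    if max_norm is None:
        return grads
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        grads = {k: g * scale for k, g in grads.items()}
    return grads


class _Adam:
    def __init__(self, cfg: TrainingConfig):
        self.cfg = cfg
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: ModelParameters, grads: GradientSet,
             lr: float) -> None:
        c = self.cfg
        self.t += 1
        for name in ModelParameters.ARRAY_FIELDS:
            gr = grads[name]
            m = self.m.setdefault(name, np.zeros_like(gr))
            v = self.v.setdefault(name, np.zeros_like(gr))
            m += (1 - c.adam_beta1) * (gr - m)
            v += (1 - c.adam_beta2) * (gr * gr - v)
            mhat = m / (1 - c.adam_beta1 ** self.t)
            vhat = v / (1 - c.adam_beta2 ** self.t)
            arr = getattr(params, name)
            arr -= lr * mhat / (np.sqrt(vhat) + c.adam_eps)


class _Momentum:
    def __init__(self, cfg: TrainingConfig):
        self.cfg = cfg
        self.vel: dict = {}

    def step(self, params: ModelParameters, grads: GradientSet,
             lr: float) -> None:
        c = self.cfg
        for name in ModelParameters.ARRAY_FIELDS:
            gr = grads[name]
            v = self.vel.setdefault(name, np.zeros_like(gr))
            v *= c.momentum
            v -= lr * gr
            getattr(params, name)[:] += v


def _make_optimizer(cfg: TrainingConfig):
    return _Adam(cfg) if cfg.optimizer == "adam" else _Momentum(cfg)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(mask: ConnectomeMask, teacher, config: TrainingConfig | None = None,
          seed: int | None = None,
          verification_schedule: CommandSchedule | None = None,
          verification_teacher=None,
          x0: ModelState | None = None,
          callback: Callable[[int, float], None] | None = None,
          params0: ModelParameters | None = None) -> TrainResult:
    """Train the network on a teacher until E <= tolerance.

    ``teacher`` is a :class:`~wormmotor.teacher.TeacherData`; its
    schedule drives the command input.  Records the learning curve
    (entry 0 is the pre-training error) and, when a verification
    schedule (and matching teacher) is given, the post-training error
    under the untrained switching times.

    Raises :class:`TrainingDivergence` if E becomes non-finite or stays
    far above its running best for many consecutive iterations.
    """
    cfg = config or TrainingConfig()
    params = params0.copy() if params0 is not None else initialize(mask, cfg, seed)
    params = project_constraints(params, mask, copy=False)
    schedule = teacher.schedule
    opt = _make_optimizer(cfg)

    err, cache = forward_error(params, schedule, teacher.d, x0)
    curve = [err]
    best = err
    bad_streak = 0
    lr = cfg.learning_rate
    converged = err <= cfg.tolerance
    for it in range(cfg.max_iterations):
        if converged:
            break
        grads, _ = bptt_gradients(params, schedule, teacher.d, x0,
                                  mask=mask, cache=cache)
        grads = _clip_gradients(grads, cfg.grad_clip_norm)
        prev = params.copy()
        prev_err = err
        opt.step(params, grads, lr)
        project_constraints(params, mask, copy=False)
        try:
            err, cache = forward_error(params, schedule, teacher.d, x0)
            blown = not np.isfinite(err)
        except FloatingPointError:
            blown = True
        if blown or err > cfg.backtrack_factor * prev_err:
            # the step destabilized the dynamics: undo it, shrink the step
            params = prev
            err, cache = forward_error(params, schedule, teacher.d, x0)
            lr = max(lr * cfg.lr_shrink, 1e-6)
        else:
            lr = min(lr * cfg.lr_grow, cfg.learning_rate)
        curve.append(err)
        if callback is not None:
            callback(it + 1, err)
        if err <= cfg.tolerance:
            converged = True
        best = min(best, err)
        bad_streak = bad_streak + 1 if err > cfg.divergence_factor * best else 0
        if bad_streak >= cfg.divergence_patience:
            raise TrainingDivergence(
                f"E stayed above {cfg.divergence_factor} x best for "
                f"{bad_streak} iterations", curve)

    residuals = {"pre_training": curve[0], "post_training": curve[-1]}
    if verification_schedule is not None:
        if verification_teacher is None:
            from .teacher import analytic_teacher
            verification_teacher = analytic_teacher(
                verification_schedule, mask.index_map, omega=teacher.omega)
        v_err, _ = forward_error(params, verification_schedule,
                                 verification_teacher.d, x0)
        residuals["verification"] = v_err

    return TrainResult(params=params, mask=mask,
                       learning_curve=np.asarray(curve), converged=converged,
                       residuals=residuals, config=cfg)
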