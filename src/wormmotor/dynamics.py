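"""Discrete-time dynamics of the coupled motor-neuron/muscle network.

Each cell carries an input current ``x`` updated by a first-order lag
recursion and emits a sigmoidal output ``y = 1 / (1 + exp(-x))``.  For
motor neuron ``i`` with lag constant ``tau_i`` and step constant ``Fs``:

    x_i(t+1) = x_i(t) / (1 + Fs*tau_i)
             + (Fs*tau_i / (1 + Fs*tau_i)) * drive_i(t)

where the drive collects chemical-synaptic input from neurons and
muscles, gap-junction difference currents ``g_ij (x_j - x_i)``, the
binary command-neuron lines, and a bias.  Muscles follow the same
recursion with neuron-synaptic, neuron-gap and muscle-gap input.
Proprioceptive feedback is carried by the muscle→neuron weight matrix
(whose mask includes the feedback pairs), so it enters the neuron drive
through the ordinary muscle-to-neuron sum.

``Fs`` appears multiplicatively as ``Fs * tau`` in the lag factors and
doubles as the step duration (0.05 s) for time bookkeeping.  All cells
update synchronously from time-``t`` values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .connectome import (ConnectomeMask, DORSAL_ROWS, NeuronIndexMap,
                         VENTRAL_ROWS)

#: Step constant of the lag recursion; one step spans 0.05 s.
FS_DEFAULT = 0.05


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Command schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommandSchedule:
    """Switching times of the binary forward/backward command input.

    ``switch_times`` is the strictly increasing sequence T_1 < T_2 < …
    (seconds, T_1 the simulation start); epochs alternate forward,
    backward, forward, … on the half-open intervals [T_v, T_{v+1}), the
    last epoch truncated at ``total_time``.
    """

    switch_times: tuple[float, ...]
    total_time: float

    def __post_init__(self):
        t = tuple(float(v) for v in self.switch_times)
        if len(t) < 1:
            raise ValueError("need at least one switch time")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("switch times must be strictly increasing")
        if self.total_time <= t[-1]:
            raise ValueError("total_time must exceed the last switch time")
        object.__setattr__(self, "switch_times", t)
        object.__setattr__(self, "total_time", float(self.total_time))

    @property
    def start(self) -> float:
        return self.switch_times[0]

    def epoch_of(self, t: float) -> int:
        """0-based epoch index of time ``t`` (0 = first forward epoch)."""
        if not self.start <= t < self.total_time:
            raise ValueError(f"t={t} outside [{self.start}, {self.total_time})")
        return int(np.searchsorted(self.switch_times, t, side="right") - 1)

    def is_forward(self, t: float) -> bool:
        return self.epoch_of(t) % 2 == 0

    def epochs(self) -> list[tuple[float, float, str]]:
        """List of (start, end, 'forward' | 'backward') spans."""
        bounds = list(self.switch_times) + [self.total_time]
        return [(bounds[k], bounds[k + 1], "forward" if k % 2 == 0 else "backward")
                for k in range(len(bounds) - 1)]

    def scaled(self, factor: float) -> "CommandSchedule":
        """Schedule with all times multiplied by ``factor``."""
        return CommandSchedule(tuple(t * factor for t in self.switch_times),
                               self.total_time * factor)


#: Training schedule used for the full-size runs (seconds).
TRAINING_SCHEDULE = CommandSchedule((0.0, 8.7, 17.6, 22.8, 26.6), 30.0)
#: Verification schedule with untrained switching times.
VERIFICATION_SCHEDULE = CommandSchedule((0.0, 4.7, 7.3, 17.25, 22.5, 28.0), 30.0)


def command_signal(t: float, schedule: CommandSchedule,
                   n_forward: int = 4, n_backward: int = 6) -> np.ndarray:
    """Binary command vector at time ``t``.

    The first ``n_forward`` entries are the forward command neurons
    (1 during forward epochs), the remaining ``n_backward`` the backward
    command neurons (1 during backward epochs).
    """
    fwd = schedule.is_forward(t)
    out = np.zeros(n_forward + n_backward)
    if fwd:
        out[:n_forward] = 1.0
    else:
        out[n_forward:] = 1.0
    return out


def command_matrix(schedule: CommandSchedule, n_steps: int, dt: float,
                   n_forward: int = 4, n_backward: int = 6) -> np.ndarray:
    """(n_steps, P) command inputs driving transitions k -> k+1.

    Row ``k`` is the command at time ``k * dt`` (the value entering the
    update that produces the state at ``(k+1) * dt``).
    """
    L = np.zeros((n_steps, n_forward + n_backward))
    for k in range(n_steps):
        L[k] = command_signal(k * dt, schedule, n_forward, n_backward)
    return L


# ---------------------------------------------------------------------------
# Parameters, state, trajectory
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """All trainable quantities of the network.

    Weight matrices are oriented (postsynaptic, presynaptic); sign
    constraints apply per presynaptic column (cholinergic classes >= 0,
    GABAergic <= 0).  Gap matrices are conductances (>= 0); ``gap_nn``
    and ``gap_mm`` are symmetric and a neuron-muscle pair shares the
    single matrix ``gap_mn`` between both update equations.
    """

    index_map: NeuronIndexMap
    w_nn: np.ndarray       # (J, J)
    w_nm: np.ndarray       # (M, J)
    w_mn: np.ndarray       # (J, M)
    w_in: np.ndarray       # (J, P)
    bias_n: np.ndarray     # (J,)
    bias_m: np.ndarray     # (M,)
    g_nn: np.ndarray       # (J, J) symmetric
    g_mn: np.ndarray       # (J, M)
    g_mm: np.ndarray       # (M, M) symmetric
    tau_n: np.ndarray      # (J,)
    tau_m: np.ndarray      # (M,)
    fs: float = FS_DEFAULT

    ARRAY_FIELDS = ("w_nn", "w_nm", "w_mn", "w_in", "bias_n", "bias_m",
                    "g_nn", "g_mn", "g_mm", "tau_n", "tau_m")

    @classmethod
    def zeros(cls, index_map: NeuronIndexMap, fs: float = FS_DEFAULT
              ) -> "ModelParameters":
        J, M, P = index_map.n_neurons, index_map.n_muscles, index_map.n_commands
        return cls(index_map,
                   w_nn=np.zeros((J, J)), w_nm=np.zeros((M, J)),
                   w_mn=np.zeros((J, M)), w_in=np.zeros((J, P)),
                   bias_n=np.zeros(J), bias_m=np.zeros(M),
                   g_nn=np.zeros((J, J)), g_mn=np.zeros((J, M)),
                   g_mm=np.zeros((M, M)), tau_n=np.zeros(J), tau_m=np.zeros(M),
                   fs=fs)

    def copy(self) -> "ModelParameters":
        kw = {f: getattr(self, f).copy() for f in self.ARRAY_FIELDS}
        return ModelParameters(self.index_map, fs=self.fs, **kw)

    def arrays(self) -> dict[str, np.ndarray]:
        return {f: getattr(self, f) for f in self.ARRAY_FIELDS}

    def masked(self, mask: ConnectomeMask) -> "ModelParameters":
        """Copy with every structurally absent entry forced to zero.

        Masked-off positions never influence the dynamics; forcing them
        to zero here also neutralizes any NaN/Inf planted outside the
        mask support.
        """
        out = self.copy()
        out.w_nn = np.where(mask.syn_nn, out.w_nn, 0.0)
        out.w_nm = np.where(mask.syn_nm, out.w_nm, 0.0)
        out.w_mn = np.where(mask.syn_mn, out.w_mn, 0.0)
        out.w_in = np.where(mask.syn_in, out.w_in, 0.0)
        out.g_nn = np.where(mask.gap_nn, out.g_nn, 0.0)
        out.g_mn = np.where(mask.gap_mn, out.g_mn, 0.0)
        out.g_mm = np.where(mask.gap_mm, out.g_mm, 0.0)
        return out

    def save(self, path) -> None:
        np.savez_compressed(
            path, fs=self.fs,
            index_map=np.frombuffer(self.index_map.to_json().encode(),
                                    dtype=np.uint8),
            **self.arrays())

    @classmethod
    def load(cls, path) -> "ModelParameters":
        with np.load(path) as z:
            imap = NeuronIndexMap.from_json(bytes(z["index_map"]).decode())
            kw = {f: z[f] for f in cls.ARRAY_FIELDS}
            return cls(imap, fs=float(z["fs"]), **kw)


@dataclass
class ModelState:
    """Instantaneous input currents of all cells."""

    x_n: np.ndarray
    x_m: np.ndarray

    @property
    def y_n(self) -> np.ndarray:
        return sigmoid(self.x_n)

    @property
    def y_m(self) -> np.ndarray:
        return sigmoid(self.x_m)

    @classmethod
    def zeros(cls, index_map: NeuronIndexMap) -> "ModelState":
        return cls(np.zeros(index_map.n_neurons), np.zeros(index_map.n_muscles))


@dataclass
class Trajectory:
    """Recorded outputs of a simulation run.

    Step ``k`` (0-based) holds the state at time ``times[k] = (k+1)*dt``;
    ``command_series[k]`` is the command input that drove the transition
    into that state.
    """

    times: np.ndarray            # (K,)
    y_m_series: np.ndarray       # (K, M)
    y_n_series: np.ndarray       # (K, J)
    command_series: np.ndarray   # (K, P)

    @property
    def n_steps(self) -> int:
        return len(self.times)

    def to_frame(self, index_map: NeuronIndexMap | None = None,
                 include_neurons: bool = True):
        """Columnar view: time, command bits, muscle (and neuron) outputs."""
        import pandas as pd
        data = {"time": self.times}
        for p in range(self.command_series.shape[1]):
            data[f"L{p + 1}"] = self.command_series[:, p]
        mnames = (index_map.muscle_names() if index_map is not None
                  else [f"m{u + 1}" for u in range(self.y_m_series.shape[1])])
        for u, name in enumerate(mnames):
            data[name] = self.y_m_series[:, u]
        if include_neurons:
            nnames = (index_map.neuron_names() if index_map is not None
                      else [f"n{i + 1}" for i in range(self.y_n_series.shape[1])])
            for i, name in enumerate(nnames):
                data[name] = self.y_n_series[:, i]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _lag_factors(tau: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    a = 1.0 / (1.0 + fs * tau)
    return a, 1.0 - a   # 1 - a == fs*tau / (1 + fs*tau)


def neuron_drive(params: ModelParameters, x_n, x_m, y_n, y_m, L) -> np.ndarray:
    """Total input to the motor neurons at one instant (bias included)."""
    p = params
    gap_out = p.g_nn.sum(axis=1) + p.g_mn.sum(axis=1)
    return (p.w_nn @ y_n + p.w_mn @ y_m
            + p.g_nn @ x_n + p.g_mn @ x_m - gap_out * x_n
            + p.w_in @ L + p.bias_n)


def muscle_drive(params: ModelParameters, x_n, x_m, y_n, y_m) -> np.ndarray:
    """Total input to the muscles at one instant (bias included)."""
    p = params
    gap_out = p.g_mn.sum(axis=0) + p.g_mm.sum(axis=1)
    return (p.w_nm @ y_n
            + p.g_mn.T @ x_n + p.g_mm @ x_m - gap_out * x_m
            + p.bias_m)


def step(state: ModelState, params: ModelParameters, L: np.ndarray,
         activation: Callable[[np.ndarray], np.ndarray] = sigmoid
         ) -> ModelState:
    """One synchronous update of all neuron and muscle currents.

    ``L`` is the command vector at the current time; both populations
    advance from time-``t`` values.  Raises on a non-finite result,
    naming the first offending cell.
    """
    if not (np.all(np.isfinite(state.x_n)) and np.all(np.isfinite(state.x_m))):
        raise FloatingPointError("non-finite state entering step")
    a_n, b_n = _lag_factors(params.tau_n, params.fs)
    a_m, b_m = _lag_factors(params.tau_m, params.fs)
    y_n, y_m = activation(state.x_n), activation(state.x_m)
    new_xn = a_n * state.x_n + b_n * neuron_drive(params, state.x_n, state.x_m,
                                                 y_n, y_m, L)
    new_xm = a_m * state.x_m + b_m * muscle_drive(params, state.x_n, state.x_m,
                                                  y_n, y_m)
    for arr, names in ((new_xn, "neuron"), (new_xm, "muscle")):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise FloatingPointError(f"non-finite current in {names} {bad[0]}")
    return ModelState(new_xn, new_xm)


def simulate(params: ModelParameters, schedule: CommandSchedule,
             x0: ModelState | None = None, mask: ConnectomeMask | None = None,
             activation: Callable[[np.ndarray], np.ndarray] = sigmoid
             ) -> Trajectory:
    """Run the network for ``round(total_time / Fs)`` steps.

    The initial state defaults to all-zero currents (outputs 0.5).  When
    a mask is given, parameters are sanitized against it first, so
    values planted outside the structural support cannot leak into the
    dynamics.  Deterministic: identical inputs give bit-identical
    trajectories.
    """
    if mask is not None:
        params = params.masked(mask)
    imap = params.index_map
    dt = params.fs
    n_steps = round(schedule.total_time / dt)
    state = x0 if x0 is not None else ModelState.zeros(imap)
    L = command_matrix(schedule, n_steps, dt, imap.n_forward, imap.n_backward)

    times = dt * np.arange(1, n_steps + 1)
    y_m_series = np.empty((n_steps, imap.n_muscles))
    y_n_series = np.empty((n_steps, imap.n_neurons))
    for k in range(n_steps):
        try:
            state = step(state, params, L[k], activation=activation)
        except FloatingPointError as err:
            raise FloatingPointError(f"at step {k}: {err}") from err
        y_n_series[k] = activation(state.x_n)
        y_m_series[k] = activation(state.x_m)
    return Trajectory(times, y_m_series, y_n_series, L)


# ---------------------------------------------------------------------------
# Traveling-wave direction
# ---------------------------------------------------------------------------

def wave_direction(y_m_series: np.ndarray, times: np.ndarray,
                   window: tuple[float, float], index_map: NeuronIndexMap,
                   row: str = "LD", exclude_head: int = 8,
                   period: float | None = None,
                   slope_threshold: float = 0.05,
                   amplitude_floor: float = 0.01) -> str:
    """Direction of the muscle-activity wave within one time window.

    ``row`` is one of the four muscle rows (``"LD"``, ``"RD"``,
    ``"LV"``, ``"RV"``) or a whole side (``"dorsal"`` / ``"ventral"``),
    in which case the left and right signals of each segment are
    averaged first — the claim under test concerns the dorsal or
    ventral muscle field, and single rows of a structurally asymmetric
    circuit can individually drift.  Each segment's oscillation phase
    is estimated by complex demodulation at the undulation frequency
    (the FFT peak of the row, or ``2*pi/period`` when the period is
    given) and regressed against head-to-tail segment index.  Phase falling toward the tail
    (negative slope) means the wave travels head to tail, matching the
    teacher convention ``sin(w t - pi q / 12)``.  The ``exclude_head``
    most anterior segments of the row are ignored — in the animal those
    muscles are driven by nerve-ring motor neurons outside this
    circuit.

    Returns ``"head_to_tail"``, ``"tail_to_head"``, or
    ``"undetermined"`` (oscillation amplitude below ``amplitude_floor``
    or |slope| below ``slope_threshold`` rad/segment).

    Raises ``ValueError`` if ``period`` is given and the window is
    shorter than one oscillation period.
    """
    t0, t1 = window
    if period is not None and (t1 - t0) < period:
        raise ValueError("window shorter than one oscillation period")
    sel = (times >= t0) & (times < t1)
    if sel.sum() < 4:
        raise ValueError("window contains too few samples")

    # a single muscle row, or a whole side with left/right averaged
    side_rows = {"dorsal": DORSAL_ROWS, "ventral": VENTRAL_ROWS}
    t = times[sel]
    if row in side_rows:
        cols, segs = [], []
        for q in range(exclude_head + 1, index_map.n_segments + 1):
            cells = [index_map.muscle_at(r, q) for r in side_rows[row]]
            cells = [c for c in cells if c is not None]
            if cells:
                cols.append(y_m_series[np.ix_(sel, cells)].mean(axis=1))
                segs.append(q)
        if len(cols) < 3:
            raise ValueError("fewer than 3 segments left after head exclusion")
        block = np.column_stack(cols)
        segs = np.array(segs)
    else:
        rows_idx = index_map.row_indices(row)
        segs = index_map.segment_of_muscle[rows_idx]
        keep = segs > exclude_head
        rows_idx, segs = rows_idx[keep], segs[keep]
        if len(rows_idx) < 3:
            raise ValueError("fewer than 3 muscles left after head exclusion")
        order = np.argsort(segs)
        rows_idx, segs = rows_idx[order], segs[order]
        block = y_m_series[np.ix_(sel, rows_idx)]
    if np.median(block.std(axis=0)) < amplitude_floor:
        return "undetermined"

    if period is not None:
        omega = 2 * np.pi / period
    else:
        dt = float(np.median(np.diff(times)))
        mean_sig = block.mean(axis=1)
        spec = np.abs(np.fft.rfft(mean_sig - mean_sig.mean()))
        freqs = 2 * np.pi * np.fft.rfftfreq(len(mean_sig), d=dt)
        spec[0] = 0.0
        omega = float(freqs[np.argmax(spec)])
        if omega <= 0:
            return "undetermined"

    centered = block - block.mean(axis=0)
    z = (centered * np.exp(-1j * omega * t)[:, None]).mean(axis=0)
    phases = np.unwrap(np.angle(z))
    slope = np.polyfit(segs.astype(float), phases, 1)[0]
    if abs(slope) < slope_threshold:
        return "undetermined"
    return "head_to_tail" if slope < 0 else "tail_to_head"


def wave_direction_table(trajectory: Trajectory, schedule: CommandSchedule,
                         index_map: NeuronIndexMap,
                         rows: Sequence[str] = ("dorsal", "ventral"),
                         exclude_head: int = 8, period: float | None = None,
                         **kwargs):
    """Per-epoch, per-row wave directions as a DataFrame.

    Epochs shorter than one oscillation period (possible at the very end
    of a schedule) cannot carry a full wave and are marked
    ``"too_short"`` instead of being judged.
    """
    import pandas as pd
    records = []
    for start, end, direction in schedule.epochs():
        for row in rows:
            if period is not None and (end - start) < period:
                d = "too_short"
            else:
                d = wave_direction(trajectory.y_m_series, trajectory.times,
                                   (start, end), index_map, row=row,
                                   exclude_head=exclude_head, period=period,
                                   **kwargs)
            records.append({"epoch_start": start, "epoch_end": end,
                            "command": direction, "row": row, "wave": d})
    return pd.DataFrame.from_records(records)
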