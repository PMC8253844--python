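"""Teacher (target) muscle-activation patterns.

Two teachers are provided.  The *analytic* teacher is a sinusoidal
traveling wave: dorsal muscle at segment q follows

    d(t) = sin(omega * t + phi_q),     phi_q(0) = -pi * q / 12,

the ventral side the same wave shifted by -pi (dorsoventral antiphase).
At every command switch T_v the phase is replaced by

    phi_new = pi - 2 * omega * T_v - phi_old,

which reverses the spatial propagation direction while keeping d(t)
continuous at the switch.  The raw sine is rescaled affinely into
[0.25, 0.75] so the target is attainable by the muscles' logistic
output.

The *measured-fluorescence emulator* stands in for calcium-imaging
recordings of a GCaMP muscle strain (HBR4): it synthesizes per-segment
dorsal/ventral fluorescence intensities carrying one forward and one
backward cycle of the wave with per-segment amplitude heterogeneity and
additive noise, converts them to fluorescence rates R = (F - F0) / F0,
smooths each trace by fitting a sum of sinusoids, tiles the fitted
cycles, and normalizes the result to [0.25, 0.75].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .connectome import NeuronIndexMap, DORSAL_ROWS
from .dynamics import CommandSchedule, FS_DEFAULT

#: Angular frequency of the undulation (rad/s), from worm motion analysis.
OMEGA_DEFAULT = 1.6 * np.pi

#: Output range the teacher is normalized to.
TEACHER_RANGE = (0.25, 0.75)


@dataclass
class TeacherData:
    """Target muscle activation matrix over the simulation horizon."""

    d: np.ndarray                 # (K, M) in the configured output range
    times: np.ndarray             # (K,)
    schedule: CommandSchedule
    index_map: NeuronIndexMap
    provenance: str               # "analytic" | "measured_emulation"
    omega: float = OMEGA_DEFAULT

    @property
    def n_steps(self) -> int:
        return len(self.times)

    @property
    def period(self) -> float:
        return 2 * np.pi / self.omega


@dataclass
class SineSum:
    """Parameters of a fitted sum of sinusoids
    ``sum_i a_i * sin(w_i * t + phi_i)``."""

    amplitudes: np.ndarray
    frequencies: np.ndarray   # rad/s
    phases: np.ndarray
    rms: float = np.nan       # residual RMS of the fit

    @property
    def n(self) -> int:
        return len(self.amplitudes)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(self.amplitudes[:, None]
                      * np.sin(self.frequencies[:, None] * t[None, :]
                               + self.phases[:, None]), axis=0)


@dataclass
class FluorescenceTrace:
    """Per-segment, per-side raw fluorescence intensity time series.

    ``f`` has shape (K, n_segments, 2); the last axis is (dorsal,
    ventral).  The baseline F0 of each trace is its minimum over time.
    """

    times: np.ndarray
    f: np.ndarray

    @property
    def f0(self) -> np.ndarray:
        return self.f.min(axis=0)


# ---------------------------------------------------------------------------
# Analytic teacher
# ---------------------------------------------------------------------------

def _epoch_phases(schedule: CommandSchedule, omega: float,
                  phi0: np.ndarray) -> list[np.ndarray]:
    """Piecewise-constant phase per epoch, updated at each switch time."""
    phases = [phi0]
    for T_v in schedule.switch_times[1:]:
        phases.append(np.pi - 2 * omega * T_v - phases[-1])
    return phases


def rescale(raw: np.ndarray, out_range: tuple[float, float] = TEACHER_RANGE,
            in_range: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    """Affine map of ``in_range`` onto ``out_range``."""
    lo, hi = out_range
    a, b = in_range
    return lo + (raw - a) * (hi - lo) / (b - a)


def analytic_teacher(schedule: CommandSchedule,
                     index_map: NeuronIndexMap | None = None,
                     omega: float = OMEGA_DEFAULT,
                     fs: float = FS_DEFAULT,
                     out_range: tuple[float, float] | None = TEACHER_RANGE
                     ) -> TeacherData:
    """Sinusoidal traveling-wave teacher with phase reversal at switches.

    The initial dorsal phase at segment q is ``-pi*q/12`` scaled to the
    map's segment count (so a scaled circuit still spans two full waves
    head to tail); ventral muscles run in antiphase; left and right rows
    of a side are identical.  ``out_range=None`` leaves the raw sine in
    [-1, 1].
    """
    imap = index_map or NeuronIndexMap.standard()
    dt = fs
    n_steps = round(schedule.total_time / dt)
    times = dt * np.arange(1, n_steps + 1)

    q = imap.segment_of_muscle.astype(float)
    # -pi*q/12 in the full animal; the same head-to-tail phase span for
    # a scaled segment count.
    phi0 = -np.pi * q * (24.0 / imap.n_segments) / 12.0
    dorsal = imap.muscle_is_dorsal
    offset = np.where(dorsal, 0.0, -np.pi)

    phases = _epoch_phases(schedule, omega, phi0)
    bounds = list(schedule.switch_times) + [schedule.total_time]
    d = np.empty((n_steps, imap.n_muscles))
    for e, phi in enumerate(phases):
        sel = (times >= bounds[e]) & (times < bounds[e + 1])
        if e == len(phases) - 1:  # include the final sample at t == T
            sel |= times >= bounds[e + 1]
        d[sel] = np.sin(omega * times[sel, None] + offset[None, :]
                        + phi[None, :])
    if out_range is not None:
        d = rescale(d, out_range)
    return TeacherData(d, times, schedule, imap, "analytic", omega)


# ---------------------------------------------------------------------------
# Fluorescence-rate conversion and sum-of-sines smoothing
# ---------------------------------------------------------------------------

def fluorescence_rate(trace: FluorescenceTrace) -> np.ndarray:
    """Convert raw fluorescence to rates ``R = (F - F0) / F0``.

    F0 is the per-trace minimum, so each output series has minimum
    exactly zero.  Raises if any baseline is zero.
    """
    f0 = trace.f0
    if np.any(f0 <= 0):
        raise ZeroDivisionError("zero or negative baseline fluorescence F0")
    return (trace.f - f0[None]) / f0[None]


class SineFitError(RuntimeError):
    """Sum-of-sines fit failed to converge; carries the best-so-far fit."""

    def __init__(self, message: str, best: SineSum):
        super().__init__(message)
        self.best = best


def _spectral_peak_freqs(t: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Top-``n`` angular frequencies of the discrete spectrum.

    The first guess is a near-zero frequency: its cosine component acts
    as a constant, absorbing any baseline offset of the series.
    """
    from scipy.signal import find_peaks

    dt = float(np.median(np.diff(t)))
    y0 = y - y.mean()
    spec = np.abs(np.fft.rfft(y0 * np.hanning(len(y0))))
    freqs = 2 * np.pi * np.fft.rfftfreq(len(y0), d=dt)
    spec[0] = 0.0
    # local maxima of the spectrum, so spectral-leakage sidelobes of a
    # strong component do not crowd out genuine weaker components
    peak_idx, _ = find_peaks(spec)
    if len(peak_idx) == 0:
        peak_idx = np.argsort(spec)[::-1][: 3 * n]
    # candidates ranked by estimated amplitude; a near-zero frequency
    # (whose cosine column acts as a constant) competes for a slot with
    # the spectral peaks according to the series' mean offset
    cands = [(abs(float(np.mean(y))), 1e-4)]
    for k in sorted(peak_idx, key=lambda k: -spec[k])[: 3 * n]:
        amp = 2 * spec[k] / (0.5 * len(y0))  # Hann coherent gain ~ 0.5
        cands.append((amp, max(freqs[k], 1e-3)))
    cands.sort(key=lambda p: -p[0])
    out: list[float] = []
    for _, f in cands:
        if len(out) >= n:
            break
        if all(abs(f - g) > 1e-6 for g in out):
            out.append(f)
    k = 1
    while len(out) < n:
        out.append(out[-1] * (1 + 0.1 * k))
        k += 1
    return np.array(out[:n])


def _sine_design(t: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Design matrix with sin/cos columns for each frequency."""
    arg = np.abs(w)[None, :] * t[:, None]
    return np.concatenate([np.sin(arg), np.cos(arg)], axis=1)


def fit_sum_of_sines(times: np.ndarray, series: np.ndarray, n: int = 8,
                     max_nfev: int = 2000, rms_tol: float | None = None
                     ) -> SineSum:
    """Least-squares fit of ``sum a_i sin(w_i t + phi_i)``.

    Uses separable (variable-projection) least squares: only the ``n``
    frequencies are optimized nonlinearly, the amplitudes and phases
    follow from a linear solve at each step.  Initial frequencies come
    from the top peaks of the discrete spectrum, making the fit
    deterministic.  Raises :class:`SineFitError` (carrying the
    best-so-far parameters) if the optimizer fails or the residual RMS
    exceeds ``rms_tol``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(series, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(t) < 4 * n:
        raise ValueError("series too short for the requested number of terms")
    if np.allclose(y, y[0]):
        # constant input: amplitudes zero, arbitrary small frequencies
        z = np.zeros(n)
        return SineSum(z, np.linspace(1.0, n, n), z.copy(),
                       rms=float(np.sqrt(np.mean((y - y.mean()) ** 2))))

    def coeffs(w):
        X = _sine_design(t, w)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return X, beta

    def resid(w):
        X, beta = coeffs(w)
        return X @ beta - y

    w0 = _spectral_peak_freqs(t, y, n)
    res = least_squares(resid, w0, max_nfev=max_nfev, method="lm")
    w = np.abs(res.x)
    X, beta = coeffs(w)
    s, c = beta[:n], beta[n:]
    amp = np.hypot(s, c)
    phi = np.arctan2(c, s)
    rms = float(np.sqrt(np.mean((X @ beta - y) ** 2)))
    fit = SineSum(amp, w, phi, rms=rms)
    scale = float(np.std(y)) or 1.0
    if not res.success and rms > 1e-6 * scale:
        raise SineFitError(f"sum-of-sines fit did not converge (rms={rms:.3g})",
                           fit)
    if rms_tol is not None and rms > rms_tol:
        raise SineFitError(f"fit rms {rms:.3g} exceeds tolerance {rms_tol:.3g}",
                           fit)
    return fit


# ---------------------------------------------------------------------------
# Measured-teacher emulation
# ---------------------------------------------------------------------------

def _one_cycle_schedule(omega: float, cycles: int) -> CommandSchedule:
    """Schedule of `cycles` repetitions of one forward + one backward period."""
    period = 2 * np.pi / omega
    times = tuple(k * period for k in range(2 * cycles))
    return CommandSchedule(times, 2 * cycles * period)


def emulate_measured_teacher(seed: int,
                             schedule: CommandSchedule | None = None,
                             index_map: NeuronIndexMap | None = None,
                             cycles: int = 3,
                             noise_sd: float = 0.05,
                             amp_heterogeneity: float = 0.2,
                             omega: float = OMEGA_DEFAULT,
                             fs: float = FS_DEFAULT,
                             n_sines: int = 8,
                             baseline: float = 50.0,
                             modulation: float = 0.8) -> TeacherData:
    """Synthetic stand-in for the measured-fluorescence teacher pipeline.

    One forward cycle followed by one backward cycle of the traveling
    wave is rendered as per-segment dorsal/ventral fluorescence
    intensities ``F = baseline * (1 + modulation * activation)`` with
    multiplicative per-segment amplitude jitter (sd ``amp_heterogeneity``)
    and additive Gaussian noise (sd ``noise_sd * baseline``).  Each
    trace is converted to rates, each single-direction piece smoothed by
    an ``n_sines``-term sinusoid fit, the fitted pieces tiled to
    ``cycles`` forward/backward repetitions, mapped onto the muscle
    layout (left = right), and the whole matrix normalized to
    [0.25, 0.75].

    With ``noise_sd = 0`` and ``amp_heterogeneity = 0`` the result
    reproduces the analytic teacher up to the sinusoid-fit error.

    Raises :class:`SineFitError` naming segment and side if any trace
    cannot be smoothed.
    """
    imap = index_map or NeuronIndexMap.standard()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = _one_cycle_schedule(omega, cycles)
    period = 2 * np.pi / omega
    dt = fs

    # --- render the one-forward + one-backward recording -----------------
    # the emulated camera samples finer than the simulation step, as a
    # real video recording would
    rec_dt = dt / 5.0
    n_rec = round(2 * period / rec_dt)
    t_rec = rec_dt * np.arange(1, n_rec + 1)
    nseg = imap.n_segments
    q = np.arange(1, nseg + 1, dtype=float)
    phi0 = -np.pi * q * (24.0 / nseg) / 12.0
    T2 = period  # switch after one full forward period
    phi1 = np.pi - 2 * omega * T2 - phi0

    gain = np.clip(1.0 + amp_heterogeneity * rng.standard_normal((nseg, 2)),
                   0.2, None)
    f = np.empty((n_rec, nseg, 2))
    for s in (0, 1):  # dorsal, ventral
        off = 0.0 if s == 0 else -np.pi
        wave = np.where(t_rec[:, None] < T2,
                        np.sin(omega * t_rec[:, None] + off + phi0[None, :]),
                        np.sin(omega * t_rec[:, None] + off + phi1[None, :]))
        act = 0.5 * (wave + 1.0)                       # [0, 1]
        f[:, :, s] = baseline * (1.0 + modulation * gain[None, :, s] * act)
    f += noise_sd * baseline * rng.standard_normal(f.shape)
    f = np.clip(f, 1e-3, None)
    trace = FluorescenceTrace(t_rec, f)
    rates = fluorescence_rate(trace)

    # --- smooth each single-direction piece per segment/side -------------
    fwd_sel = t_rec < T2
    fits = np.empty((nseg, 2, 2), dtype=object)  # (segment, side, piece)
    for i in range(nseg):
        for s, side in enumerate(("dorsal", "ventral")):
            for p, sel in enumerate((fwd_sel, ~fwd_sel)):
                try:
                    fits[i, s, p] = fit_sum_of_sines(t_rec[sel], rates[sel, i, s],
                                                     n=n_sines)
                except SineFitError as err:
                    raise SineFitError(
                        f"segment {i + 1}, {side}, "
                        f"{'forward' if p == 0 else 'backward'} piece: {err}",
                        err.best) from err

    # --- tile the fitted cycles along the output schedule -----------------
    n_steps = round(schedule.total_time / dt)
    times = dt * np.arange(1, n_steps + 1)
    bounds = list(schedule.switch_times) + [schedule.total_time]
    seg_series = np.empty((n_steps, nseg, 2))
    piece_start = (0.0, T2)
    for e in range(len(bounds) - 1):
        sel = (times >= bounds[e]) & (times <= bounds[e + 1]
                                      if e == len(bounds) - 2
                                      else times < bounds[e + 1])
        p = e % 2  # even epochs replay the forward piece
        # replay the fitted piece from its own start, wrapped on its period
        local = piece_start[p] + np.mod(times[sel] - bounds[e], period)
        for i in range(nseg):
            for s in (0, 1):
                seg_series[sel, i, s] = fits[i, s, p](local)

    # --- map segments onto the muscle layout ------------------------------
    d = np.empty((n_steps, imap.n_muscles))
    qm = imap.segment_of_muscle
    dorsal = imap.muscle_is_dorsal
    for u in range(imap.n_muscles):
        d[:, u] = seg_series[:, qm[u] - 1, 0 if dorsal[u] else 1]

    d = normalize_range(d, TEACHER_RANGE)
    return TeacherData(d, times, schedule, imap, "measured_emulation", omega)


def normalize_range(x: np.ndarray, out_range: tuple[float, float] = TEACHER_RANGE
                    ) -> np.ndarray:
    """Affinely map the array's global min/max onto ``out_range``.

    Idempotent: normalizing an already-normalized array is the identity.
    """
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.full_like(x, 0.5 * (out_range[0] + out_range[1]))
    return rescale(x, out_range, (lo, hi))
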