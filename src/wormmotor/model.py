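"""Model / results interface for the neuromuscular network.

:class:`NeuromuscularModel` bundles the fixed ingredients of a training
problem — the connectivity mask, the teacher data, and the training
configuration — and :meth:`NeuromuscularModel.fit` runs constrained
BPTT, returning a :class:`TrainingResults` with the trained parameters,
the learning curve, residual diagnostics, and a ``summary()`` table.
Simulation and plotting hang off the results object.

Example
-------
>>> from wormmotor import NeuromuscularModel
>>> model = NeuromuscularModel.from_synthetic(n_segments=8, seed=0)
>>> res = model.fit(seed=1)
>>> print(res.summary())                      # doctest: +SKIP
>>> traj = res.simulate()                     # trained schedule
>>> res.wave_directions()                     # per-epoch wave table
"""

from __future__ import annotations



import numpy as np

from .connectome import ConnectomeMask, NeuronIndexMap, synthesize_connectome
from .dynamics import (CommandSchedule, ModelState, Trajectory,
                       TRAINING_SCHEDULE, VERIFICATION_SCHEDULE,
                       simulate, wave_direction_table)
from .teacher import TeacherData, analytic_teacher, emulate_measured_teacher
from .training import TrainingConfig, TrainResult, train


class NeuromuscularModel:
    """A connectome-constrained motor-circuit model bound to teacher data.

    Parameters
    ----------
    teacher
        Target muscle-activation matrix (drives the command schedule too).
    mask
        Structural connectivity; defines which parameters exist.
    config
        Training hyper-parameters; defaults to :class:`TrainingConfig`.
    verification_schedule
        Untrained switching times used for the generalization check
        after fitting (optional).
    """

    def __init__(self, teacher: TeacherData, mask: ConnectomeMask,
                 config: TrainingConfig | None = None,
                 verification_schedule: CommandSchedule | None = None):
        if teacher.index_map.n_muscles != mask.index_map.n_muscles:
            raise ValueError("teacher and mask muscle counts differ")
        self.teacher = teacher
        self.mask = mask
        self.config = config or TrainingConfig()
        self.verification_schedule = verification_schedule

    @property
    def index_map(self) -> NeuronIndexMap:
        return self.mask.index_map

    @classmethod
    def from_synthetic(cls, n_segments: int = 24,
                       teacher_mode: str = "analytic",
                       schedule: CommandSchedule | None = None,
                       verification_schedule: CommandSchedule | None = None,
                       seed: int = 0,
                       omega: float | None = None,
                       density=None, locality_span: int = 7,
                       proprio_span: int = 7,
                       config: TrainingConfig | None = None,
                       **teacher_kwargs) -> "NeuromuscularModel":
        """Build model + synthetic connectome + teacher in one call.

        ``n_segments=24`` gives the full 69-neuron / 95-muscle circuit;
        smaller values give proportionally scaled circuits (with the
        schedule scaled to match when none is supplied).
        """
        imap = (NeuronIndexMap.standard() if n_segments == 24
                else NeuronIndexMap.scaled(n_segments))
        span = min(locality_span, max(1, n_segments // 2))
        pspan = min(proprio_span, max(1, n_segments // 2))
        mask = synthesize_connectome(imap, density=density,
                                     locality_span=span, seed=seed,
                                     proprio_span=pspan)
        scale = n_segments / 24.0
        if schedule is None:
            schedule = TRAINING_SCHEDULE if n_segments == 24 \
                else TRAINING_SCHEDULE.scaled(scale)
        if verification_schedule is None:
            verification_schedule = VERIFICATION_SCHEDULE if n_segments == 24 \
                else VERIFICATION_SCHEDULE.scaled(scale)
        kw = dict(teacher_kwargs)
        if omega is not None:
            kw["omega"] = omega
        if teacher_mode == "analytic":
            teacher = analytic_teacher(schedule, imap, **kw)
        elif teacher_mode == "measured_emulation":
            teacher = emulate_measured_teacher(seed, schedule=schedule,
                                               index_map=imap, **kw)
        else:
            raise ValueError(f"unknown teacher_mode {teacher_mode!r}")
        return cls(teacher, mask, config=config,
                   verification_schedule=verification_schedule)

    # ------------------------------------------------------------------

    def fit(self, seed: int | None = None, **kwargs) -> "TrainingResults":
        """Run constrained BPTT training; returns a results object."""
        res = train(self.mask, self.teacher, self.config, seed=seed,
                    verification_schedule=self.verification_schedule,
                    **kwargs)
        return TrainingResults(self, res)

    def simulate(self, params, schedule: CommandSchedule | None = None,
                 x0: ModelState | None = None) -> Trajectory:
        return simulate(params, schedule or self.teacher.schedule,
                        x0=x0, mask=self.mask)


class TrainingResults:
    """Fitted parameters plus diagnostics of one training trial."""

    def __init__(self, model: NeuromuscularModel, result: TrainResult):
        self.model = model
        self._result = result

    # pass-throughs ----------------------------------------------------
    @property
    def params(self):
        return self._result.params

    @property
    def learning_curve(self) -> np.ndarray:
        return self._result.learning_curve

    @property
    def final_e(self) -> float:
        return self._result.final_e

    @property
    def iterations_used(self) -> int:
        return self._result.iterations_used

    @property
    def converged(self) -> bool:
        return self._result.converged

    @property
    def residuals(self) -> dict:
        return self._result.residuals

    @property
    def train_result(self) -> TrainResult:
        """The underlying plain result (used by the analysis helpers)."""
        return self._result

    # behaviour --------------------------------------------------------

    def simulate(self, schedule: CommandSchedule | None = None,
                 x0: ModelState | None = None) -> Trajectory:
        """Run the trained network (defaults to the training schedule)."""
        return self.model.simulate(self.params, schedule, x0)

    def wave_directions(self, schedule: CommandSchedule | None = None,
                        rows=("dorsal", "ventral"),
                        exclude_head: int | None = None,
                        **kwargs):
        """Per-epoch traveling-wave directions of the trained network."""
        imap = self.model.index_map
        schedule = schedule or self.model.teacher.schedule
        traj = self.simulate(schedule)
        if exclude_head is None:
            # the paper-scale convention (8 head muscles) shrunk with the map
            exclude_head = max(1, round(8 * imap.n_segments / 24))
        period = 2 * np.pi / self.model.teacher.omega
        return wave_direction_table(traj, schedule, imap, rows=rows,
                                    exclude_head=exclude_head, period=period,
                                    **kwargs)

    def summary(self) -> str:
        """Human-readable fit report."""
        imap = self.model.index_map
        r = self._result
        lines = [
            "Neuromuscular network BPTT fit",
            "=" * 46,
            f"{'motor neurons':<28}{imap.n_neurons:>10d}",
            f"{'muscle cells':<28}{imap.n_muscles:>10d}",
            f"{'command inputs':<28}{imap.n_commands:>10d}",
            f"{'synaptic entries (mask)':<28}{self.model.mask.n_synaptic():>10d}",
            f"{'gap-junction pairs (mask)':<28}{self.model.mask.n_gap_pairs():>10d}",
            f"{'teacher':<28}{self.model.teacher.provenance:>10s}",
            "-" * 46,
            f"{'iterations used':<28}{r.iterations_used:>10d}",
            f"{'converged (E <= tol)':<28}{str(r.converged):>10s}",
            f"{'pre-training E':<28}{r.residuals['pre_training']:>10.5f}",
            f"{'post-training E':<28}{r.residuals['post_training']:>10.5f}",
        ]
        if "verification" in r.residuals:
            lines.append(f"{'verification E':<28}"
                         f"{r.residuals['verification']:>10.5f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<TrainingResults: E={self.final_e:.5f} "
                f"iterations={self.iterations_used} "
                f"converged={self.converged}>")

    # plotting ----------------------------------------------------------

    def plot_learning_curve(self, ax=None):
        """Learning curve on a log scale with the tolerance line."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.learning_curve)
        tol = (self._result.config.tolerance if self._result.config
               else 0.005)
        ax.axhline(tol, color="red", ls=":", label=f"tolerance {tol}")
        ax.set_xlabel("iteration")
        ax.set_ylabel("evaluation function E")
        ax.legend()
        return ax

    def plot_muscle_activity(self, schedule: CommandSchedule | None = None,
                             ax=None, cmap="viridis"):
        """Muscle-activation heat map (muscle index vs time)."""
        import matplotlib.pyplot as plt
        traj = self.simulate(schedule)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 8))
        im = ax.imshow(traj.y_m_series, aspect="auto", origin="lower",
                       extent=[1, traj.y_m_series.shape[1],
                               traj.times[0], traj.times[-1]],
                       cmap=cmap)
        ax.set_xlabel("muscle cell (head to tail, by row)")
        ax.set_ylabel("time (s)")
        plt.colorbar(im, ax=ax, label="muscle activation")
        return ax
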