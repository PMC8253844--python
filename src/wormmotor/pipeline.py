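"""End-to-end experiment orchestration.

``run_experiment`` executes the full analysis — build (or load) a
connectivity mask, generate teacher data, train one or more trials,
simulate the verification schedule, and fit the weight-strength
distributions — writing every artifact plus a manifest (inputs, seeds,
output hashes) to an output directory.  Re-running with the same
configuration reproduces every file bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import fit_modified_boltzmann, pool_weights, residual_summary
from .connectome import ConnectomeMask, NeuronIndexMap, synthesize_connectome
from .dynamics import (CommandSchedule, TRAINING_SCHEDULE,
                       VERIFICATION_SCHEDULE, simulate, wave_direction_table)
from .model import NeuromuscularModel
from .teacher import analytic_teacher, emulate_measured_teacher
from .training import TrainingConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one experiment run.

    Every stochastic stage derives its seed from ``seed``: the mask uses
    ``seed``, trial k trains from ``seed + 1 + k``, the measured-teacher
    emulator uses ``seed + 101``.
    """

    n_segments: int = 24
    teacher_mode: str = "analytic"        # "analytic" | "measured_emulation"
    seed: int = 0
    n_trials: int = 1
    mask_file: str | None = None          # load instead of synthesizing
    schedule: list[float] | None = None   # switch times; None = default
    total_time: float | None = None
    verification_schedule: list[float] | None = None
    verification_total_time: float | None = None
    density: dict | float | None = None
    locality_span: int = 7
    proprio_span: int = 7
    n_bins: int = 20
    training: dict = field(default_factory=dict)
    teacher_kwargs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def resolve_schedules(self) -> tuple[CommandSchedule, CommandSchedule]:
        scale = self.n_segments / 24.0
        if self.schedule is not None:
            sched = CommandSchedule(tuple(self.schedule), self.total_time)
        else:
            sched = TRAINING_SCHEDULE.scaled(scale) if scale != 1.0 \
                else TRAINING_SCHEDULE
        if self.verification_schedule is not None:
            ver = CommandSchedule(tuple(self.verification_schedule),
                                  self.verification_total_time)
        else:
            ver = VERIFICATION_SCHEDULE.scaled(scale) if scale != 1.0 \
                else VERIFICATION_SCHEDULE
        return sched, ver


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_experiment(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline; returns (and writes) the manifest.

    Artifacts: ``mask.npz``, ``teacher.csv``, per-trial parameter
    archives and learning curves, trained/verification trajectories of
    trial 0, the residual-error table, weight histograms with their
    modified-Boltzmann fits, and ``manifest.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        imap = (NeuronIndexMap.standard() if config.n_segments == 24
                else NeuronIndexMap.scaled(config.n_segments))
        sched, ver = config.resolve_schedules()

        stage = "make-mask"
        if config.mask_file:
            mask = ConnectomeMask.load(config.mask_file)
            imap = mask.index_map
        else:
            span = min(config.locality_span, max(1, config.n_segments // 2))
            pspan = min(config.proprio_span, max(1, config.n_segments // 2))
            mask = synthesize_connectome(imap, density=config.density,
                                         locality_span=span,
                                         seed=config.seed, proprio_span=pspan)
        mask.save(out / "mask.npz")
        written.append(out / "mask.npz")

        stage = "make-teacher"
        if config.teacher_mode not in ("analytic", "measured_emulation"):
            raise ValueError(f"unknown teacher_mode {config.teacher_mode!r}")
        if config.teacher_mode == "analytic":
            teacher = analytic_teacher(sched, imap, **config.teacher_kwargs)
        else:
            teacher = emulate_measured_teacher(config.seed + 101,
                                               schedule=sched, index_map=imap,
                                               **config.teacher_kwargs)
        np.savetxt(out / "teacher.csv",
                   np.column_stack([teacher.times, teacher.d]),
                   delimiter=",", fmt="%.6f")
        written.append(out / "teacher.csv")

        stage = "train"
        tcfg = TrainingConfig(**config.training)
        model = NeuromuscularModel(teacher, mask, tcfg,
                                   verification_schedule=ver)
        results = []
        for k in range(config.n_trials):
            t0 = time.time()
            res = model.fit(seed=config.seed + 1 + k)
            logger.info("trial %d: E=%.5f after %d iterations (%.0f s)",
                        k, res.final_e, res.iterations_used, time.time() - t0)
            results.append(res)
            res.params.save(out / f"params_trial{k}.npz")
            np.savetxt(out / f"learning_curve_trial{k}.csv",
                       res.learning_curve, delimiter=",", fmt="%.8f")
            written += [out / f"params_trial{k}.npz",
                        out / f"learning_curve_trial{k}.csv"]

        stage = "simulate"
        for name, schd in (("trained", sched), ("verification", ver)):
            traj = results[0].simulate(schd)
            traj.to_frame(imap).to_csv(out / f"trajectory_{name}.csv",
                                       index=False, float_format="%.6f")
            written.append(out / f"trajectory_{name}.csv")
            tab = results[0].wave_directions(schd)
            tab.to_csv(out / f"wave_directions_{name}.csv", index=False)
            written.append(out / f"wave_directions_{name}.csv")

        stage = "analyze"
        residual_summary([r.train_result for r in results]).to_csv(
            out / "residuals.csv")
        written.append(out / "residuals.csv")
        fits = {}
        for src in ("synaptic", "conductance"):
            hist = pool_weights([r.train_result for r in results],
                                source=src, n_bins=config.n_bins)
            hist.to_frame().to_csv(out / f"histogram_{src}.csv", index=False)
            written.append(out / f"histogram_{src}.csv")
            fit = fit_modified_boltzmann(hist)
            fits[src] = {"A": fit.A, "a": fit.a, "beta": fit.beta,
                         "n": fit.n, "r_squared": fit.r_squared,
                         "p_value": fit.fit_pvalue}
        with open(out / "boltzmann_fits.json", "w") as fh:
            json.dump(fits, fh, indent=2)
        written.append(out / "boltzmann_fits.json")
    except Exception as err:
        partial = {"stage_failed": stage, "error": str(err),
                   "outputs": {p.name: _sha256(p) for p in written if p.exists()}}
        with open(out / "manifest.json", "w") as fh:
            json.dump(partial, fh, indent=2)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_neurons": imap.n_neurons,
        "n_muscles": imap.n_muscles,
        "trials": [{"seed": config.seed + 1 + k,
                    "final_e": r.final_e,
                    "iterations": r.iterations_used,
                    "converged": bool(r.converged)}
                   for k, r in enumerate(results)],
        "boltzmann_fits": fits,
        "outputs": {p.name: _sha256(p) for p in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
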