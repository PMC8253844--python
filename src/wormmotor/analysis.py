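"""Post-training analysis of connection-strength distributions.

Trained synaptic weight magnitudes (and, separately, gap-junction
conductances) pooled across training trials are binned into equal-width
histograms and fitted with the modified Boltzmann distribution

    p(w) = A * exp(-beta * (a * |w|)) / (a * |w|)**(1 - 1/n),

where A and a are scale factors, beta the power index, and n the total
number of structural connections (fixed, not fitted).  A and a are not
jointly identifiable (the family only depends on lambda = beta * a and
an overall scale), so the fit is performed in the reduced
parameterization ``C * exp(-lambda w) / w**(1 - 1/n)`` with a frozen at
1; the reported (A, beta) are the reduced parameters mapped back.
Goodness of fit is the coefficient of determination on the mean bin
frequencies, plus the F-test p-value of the regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .training import TrainResult

#: Weight matrices pooled for the chemical-synapse histogram.
SYNAPTIC_FIELDS = ("w_nn", "w_nm", "w_mn", "w_in")


@dataclass
class WeightHistogram:
    """Per-trial and pooled histogram of connection-strength magnitudes."""

    bin_edges: np.ndarray          # (n_bins + 1,)
    frequencies: np.ndarray        # (n_trials, n_bins) raw counts
    source: str                    # "synaptic" | "conductance"
    n_total: int                   # structurally allowed connections

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean_frequency(self) -> np.ndarray:
        return self.frequencies.mean(axis=0)

    @property
    def n_trials(self) -> int:
        return self.frequencies.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_left": self.bin_edges[:-1],
                           "bin_right": self.bin_edges[1:],
                           "mean_frequency": self.mean_frequency})
        for k in range(self.n_trials):
            df[f"trial_{k}"] = self.frequencies[k]
        return df


@dataclass
class BoltzmannFit:
    """Fitted modified-Boltzmann parameters and goodness of fit."""

    A: float
    a: float
    beta: float
    n: int
    r_squared: float
    fit_pvalue: float
    residual_rms: float

    def __call__(self, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        aw = self.a * np.abs(w)
        return self.A * np.exp(-self.beta * aw) / aw ** (1.0 - 1.0 / self.n)


def _trial_magnitudes(result: TrainResult, source: str) -> np.ndarray:
    """Nonzero connection-strength magnitudes of one trained trial.

    Exact zeros (masked-off or driven onto the sign boundary by the
    projection) are excluded: the distribution describes the strength of
    existing connections, and the fitted density diverges at w -> 0.
    """
    p, mask = result.params, result.mask
    if source == "synaptic":
        vals = [np.abs(p.w_nn[mask.syn_nn]), np.abs(p.w_nm[mask.syn_nm]),
                np.abs(p.w_mn[mask.syn_mn]), np.abs(p.w_in[mask.syn_in])]
    elif source == "conductance":
        iu_n = np.triu(mask.gap_nn, 1)
        iu_m = np.triu(mask.gap_mm, 1)
        vals = [p.g_nn[iu_n], p.g_mn[mask.gap_mn], p.g_mm[iu_m]]
    else:
        raise ValueError(f"unknown source {source!r}")
    v = np.concatenate(vals)
    return v[v > 0]


def pool_weights(results: list[TrainResult], source: str = "synaptic",
                 n_bins: int = 20) -> WeightHistogram:
    """Histogram trained weight magnitudes across trials.

    ``source="synaptic"`` pools all chemical-synapse matrices over their
    mask-true entries; ``source="conductance"`` pools unique unordered
    gap-junction pairs.  All trials share equal-width bins spanning the
    pooled range; per-trial counts and their mean are kept.
    """
    if not results:
        raise ValueError("need at least one training result")
    per_trial = [_trial_magnitudes(r, source) for r in results]
    pooled = np.concatenate(per_trial)
    if pooled.size == 0:
        raise ValueError("no nonzero weights to pool")
    edges = np.linspace(0.0, float(pooled.max()), n_bins + 1)
    freqs = np.stack([np.histogram(v, bins=edges)[0] for v in per_trial])
    mask0 = results[0].mask
    n_total = (mask0.n_synaptic() if source == "synaptic"
               else mask0.n_gap_pairs())
    return WeightHistogram(edges, freqs, source, n_total)


def fit_modified_boltzmann(hist: WeightHistogram) -> BoltzmannFit:
    """Least-squares fit of the modified Boltzmann form to mean frequencies.

    Only occupied bins enter the fit (the model diverges at zero
    strength and empty tail bins carry no information about the decaying
    density; R² is still computed over the occupied bins fitted).
    Initial values come from a log-domain linear pre-fit, so the result
    is deterministic.  Raises ``RuntimeError`` with diagnostics if the
    optimizer fails.
    """
    w = hist.centers
    f = hist.mean_frequency
    keep = f > 0
    if keep.sum() < 5:
        raise ValueError("need at least 5 occupied bins")
    w, f = w[keep], f[keep]
    n = max(hist.n_total, 2)
    expo = 1.0 - 1.0 / n

    # log-linear pre-fit: log f + expo*log w = log C - lambda * w
    z = np.log(f) + expo * np.log(w)
    slope, intercept = np.polyfit(w, z, 1)
    lam0 = max(-slope, 1e-6)
    c0 = np.exp(intercept)

    def model(p):
        logc, lam = p
        return np.exp(logc) * np.exp(-lam * w) / w ** expo

    def resid(p):
        return model(p) - f

    res = optimize.least_squares(resid, x0=[np.log(c0), lam0], method="lm",
                                 max_nfev=10000)
    if not res.success:
        raise RuntimeError(f"modified-Boltzmann fit failed: {res.message}; "
                           f"best params {res.x}, cost {res.cost:.4g}")
    logc, lam = res.x
    fhat = model(res.x)
    ss_res = float(np.sum((f - fhat) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    # F-test of the 2-parameter regression against the mean-only model
    k, m = 2, len(f)
    if m > k and ss_res > 0:
        fstat = ((ss_tot - ss_res) / (k - 1)) / (ss_res / (m - k))
        pval = float(stats.f.sf(fstat, k - 1, m - k))
    else:
        pval = 0.0
    return BoltzmannFit(A=float(np.exp(logc)), a=1.0, beta=float(lam), n=n,
                        r_squared=r2, fit_pvalue=pval,
                        residual_rms=float(np.sqrt(np.mean((f - fhat) ** 2))))


def residual_summary(results: list[TrainResult]) -> pd.DataFrame:
    """Pre-training / post-training / verification errors per trial.

    Appends group mean and SD rows.  Raises if a converged trial failed
    to reduce its error below the pre-training level.
    """
    rows = []
    for k, r in enumerate(results):
        rows.append({
            "trial": k,
            "pre_E": r.residuals.get("pre_training", np.nan),
            "post_E": r.residuals.get("post_training", np.nan),
            "verification_E": r.residuals.get("verification", np.nan),
            "converged": r.converged,
        })
        if r.converged and not rows[-1]["post_E"] < rows[-1]["pre_E"]:
            raise AssertionError(f"trial {k}: post-training error did not "
                                 "improve on pre-training")
    df = pd.DataFrame(rows).set_index("trial")
    stats_rows = df[["pre_E", "post_E", "verification_E"]].agg(["mean", "std"])
    stats_rows["converged"] = ""
    return pd.concat([df, stats_rows])
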