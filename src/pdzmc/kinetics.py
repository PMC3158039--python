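"""Ensemble relaxation analysis for MC kinetics runs.

Peptides start in random conformations away from the receptor surface
and relax toward binding under small-step fixed-temperature MC.  The
ensemble mean of a binding observable against MC steps is fitted to a
single exponential a + b exp(-t / tau); tau is the relaxation time in
units of elementary MC steps (it carries no rigorous physical-time
meaning, but its ratio between systems ranks their binding kinetics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .sampling import Trajectory

__all__ = [
    "RelaxationCurve",
    "ExponentialFit",
    "relaxation_curve",
    "fit_single_exponential",
    "compare_relaxation",
]


@dataclass(frozen=True)
class RelaxationCurve:
    """Pointwise ensemble mean and standard error of an observable."""

    steps: np.ndarray
    means: np.ndarray
    errors: np.ndarray  #: across-run standard errors of the mean
    n_runs: int
    observable: str = ""

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("relaxation analysis needs at least 2 runs")
        s = np.asarray(self.steps, dtype=float)
        if (np.diff(s) <= 0).any():
            raise ValueError("step grid must be strictly increasing")


@dataclass(frozen=True)
class ExponentialFit:
    """Parameters of a + b exp(-t/tau) with errors."""

    a: float  #: asymptote (observable units)
    b: float  #: amplitude
    tau: float  #: relaxation time (MC steps), > 0
    errors: dict = field(default_factory=dict)
    residual: float = np.nan
    converged: bool = True
    flags: tuple[str, ...] = ()

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.a + self.b * np.exp(-np.asarray(t, dtype=float) / self.tau)


def relaxation_curve(
    ensemble: Sequence[Trajectory] | np.ndarray,
    observable: str | Callable[[pd.DataFrame], np.ndarray] = "E_hb_inter",
    steps: np.ndarray | None = None,
    normalize_by: float = 1.0,
) -> RelaxationCurve:
    """Pointwise mean and standard error across an ensemble of runs.

    *ensemble* is either a list of kinetics trajectories sharing one
    recording grid, or a raw (n_runs, n_points) array (with *steps*).
    ``normalize_by`` divides the observable (e.g. the number of peptide
    residues for per-residue energies).
    """
    if isinstance(ensemble, np.ndarray):
        if steps is None:
            raise ValueError("raw ensembles need an explicit step grid")
        values = np.asarray(ensemble, dtype=float)
        name = "raw"
    else:
        trajs = list(ensemble)
        if not trajs:
            raise ValueError("empty ensemble")
        steps = trajs[0].df["step"].to_numpy()
        rows = []
        for traj in trajs:
            s = traj.df["step"].to_numpy()
            if len(s) != len(steps) or (s != steps).any():
                raise ValueError("all runs must share the recording step grid")
            if callable(observable):
                rows.append(np.asarray(observable(traj.df), dtype=float))
            else:
                rows.append(traj.df[observable].to_numpy(dtype=float))
        values = np.vstack(rows)
        name = observable if isinstance(observable, str) else "custom"
    values = values / normalize_by
    n = values.shape[0]
    if n < 2:
        raise ValueError("relaxation analysis needs at least 2 runs")
    return RelaxationCurve(
        steps=np.asarray(steps, dtype=float),
        means=values.mean(axis=0),
        errors=values.std(axis=0, ddof=1) / math.sqrt(n),
        n_runs=n,
        observable=name,
    )


def fit_single_exponential(curve: RelaxationCurve) -> ExponentialFit:
    """Weighted least-squares fit of a + b exp(-t/tau).

    The initial tau comes from a log-linear regression of |X - X_inf|
    with X_inf estimated from the curve tail; constant curves leave b
    unidentifiable and are flagged.
    """
    t = curve.steps
    x = curve.means
    if len(t) < 5:
        raise ValueError("exponential fit needs at least 5 grid points")
    span = x.max() - x.min()
    if span == 0:
        return ExponentialFit(
            a=float(x[0]), b=0.0, tau=np.nan,
            converged=False, flags=("constant curve: b unidentifiable",),
        )
    tail = x[-max(3, len(x) // 10):].mean()
    resid = np.abs(x - tail)
    ok = resid > 1e-12 * span
    if ok.sum() >= 3:
        slope, icept = np.polyfit(t[ok], np.log(resid[ok]), 1)
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
        b0 = math.copysign(math.exp(icept), x[0] - tail)
    else:
        tau0 = (t[-1] - t[0]) / 3.0
        b0 = x[0] - tail
    tau0 = min(max(tau0, (t[1] - t[0]) / 10.0), 100.0 * (t[-1] - t[0]))
    sigma = np.where(curve.errors > 0, curve.errors, np.nan)
    if np.isnan(sigma).any():
        sigma = None

    def model(tt, a, b, tau):
        return a + b * np.exp(-tt / tau)

    try:
        popt, pcov = curve_fit(
            model, t, x, p0=(tail, b0, tau0), sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=((-np.inf, -np.inf, (t[1] - t[0]) * 1e-6), (np.inf, np.inf, np.inf)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return ExponentialFit(
            a=np.nan, b=np.nan, tau=np.nan, converged=False,
            flags=(f"fit failed: {exc}",),
        )
    perr = np.sqrt(np.diag(pcov))
    r = x - model(t, *popt)
    if sigma is not None:
        r = r / sigma
    return ExponentialFit(
        a=float(popt[0]), b=float(popt[1]), tau=float(popt[2]),
        errors={"a": perr[0], "b": perr[1], "tau": perr[2]},
        residual=float(np.sqrt(np.mean(r**2))),
    )


def compare_relaxation(
    fit_a: ExponentialFit, fit_b: ExponentialFit, sigma_threshold: float = 2.0
) -> dict:
    """Relaxation-time ratio tau_A / tau_B with first-order error propagation.

    Flags the difference as significant when |ratio - 1| exceeds
    *sigma_threshold* propagated standard errors.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both exponential fits must have converged")
    ratio = fit_a.tau / fit_b.tau
    ra = fit_a.errors.get("tau", 0.0) / fit_a.tau
    rb = fit_b.errors.get("tau", 0.0) / fit_b.tau
    err = abs(ratio) * math.sqrt(ra * ra + rb * rb)
    significant = err > 0 and abs(ratio - 1.0) > sigma_threshold * err
    return {
        "ratio": ratio,
        "error": err,
        "significant": bool(significant),
        "sigma_threshold": sigma_threshold,
    }
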