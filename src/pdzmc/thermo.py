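"""Equilibrium analysis of binding trajectories.

Thermal averages with jackknife errors, four-parameter two-state fits
of binding curves, specific heat from energy fluctuations, bound-state
probability curves, free-energy surfaces F = -T ln P over (E, X) with
X an order parameter, single-histogram reweighting, and free-energy
barrier extraction from 1D profiles.

Two-state model.  An observable X measured against temperature is
fitted to

    X(T) = X_U + (X_B - X_U) * p_B(T),
    p_B(T) = 1 / (1 + exp[-dE (1/T - 1/Tm)]),

with exactly four free parameters: the unbound and bound baselines
X_U, X_B, the energy difference dE = E_U - E_B >= 0 between the two
states, and the midpoint temperature Tm at which both states are
equally populated (k_B = 1 throughout).  The fitted curve passes
through (X_U + X_B)/2 at Tm by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit

from .order_params import DEFAULT_BOUND_RCUT
from .sampling import Trajectory

__all__ = [
    "BindingCurve",
    "TwoStateFit",
    "FreeEnergySurface",
    "BarrierResult",
    "thermal_average",
    "binding_curve",
    "fit_two_state",
    "two_state_model",
    "specific_heat",
    "cv_from_samples",
    "reweighted_mean",
    "p_bound_curve",
    "free_energy_surface",
    "reweight_single_histogram",
    "barrier_height",
]

DEFAULT_EQUILIBRATION = 0.2  #: fraction of each run discarded as equilibration
JACKKNIFE_BLOCKS = 20  #: contiguous blocks for single-run jackknife


@dataclass(frozen=True)
class BindingCurve:
    """Mean observable vs temperature with jackknife standard errors."""

    temperatures: np.ndarray
    means: np.ndarray
    errors: np.ndarray
    observable: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        m = np.asarray(self.means, dtype=float)
        e = np.asarray(self.errors, dtype=float)
        if not (t.shape == m.shape == e.shape):
            raise ValueError("temperatures, means and errors must align")
        if (e < 0).any():
            raise ValueError("errors must be non-negative")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "errors", e)


@dataclass(frozen=True)
class TwoStateFit:
    """Fitted two-state parameters (X_U, X_B, dE, Tm) with errors."""

    X_U: float
    X_B: float
    dE: float  #: E_U - E_B >= 0, model units
    Tm: float  #: midpoint temperature, model units
    errors: dict = field(default_factory=dict)
    residual: float = np.nan
    converged: bool = True
    flags: tuple[str, ...] = ()

    def predict(self, T: np.ndarray) -> np.ndarray:
        return two_state_model(np.asarray(T, dtype=float), self.X_U, self.X_B, self.dE, self.Tm)


def two_state_model(T, X_U, X_B, dE, Tm):
    """Two-state observable curve; bound state dominates below Tm."""
    p_b = 1.0 / (1.0 + np.exp(-dE * (1.0 / T - 1.0 / Tm)))
    return X_U + (X_B - X_U) * p_b


def _equilibrated(values: np.ndarray, equilibration: float) -> np.ndarray:
    n0 = int(len(values) * equilibration)
    return values[n0:]


def _jackknife(block_means: np.ndarray) -> tuple[float, float]:
    """Delete-one jackknife mean and standard error over blocks/runs."""
    n = len(block_means)
    if n < 2:
        raise ValueError("jackknife needs at least 2 blocks or runs")
    total = block_means.sum()
    loo = (total - block_means) / (n - 1)
    mean = float(block_means.mean())
    err = math.sqrt((n - 1) / n * float(((loo - loo.mean()) ** 2).sum()))
    return mean, err


def _blocks_from_run(values: np.ndarray, n_blocks: int) -> np.ndarray:
    usable = len(values) - len(values) % n_blocks
    if usable < n_blocks:
        return values.reshape(-1, 1).mean(axis=1)  # degenerate: one value per block
    return values[:usable].reshape(n_blocks, -1).mean(axis=1)


def _per_run_samples(
    trajs: Sequence[Trajectory],
    observable: str | Callable[[pd.DataFrame], np.ndarray],
    T: float | None,
    equilibration: float,
) -> list[np.ndarray]:
    out = []
    for traj in trajs:
        df = traj.df
        if T is not None:
            df = df[np.isclose(df["T"].to_numpy(), T)]
        if callable(observable):
            vals = np.asarray(observable(df), dtype=float)
        else:
            vals = df[observable].to_numpy(dtype=float)
        vals = _equilibrated(vals, equilibration)
        if len(vals):
            out.append(vals)
    return out


def thermal_average(
    trajs: Sequence[Trajectory] | Trajectory,
    observable: str | Callable[[pd.DataFrame], np.ndarray],
    T: float | None = None,
    equilibration: float = DEFAULT_EQUILIBRATION,
) -> tuple[float, float]:
    """Mean of an observable with a delete-one jackknife error.

    The jackknife unit is the independent run when two or more runs are
    given, otherwise ``JACKKNIFE_BLOCKS`` contiguous blocks of the
    single run.  *observable* is a trajectory column name or a callable
    mapping the record frame to values; *T* restricts the records to
    one temperature (for simulated-tempering data).
    """
    trajs = [trajs] if isinstance(trajs, Trajectory) else list(trajs)
    samples = _per_run_samples(trajs, observable, T, equilibration)
    if not samples:
        raise ValueError("no samples after equilibration/temperature selection")
    if len(samples) >= 2:
        block_means = np.array([s.mean() for s in samples])
    else:
        block_means = _blocks_from_run(samples[0], JACKKNIFE_BLOCKS)
        if len(block_means) < 2:
            raise ValueError("insufficient data for jackknife blocking")
    return _jackknife(block_means)


def binding_curve(
    trajs: Sequence[Trajectory] | Trajectory,
    observable: str | Callable[[pd.DataFrame], np.ndarray],
    temperatures: Sequence[float] | None = None,
    equilibration: float = DEFAULT_EQUILIBRATION,
    name: str | None = None,
) -> BindingCurve:
    """Thermodynamic average of an observable as a function of temperature."""
    trajs = [trajs] if isinstance(trajs, Trajectory) else list(trajs)
    if temperatures is None:
        temperatures = sorted({t for traj in trajs for t in traj.temperatures})
    means, errs, kept = [], [], []
    for T in temperatures:
        try:
            m, e = thermal_average(trajs, observable, T=T, equilibration=equilibration)
        except ValueError:
            continue  # temperature barely visited (e.g. early ST records)
        kept.append(T)
        means.append(m)
        errs.append(e)
    if not kept:
        raise ValueError("no temperature had sufficient data")
    temperatures = kept
    return BindingCurve(
        temperatures=np.asarray(temperatures, dtype=float),
        means=np.asarray(means),
        errors=np.asarray(errs),
        observable=name or (observable if isinstance(observable, str) else "custom"),
    )


def fit_two_state(curve: BindingCurve) -> TwoStateFit:
    """Weighted least-squares fit of the 4-parameter two-state expression.

    Curve errors are used as weights where available.  Degenerate flat
    curves leave dE unidentifiable and are flagged rather than fitted.
    """
    t = curve.temperatures
    x = curve.means
    if len(t) < 5:
        raise ValueError("two-state fit needs at least 5 temperature points")
    span = x.max() - x.min()
    if span == 0 or not np.isfinite(span):
        return TwoStateFit(
            X_U=float(x[0]), X_B=float(x[0]), dE=np.nan, Tm=np.nan,
            converged=False, flags=("flat-curve: dE unidentifiable",),
        )
    sigma = np.where(curve.errors > 0, curve.errors, np.nanmax(curve.errors) or 1.0)
    if (sigma == 0).all():
        sigma = None
    # initial guess: baselines from the ends, Tm from the interpolated
    # half-transition crossing (robust for sharp, step-like curves)
    order = np.argsort(t)
    ts, xs_ = t[order], x[order]
    x_lo, x_hi = xs_[0], xs_[-1]
    mid = 0.5 * (x_lo + x_hi)
    tm0 = float(ts[np.argmin(np.abs(xs_ - mid))])
    crossing = np.flatnonzero((xs_[:-1] - mid) * (xs_[1:] - mid) <= 0)
    if len(crossing):
        i = crossing[0]
        if xs_[i + 1] != xs_[i]:
            frac = (mid - xs_[i]) / (xs_[i + 1] - xs_[i])
            tm0 = float(ts[i] + frac * (ts[i + 1] - ts[i]))
    p0 = (x_hi, x_lo, 20.0, tm0)
    try:
        popt, pcov = curve_fit(
            two_state_model, t, x, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            bounds=((-np.inf, -np.inf, 0.0, t.min() * 0.5), (np.inf, np.inf, np.inf, t.max() * 1.5)),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        return TwoStateFit(
            X_U=np.nan, X_B=np.nan, dE=np.nan, Tm=np.nan,
            converged=False, flags=(f"fit failed: {exc}",),
        )
    perr = np.sqrt(np.diag(pcov))
    resid = x - two_state_model(t, *popt)
    if sigma is not None:
        resid = resid / sigma
    return TwoStateFit(
        X_U=float(popt[0]), X_B=float(popt[1]), dE=float(popt[2]), Tm=float(popt[3]),
        errors={"X_U": perr[0], "X_B": perr[1], "dE": perr[2], "Tm": perr[3]},
        residual=float(np.sqrt(np.mean(resid**2))),
    )


def cv_from_samples(
    energies: np.ndarray,
    T: float,
    n_res: int,
    weights: np.ndarray | None = None,
) -> float:
    """Specific heat per residue from (optionally weighted) energy samples.

    Cv = (<E^2> - <E>^2) / (N T^2) with k_B = 1.  With *weights* this
    evaluates the fluctuation formula under an arbitrary distribution
    (e.g. exact enumeration weights, or reweighting factors).
    """
    e = np.asarray(energies, dtype=float)
    if weights is None:
        e1, e2 = e.mean(), (e * e).mean()
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        e1, e2 = float(w @ e), float(w @ (e * e))
    return (e2 - e1 * e1) / (n_res * T * T)


def specific_heat(
    trajs: Sequence[Trajectory] | Trajectory,
    n_res: int,
    temperatures: Sequence[float] | None = None,
    equilibration: float = DEFAULT_EQUILIBRATION,
) -> BindingCurve:
    """Specific heat per amino acid from total-energy fluctuations.

    Cv(T) = (<E^2> - <E>^2) / (N T^2) with k_B = 1 and N the total
    number of amino acids; jackknife errors over runs or blocks.
    """
    trajs = [trajs] if isinstance(trajs, Trajectory) else list(trajs)
    if temperatures is None:
        temperatures = sorted({t for traj in trajs for t in traj.temperatures})
    means, errs, kept = [], [], []
    for T in temperatures:
        samples = _per_run_samples(trajs, "E_total", T, equilibration)
        if not samples:
            continue
        if len(samples) >= 2:
            cvs = np.array([s.var() / (n_res * T * T) for s in samples])
        else:
            s = samples[0]
            blocks = np.array_split(s, JACKKNIFE_BLOCKS)
            cvs = np.array([b.var() / (n_res * T * T) for b in blocks if len(b) > 1])
        if len(cvs) < 2:
            continue  # temperature barely visited
        m, e = _jackknife(cvs)
        kept.append(T)
        means.append(m)
        errs.append(e)
    if not kept:
        raise ValueError("specific heat needs >= 2 runs or blocks at some temperature")
    return BindingCurve(
        temperatures=np.asarray(kept, dtype=float),
        means=np.asarray(means), errors=np.asarray(errs), observable="Cv",
    )


def p_bound_curve(
    trajs: Sequence[Trajectory] | Trajectory,
    r_cut: float = DEFAULT_BOUND_RCUT,
    temperatures: Sequence[float] | None = None,
    equilibration: float = DEFAULT_EQUILIBRATION,
) -> BindingCurve:
    """Probability of occupying the binding pocket vs temperature.

    A frame is bound when its recorded non-optimized all-heavy RMSD is
    below *r_cut* (6 Angstrom default; 9 Angstrom for the sensitivity
    check, which can only increase the probability).
    """
    return binding_curve(
        trajs,
        lambda df: (df["rmsd"].to_numpy() < r_cut).astype(float),
        temperatures=temperatures,
        equilibration=equilibration,
        name=f"P_bound(rmsd<{r_cut})",
    )


@dataclass(frozen=True)
class FreeEnergySurface:
    """Binned free-energy surface F = -T ln P, minimum shifted to zero."""

    e_edges: np.ndarray
    x_edges: np.ndarray
    F: np.ndarray  #: (n_e_bins, n_x_bins), inf on unoccupied bins
    T: float
    x_name: str
    profile_x: np.ndarray = field(default=None)  #: 1D marginal profile over X
    profile_e: np.ndarray = field(default=None)  #: 1D marginal profile over E

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def e_centers(self) -> np.ndarray:
        return 0.5 * (self.e_edges[:-1] + self.e_edges[1:])


def _fd_bins(values: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis bin edges with sane fallbacks."""
    v = np.asarray(values, dtype=float)
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    if iqr <= 0:
        return np.linspace(v.min() - 0.5, v.max() + 0.5, 21)
    width = 2 * iqr / len(v) ** (1 / 3)
    n = max(10, min(200, int(np.ceil((v.max() - v.min()) / width))))
    return np.linspace(v.min(), v.max() + 1e-9, n + 1)


DEFAULT_BIN_WIDTH = {"dcm": 0.25, "Q": 0.04}


def free_energy_surface(
    samples: pd.DataFrame,
    T: float,
    x: str = "dcm",
    weights: np.ndarray | None = None,
    x_bin_width: float | None = None,
) -> FreeEnergySurface:
    """2D free-energy surface over (total energy, order parameter).

    F = -T ln P(E, X) up to an additive constant (the minimum is
    shifted to zero); unoccupied bins are +inf.  1D profiles come from
    the corresponding marginal distributions.  *samples* must be drawn
    at the single temperature *T* (or reweighted to it, via *weights*).
    """
    if len(samples) == 0:
        raise ValueError("no samples")
    e = samples["E_total"].to_numpy(dtype=float)
    xv = samples[x].to_numpy(dtype=float)
    e_edges = _fd_bins(e)
    width = x_bin_width or DEFAULT_BIN_WIDTH.get(x, 0.25)
    lo = math.floor(xv.min() / width) * width
    hi = math.ceil(xv.max() / width) * width + 1e-9
    x_edges = np.arange(lo, hi + width, width)
    hist2, _, _ = np.histogram2d(e, xv, bins=(e_edges, x_edges), weights=weights)
    hist_x, _ = np.histogram(xv, bins=x_edges, weights=weights)
    hist_e, _ = np.histogram(e, bins=e_edges, weights=weights)

    def to_f(hist: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            f = np.where(hist > 0, -T * np.log(hist), np.inf)
        return f - f.min()

    return FreeEnergySurface(
        e_edges=e_edges, x_edges=x_edges, F=to_f(hist2), T=T, x_name=x,
        profile_x=to_f(hist_x), profile_e=to_f(hist_e),
    )


def reweight_single_histogram(
    samples: pd.DataFrame,
    T_from: float,
    T_to: float,
    min_ess_fraction: float = 0.05,
) -> tuple[np.ndarray, float, list[str]]:
    """Boltzmann single-histogram reweighting from T_from to T_to.

    Returns normalized weights proportional to exp[-E (1/T_to -
    1/T_from)], the effective sample size, and any flags.  At
    T_to == T_from the weights are exactly uniform.
    """
    e = samples["E_total"].to_numpy(dtype=float)
    if len(e) == 0:
        raise ValueError("no samples to reweight")
    dbeta = 1.0 / T_to - 1.0 / T_from
    logw = -e * dbeta
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    ess = 1.0 / float((w**2).sum())
    flags = []
    if ess < min_ess_fraction * len(e):
        flags.append(
            f"effective sample size {ess:.1f} below floor "
            f"({min_ess_fraction:.0%} of {len(e)})"
        )
    return w, ess, flags


def reweighted_mean(
    samples: pd.DataFrame, observable: str, T_from: float, T_to: float
) -> float:
    """Reweighted expectation of a trajectory column at temperature T_to."""
    w, _, _ = reweight_single_histogram(samples, T_from, T_to)
    return float(np.sum(w * samples[observable].to_numpy(dtype=float)))


@dataclass(frozen=True)
class BarrierResult:
    """Barrier between the bound basin and the unbound basin of a 1D profile."""

    delta_f: float  #: F(TS) - F(bound minimum), >= 0; nan if no barrier
    ts_x: float  #: transition-state location along X
    bound_x: float  #: bound-minimum location
    unbound_x: float  #: unbound-minimum location
    has_barrier: bool


def barrier_height(
    x: np.ndarray,
    F: np.ndarray,
    bound_region: tuple[float, float],
    smooth_sigma: float = 1.0,
) -> BarrierResult:
    """Free-energy difference between the transition state and the bound state.

    The bound basin B is the deepest minimum inside *bound_region*; the
    unbound basin is the deepest minimum outside it; the transition
    state is the highest point on the profile between the two.  Light
    Gaussian smoothing (in bins) is used only to locate the extrema;
    the reported delta F uses the unsmoothed values.  A monotone
    profile yields a no-barrier result, not an exception.
    """
    x = np.asarray(x, dtype=float)
    F = np.asarray(F, dtype=float)
    finite = np.isfinite(F)
    if finite.sum() < 3:
        raise ValueError("profile has fewer than 3 occupied bins")
    xs, fs = x[finite], F[finite]
    f_loc = gaussian_filter1d(fs, smooth_sigma) if smooth_sigma > 0 else fs
    in_b = (xs >= bound_region[0]) & (xs <= bound_region[1])
    if not in_b.any() or in_b.all():
        return BarrierResult(np.nan, np.nan, np.nan, np.nan, has_barrier=False)
    ib = np.flatnonzero(in_b)[np.argmin(f_loc[in_b])]
    iu = np.flatnonzero(~in_b)[np.argmin(f_loc[~in_b])]
    lo, hi = (ib, iu) if ib < iu else (iu, ib)
    if hi - lo < 2:
        return BarrierResult(np.nan, np.nan, float(xs[ib]), float(xs[iu]), has_barrier=False)
    seg = slice(lo + 1, hi)
    its = lo + 1 + int(np.argmax(f_loc[seg]))
    delta = float(fs[its] - fs[ib])
    # monotone profile: the "barrier" top coincides with an endpoint level
    if f_loc[its] <= max(f_loc[ib], f_loc[iu]) + 1e-12:
        return BarrierResult(np.nan, np.nan, float(xs[ib]), float(xs[iu]), has_barrier=False)
    return BarrierResult(
        delta_f=delta, ts_x=float(xs[its]), bound_x=float(xs[ib]),
        unbound_x=float(xs[iu]), has_barrier=True,
    )
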