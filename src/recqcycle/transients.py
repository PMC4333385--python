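"""Simulation and reduction of the transient and steady-state experiments.

Covers the stopped-flow md-nucleotide binding and chasing transients, the
quenched-flow fraction-cleaved time courses, reporter-based Pi-release
progress curves and the steady-state rate-vs-[ATP] analysis, together with
the fitting primitives used to reduce them (single exponential, k_obs vs
concentration line, Hill curve, burst back-extrapolation).

md-nucleotide binding transients are generated, by default, from the
two-state relaxation model that the field uses to interpret them: the
observed fluorescence rise is single-exponential with

    k_obs = k1*[mdATP] + k_m1 + k2        (mdATP; hydrolysis terminates the
                                           observed pre-hydrolytic complex)
    k_obs = k_m4*[mdADP] + k4             (mdADP)

so a linear fit of k_obs against concentration returns the association rate
constant as the slope and the breakdown-pathway sum as the intercept.  The
full four-state simulation is available via ``model="full"`` for
cross-checking; see docs/methods.md for where the two routes diverge.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lmfit import Model
from scipy.linalg import expm
from scipy.stats import linregress

from .scheme import (
    RateConstantSet,
    ReactionMixture,
    STATE_INDEX,
    cycle_flux,
    integrate_scheme,
    rate_matrix,
)

__all__ = [
    "TransientTrace",
    "ExpFitResult",
    "KobsConcSeries",
    "LineFitResult",
    "SteadyStateCurve",
    "HillFitResult",
    "FitError",
    "simulate_md_binding",
    "simulate_md_chase",
    "simulate_quenched_flow",
    "simulate_pi_release",
    "fit_single_exponential",
    "fit_kobs_line",
    "binding_kobs_series",
    "steady_state_curve",
    "fit_hill",
    "burst_amplitude",
]

OBSERVABLES = (
    "md_fluorescence",
    "fraction_cleaved",
    "pi_released",
    "nadh_absorbance_rate",
    "unknown",
)


class FitError(RuntimeError):
    """A least-squares reduction failed to converge or was degenerate."""


@dataclass
class TransientTrace:
    """A sampled time course of one observable.

    ``signal`` is in uM for concentration-like observables
    (``pi_released``), dimensionless for ``fraction_cleaved``, and in
    bound-enzyme uM (proportional to fluorescence) for
    ``md_fluorescence``.  ``meta`` carries concentrations, condition, seed
    and noise metadata.
    """

    time: np.ndarray
    signal: np.ndarray
    observable: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if len(self.time) and np.any(np.diff(self.time) <= 0):
            raise ValueError("time points must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal values must be finite")
        if self.observable not in OBSERVABLES:
            raise ValueError(f"unknown observable id {self.observable!r}")


@dataclass
class ExpFitResult:
    k_obs: float
    amplitude: float
    offset: float
    residual_norm: float
    k_obs_stderr: float | None = None


@dataclass
class KobsConcSeries:
    """Observed rate constants against pseudo-first-order ligand concentration."""

    conc: np.ndarray
    k_obs: np.ndarray
    condition: str = "dna_bound"

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if self.conc.shape != self.k_obs.shape:
            raise ValueError("conc and k_obs must have equal length")


@dataclass
class LineFitResult:
    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float


@dataclass
class SteadyStateCurve:
    atp: np.ndarray
    rate: np.ndarray  # per enzyme, s^-1

    def __post_init__(self) -> None:
        self.atp = np.asarray(self.atp, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if np.any(self.rate < -1e-12):
            raise ValueError("steady-state rates must be >= 0")


@dataclass
class HillFitResult:
    k_cat: float
    K_atp: float
    n: float
    k_cat_stderr: float | None = None
    K_atp_stderr: float | None = None
    n_stderr: float | None = None


def _expected_kobs(rates: RateConstantSet, nucleotide: str, conc: float) -> float:
    if nucleotide == "mdATP":
        return rates.k1 * conc + rates.k_m1 + rates.k2
    if nucleotide == "mdADP":
        return rates.k_m4 * conc + rates.k4
    raise ValueError("nucleotide must be 'mdATP' or 'mdADP'")


def _default_binding_grid(k_obs: float, n: int = 60) -> np.ndarray:
    # span three half-lives of the expected relaxation (the fit window used
    # throughout); first point just off zero as a stopped-flow record would be
    t_end = 3.0 * math.log(2.0) / k_obs
    return np.linspace(t_end / n, t_end, n)


def simulate_md_binding(rates: RateConstantSet, nucleotide: str, conc: float,
                        enzyme: float = 1.0, t_grid: Sequence[float] | None = None,
                        model: str = "relaxation") -> TransientTrace:
    """Fluorescence transient of md-nucleotide binding under excess nucleotide.

    ``model="relaxation"`` (default) produces the exactly single-exponential
    two-state relaxation; ``model="full"`` integrates the four-state scheme
    at fixed ligand (signal = total md-bound enzyme).  A
    ``pseudo_first_order_warning`` is set in ``meta`` when the nucleotide is
    not in sufficient excess over the enzyme.
    """
    if conc <= 0 or enzyme <= 0:
        raise ValueError("conc and enzyme must be positive")
    k_obs = _expected_kobs(rates, nucleotide, conc)
    t = (np.asarray(t_grid, dtype=float) if t_grid is not None
         else _default_binding_grid(k_obs))
    meta = {
        "nucleotide": nucleotide, "conc_uM": conc, "enzyme_uM": enzyme,
        "condition": rates.condition, "model": model,
    }
    if conc < 5.0 * enzyme:
        meta["pseudo_first_order_warning"] = True
    if model == "relaxation":
        if nucleotide == "mdATP":
            amp = enzyme * rates.k1 * conc / k_obs
        else:
            amp = enzyme * rates.k_m4 * conc / k_obs
        signal = amp * (1.0 - np.exp(-k_obs * t))
    elif model == "full":
        if nucleotide == "mdADP":
            # hydrolysis bypassed: direct E <-> D two-state system
            ko = rates.k_m4 * conc + rates.k4
            amp = enzyme * rates.k_m4 * conc / ko
            signal = amp * (1.0 - np.exp(-ko * t))
        else:
            A = rate_matrix(rates, atp=conc)
            A = A.T - np.diag(A.sum(axis=1))
            p0 = np.array([1.0, 0.0, 0.0, 0.0])
            bound = np.array([(expm(A * ti) @ p0)[1:].sum() for ti in t])
            signal = enzyme * bound
    else:
        raise ValueError("model must be 'relaxation' or 'full'")
    return TransientTrace(t, signal, "md_fluorescence", meta)


def simulate_md_chase(rates: RateConstantSet, mdadp_conc: float, enzyme: float,
                      chase_atp: float, t_grid: Sequence[float] | None = None) -> TransientTrace:
    """mdADP displacement ('chasing') transient.

    The enzyme.mdADP complex (pre-equilibrated at ``mdadp_conc``) is mixed
    with excess unlabeled ATP; the md-fluorescence decays as mdADP is
    released and its rebinding is suppressed by ATP competition for the apo
    enzyme.  ``chase_atp=inf`` gives the exact single-exponential decay at
    k4.  Raises ValueError for a zero chase (no chase condition).
    """
    if chase_atp <= 0:
        raise ValueError("chase requires a positive unlabeled-ATP concentration")
    if mdadp_conc <= 0 or enzyme <= 0:
        raise ValueError("mdadp_conc and enzyme must be positive")
    Kd = rates.k4 / rates.k_m4
    bound0 = enzyme * mdadp_conc / (mdadp_conc + Kd)
    if t_grid is None:
        t_end = 5.0 / rates.k4
        t_grid = np.linspace(t_end / 80, t_end, 80)
    t = np.asarray(t_grid, dtype=float)
    meta = {"mdadp_uM": mdadp_conc, "enzyme_uM": enzyme, "chase_atp_uM": chase_atp,
            "condition": rates.condition}
    if math.isinf(chase_atp):
        signal = bound0 * np.exp(-rates.k4 * t)
        return TransientTrace(t, signal, "md_fluorescence", meta)
    # five-state linear system: D_md, E, T, DPi, D (unlabeled), with free
    # mdADP clamped at its pre-mix concentration (excess over enzyme)
    k = rates
    A = np.zeros((5, 5))  # A[i, j]: rate j -> i on columns (dp/dt = A p)
    def add(i, j, rate):  # transition j -> i
        A[i, j] += rate
        A[j, j] -= rate
    Dmd, E, T, DPi, D = range(5)
    add(E, Dmd, k.k4)
    add(Dmd, E, k.k_m4 * mdadp_conc)
    add(T, E, k.k1 * chase_atp)
    add(E, T, k.k_m1)
    add(DPi, T, k.k2)
    add(T, DPi, k.k_m2)
    add(D, DPi, k.k3)
    add(E, D, k.k4)
    p0 = np.zeros(5)
    p0[Dmd] = bound0
    p0[E] = enzyme - bound0
    signal = np.array([(expm(A * ti) @ p0)[Dmd] for ti in t])
    return TransientTrace(t, signal, "md_fluorescence", meta)


def simulate_quenched_flow(rates: RateConstantSet, enzyme: float, atp: float,
                           time_points: Sequence[float]) -> TransientTrace:
    """Fraction of ATP chemically cleaved at acid-quench time points.

    The acid quench counts every cleaved gamma-phosphate: enzyme-bound
    ADP.Pi plus all released Pi, divided by total ATP.
    """
    if atp <= 0:
        raise ValueError("quenched-flow requires atp > 0")
    tp = np.asarray(time_points, dtype=float)
    if np.any(tp < 0):
        raise ValueError("time points must be >= 0")
    grid = tp if tp[0] == 0 else np.concatenate([[0.0], tp])
    mixture = ReactionMixture(enzyme_total=enzyme, atp=atp)
    traj = integrate_scheme(rates, mixture, grid)
    cleaved = (traj.state("DPi") + traj.pi_cum) / atp
    if tp[0] != 0:
        cleaved = cleaved[1:]
    cleaved = np.clip(cleaved, 0.0, None)
    meta = {"enzyme_uM": enzyme, "atp_uM": atp, "condition": rates.condition}
    return TransientTrace(tp, cleaved, "fraction_cleaved", meta)


def simulate_pi_release(rates: RateConstantSet, enzyme: float, atp: float,
                        t_grid: Sequence[float],
                        reporter_conc: float | None = None) -> TransientTrace:
    """Reporter-captured Pi progress curve (uM) with irreversible capture.

    Emulates the fluorescent phosphate-binding-protein assay: every released
    Pi is captured instantly and cannot rebind.  When ``reporter_conc`` is
    given and the captured Pi exceeds it, a ``reporter_saturated`` warning
    flag is set in ``meta``.
    """
    if atp <= 0 or enzyme <= 0:
        raise ValueError("enzyme and atp must be positive")
    mixture = ReactionMixture(enzyme_total=enzyme, atp=atp, sequester_pi=True,
                              reporter_capacity=reporter_conc)
    traj = integrate_scheme(rates, mixture, np.asarray(t_grid, dtype=float))
    meta = {"enzyme_uM": enzyme, "atp_uM": atp, "condition": rates.condition}
    if reporter_conc is not None and np.any(traj.pi_captured > reporter_conc):
        meta["reporter_saturated"] = True
    t = traj.t
    signal = traj.pi_captured
    if t[0] == 0 and len(t) > 2:
        pass  # keep the zero point; fits handle it
    return TransientTrace(t, signal, "pi_released", meta)


def fit_single_exponential(trace: TransientTrace) -> ExpFitResult:
    """Least-squares single-exponential fit y(t) = offset - amplitude*exp(-k t).

    Rising transients have positive amplitude with offset = plateau;
    decaying transients have negative amplitude.  Requires >= 8 points.
    """
    t, y = trace.time, trace.signal
    if len(t) < 8:
        raise FitError("need at least 8 points for an exponential fit")
    span = float(y.max() - y.min())
    if span == 0 or span < 1e-12 * max(1.0, abs(float(y.mean()))):
        raise FitError("degenerate (constant) trace")
    # initial guesses from the 63%-completion time
    y_inf = float(y[-1])
    amp0 = y_inf - float(y[0])
    target = y[0] + amp0 * (1 - 1 / math.e)
    idx = np.argmin(np.abs(y - target))
    k0 = 1.0 / max(float(t[max(int(idx), 1)]), 1e-9)

    def f(t, k_obs, amplitude, offset):
        return offset - amplitude * np.exp(-k_obs * t)

    model = Model(f)
    params = model.make_params(k_obs=k0, amplitude=amp0, offset=y_inf)
    params["k_obs"].set(min=1e-12)
    try:
        res = model.fit(y, params, t=t)
    except Exception as exc:  # pragma: no cover - lmfit internal failures
        raise FitError(f"exponential fit failed: {exc}") from exc
    if not res.success or not math.isfinite(res.params["k_obs"].value):
        raise FitError(f"exponential fit did not converge: {res.message}")
    k_fit = float(res.params["k_obs"].value)
    if k_fit <= 0:
        raise FitError("fitted k_obs is not positive")
    return ExpFitResult(
        k_obs=k_fit,
        amplitude=float(res.params["amplitude"].value),
        offset=float(res.params["offset"].value),
        residual_norm=float(np.linalg.norm(res.residual)),
        k_obs_stderr=(float(res.params["k_obs"].stderr)
                      if res.params["k_obs"].stderr is not None else None),
    )


def binding_kobs_series(rates: RateConstantSet, nucleotide: str,
                        concs: Sequence[float], enzyme: float = 1.0,
                        model: str = "relaxation") -> KobsConcSeries:
    """Simulate binding transients at several concentrations and fit each."""
    k_obs = []
    for c in concs:
        trace = simulate_md_binding(rates, nucleotide, c, enzyme, model=model)
        k_obs.append(fit_single_exponential(trace).k_obs)
    return KobsConcSeries(np.asarray(concs, float), np.asarray(k_obs),
                          condition=rates.condition)


def fit_kobs_line(series: KobsConcSeries) -> LineFitResult:
    """Ordinary least-squares line through a k_obs vs concentration series.

    The intercept interpretation is left to the caller (k_m1 + k2 for
    mdATP, k4 for mdADP).
    """
    if len(series.conc) < 3:
        raise ValueError("need at least 3 concentrations for a line fit")
    res = linregress(series.conc, series.k_obs)
    return LineFitResult(
        slope=float(res.slope), intercept=float(res.intercept),
        slope_stderr=float(res.stderr) if res.stderr is not None else float("nan"),
        intercept_stderr=(float(res.intercept_stderr)
                          if res.intercept_stderr is not None else float("nan")))


def _linear_window(rates: RateConstantSet, t: np.ndarray) -> np.ndarray:
    """Mask selecting the steady-state linear phase: t >= 5/k2_effective."""
    k2_eff = rates.k2 * rates.k3 / (rates.k3 + rates.k_m2) if (rates.k3 + rates.k_m2) > 0 \
        else rates.k2
    if k2_eff <= 0:
        return np.ones_like(t, dtype=bool)
    return t >= 5.0 / k2_eff


def steady_state_curve(rates: RateConstantSet, atp_concs: Sequence[float],
                       enzyme: float, n_points: int = 40) -> SteadyStateCurve:
    """Steady-state Pi-production rate per enzyme at each ATP concentration.

    Each point simulates a reporter progress curve and takes the slope of
    its linear phase (the pre-steady-state transient, the first 5/k2
    seconds, is excluded).  The trace length is limited so that substrate
    depletion stays below ~5%.
    """
    atp_concs = np.asarray(atp_concs, dtype=float)
    rates_out = np.zeros_like(atp_concs)
    k2_eff = rates.k2 * rates.k3 / (rates.k3 + rates.k_m2) if (rates.k3 + rates.k_m2) > 0 \
        else rates.k2
    if k2_eff <= 0:
        raise ValueError("scheme has no hydrolysis flux (k2_eff = 0)")
    t_pre = 5.0 / k2_eff
    for i, atp in enumerate(atp_concs):
        if atp == 0:
            rates_out[i] = 0.0
            continue
        flux_est = cycle_flux(rates, atp)
        if flux_est <= 0:
            rates_out[i] = 0.0
            continue
        # cap substrate depletion at ~2% over the slope window
        t_lin = min(0.02 * atp / (enzyme * flux_est), 100.0 / flux_est)
        t_end = t_pre + max(t_lin, 3 * t_pre / n_points)
        grid = np.linspace(0.0, t_end, n_points + 1)
        trace = simulate_pi_release(rates, enzyme, atp, grid)
        mask = _linear_window(rates, trace.time)
        if mask.sum() < 3:
            raise ValueError("linear-phase window shorter than 3 sampling intervals")
        slope, _ = np.polyfit(trace.time[mask], trace.signal[mask], 1)
        rates_out[i] = max(slope / enzyme, 0.0)
    return SteadyStateCurve(atp_concs, rates_out)


def fit_hill(curve: SteadyStateCurve) -> HillFitResult:
    """Fit v = k_cat*[ATP]^n / (K^n + [ATP]^n) to a steady-state curve."""
    mask = curve.atp > 0
    a, v = curve.atp[mask], curve.rate[mask]
    if len(a) < 5:
        raise ValueError("need at least 5 nonzero ATP concentrations")

    def hill(atp, k_cat, K_atp, n):
        an = atp ** n
        return k_cat * an / (K_atp ** n + an)

    vmax0 = float(v.max())
    half = np.argmin(np.abs(v - vmax0 / 2))
    model = Model(hill)
    params = model.make_params(k_cat=vmax0, K_atp=max(float(a[half]), 1e-6), n=1.0)
    params["k_cat"].set(min=1e-12)
    params["K_atp"].set(min=1e-9)
    params["n"].set(min=0.1, max=4.0)
    res = model.fit(v, params, atp=a)
    if not res.success:
        raise FitError(f"Hill fit did not converge: {res.message}")

    def err(name):
        s = res.params[name].stderr
        return float(s) if s is not None else None

    return HillFitResult(
        k_cat=float(res.params["k_cat"].value),
        K_atp=float(res.params["K_atp"].value),
        n=float(res.params["n"].value),
        k_cat_stderr=err("k_cat"), K_atp_stderr=err("K_atp"), n_stderr=err("n"))


def burst_amplitude(trace: TransientTrace, enzyme: float | None = None,
                    linear_fraction: float = 0.5) -> float:
    """Back-extrapolated burst amplitude per enzyme of a progress curve.

    Fits a line to the trailing ``linear_fraction`` of the points and
    returns its t = 0 intercept divided by the enzyme concentration.
    Raises :class:`FitError` when the tail is not resolvably linear.
    """
    if enzyme is None:
        enzyme = trace.meta.get("enzyme_uM")
        if enzyme is None:
            raise ValueError("enzyme concentration not given and absent from trace.meta")
    t, y = trace.time, trace.signal
    n_tail = max(int(len(t) * linear_fraction), 4)
    if n_tail > len(t):
        raise FitError("trace too short to resolve a linear phase")
    tt, yy = t[-n_tail:], y[-n_tail:]
    slope, intercept = np.polyfit(tt, yy, 1)
    # linearity check: the two halves of the window must agree in slope
    half = n_tail // 2
    s1 = np.polyfit(tt[:half], yy[:half], 1)[0]
    s2 = np.polyfit(tt[half:], yy[half:], 1)[0]
    scale = max(abs(s1), abs(s2))
    if scale > 0 and abs(s1 - s2) / scale > 0.15:
        raise FitError("no linear phase detected in the trailing window")
    return float(intercept) / enzyme
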