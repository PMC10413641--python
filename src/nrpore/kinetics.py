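"""Two-phase adsorption kinetics from FTIR band areas and NR protein coverage.

Protein accumulation at the membrane follows two well-separated processes:
a fast initial adsorption (Langmuir-like, minutes) and a slow surface
complex formation / perforation phase (hours).  Both the integrated amide I
band area (ATR-FTIR, one spectrum every ~80 s) and the protein volume
fraction of the surface layers from time-resolved reflectometry (one curve
per 40-60 min) track the same quantity — interfacial protein amount — so
they are fitted with the same rising biexponential,

    y(t) = baseline + A_f (1 - exp(-t/tau_f)) + A_s (1 - exp(-t/tau_s)),

and compared after normalization.  The coarse NR sampling cannot resolve
the fast phase; those traces are fitted with the single (slow) exponential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import pearsonr

__all__ = [
    "KineticTrace",
    "BiexpFit",
    "amide_band_area",
    "fit_biexponential",
    "compare_traces",
]


@dataclass
class KineticTrace:
    """Signal versus time: band area (a.u.) or protein volume fraction.

    ``t_window`` optionally records the acquisition span of each point
    (minutes) — for reflectometry points this is the bin width over which
    the dataset was collected.
    """

    t: np.ndarray
    y: np.ndarray
    dy: np.ndarray
    t_window: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.t_window is not None:
            self.t_window = np.asarray(self.t_window, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.dy < 0):
            raise ValueError("dy must be non-negative")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class BiexpFit:
    """Parameters of the two-exponential saturation model.

    Time constants are ordered so ``tau_fast < tau_slow``.  ``errors`` are
    1-sigma uncertainties from the weighted-least-squares covariance.
    ``degenerate`` flags fits where one amplitude collapsed to ~0 (the data
    are effectively single-exponential); ``converged`` is the optimizer
    status.
    """

    a_fast: float
    tau_fast: float
    a_slow: float
    tau_slow: float
    baseline: float
    errors: dict[str, float]
    chi2: float
    converged: bool = True
    degenerate: bool = False
    n_exp: int = 2


def amide_band_area(
    wavenumber: np.ndarray,
    absorbance: np.ndarray,
    window: tuple[float, float] = (1600.0, 1700.0),
) -> float:
    """Integrated amide I band area above a linear baseline.

    Trapezoidal integral of the absorbance over ``window`` (cm^-1) minus the
    straight line drawn between the window endpoints, making the area
    invariant to any constant (or linear) offset.
    """
    wn = np.asarray(wavenumber, dtype=float)
    ab = np.asarray(absorbance, dtype=float)
    if wn[0] > wn[-1]:  # spectra are often stored high-to-low wavenumber
        wn, ab = wn[::-1], ab[::-1]
    lo, hi = min(window), max(window)
    if lo < wn[0] or hi > wn[-1]:
        raise ValueError(f"window {window} outside spectrum range ({wn[0]}, {wn[-1]})")
    mask = (wn >= lo) & (wn <= hi)
    x, y = wn[mask], ab[mask]
    y_lo, y_hi = np.interp([lo, hi], wn, ab)
    baseline = y_lo + (y_hi - y_lo) * (x - lo) / (hi - lo)
    return float(np.trapezoid(y - baseline, x))


def _biexp(t, baseline, a_f, tau_f, a_s, tau_s):
    return baseline + a_f * (1 - np.exp(-t / tau_f)) + a_s * (1 - np.exp(-t / tau_s))


def fit_biexponential(
    trace: KineticTrace,
    seed: int | None = 0,
    n_exp: int = 2,
    fit_baseline: bool = True,
) -> BiexpFit:
    """Weighted least-squares fit of the rising-saturation exponential model.

    Multi-start over a grid of time-constant initializations guards against
    local minima; parameters are uncertainty-weighted by ``trace.dy``.
    With ``n_exp=1`` only the slow process is fitted (the form used for
    coarsely sampled reflectometry traces).  A fit whose second amplitude
    collapses below 1% of the total is flagged ``degenerate``.
    """
    n_par = (2 * n_exp) + (1 if fit_baseline else 0)
    if len(trace) < max(6, n_par + 1):
        raise ValueError(f"need at least {max(6, n_par + 1)} points, got {len(trace)}")
    t, y = trace.t, trace.y
    pos = trace.dy[trace.dy > 0]
    fallback = float(np.median(pos)) if pos.size else 1.0
    w = 1.0 / np.where(trace.dy > 0, trace.dy, fallback)
    span = float(t[-1] - t[0])
    amp0 = float(np.max(y) - np.min(y))

    def residuals(p):
        if n_exp == 2:
            b, a_f, tau_f, a_s, tau_s = p
        else:
            b, a_s, tau_s = p
            a_f, tau_f = 0.0, 1.0
        if not fit_baseline:
            b = 0.0
        return (_biexp(t, b, a_f, tau_f, a_s, tau_s) - y) * w

    if n_exp == 2:
        starts = [
            (0.0, 0.5 * amp0, tf, 0.5 * amp0, ts)
            for tf in (0.02 * span, 0.05 * span, 0.15 * span)
            for ts in (0.4 * span, 1.0 * span, 2.0 * span)
        ]
        lower = [-np.inf, 0.0, 1e-6, 0.0, 1e-6]
        upper = [np.inf, np.inf, 50 * span, np.inf, 50 * span]
    else:
        starts = [(0.0, amp0, ts) for ts in (0.2 * span, 0.5 * span, 1.0 * span, 3.0 * span)]
        lower = [-np.inf, 0.0, 1e-6]
        upper = [np.inf, np.inf, 50 * span]

    best = None
    for p0 in starts:
        try:
            sol = least_squares(residuals, p0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("biexponential fit failed from every start")

    converged = bool(best.success)
    chi2 = float(2.0 * best.cost)
    # covariance from the Jacobian at the optimum
    names2 = ["baseline", "a_fast", "tau_fast", "a_slow", "tau_slow"]
    names1 = ["baseline", "a_slow", "tau_slow"]
    names = names2 if n_exp == 2 else names1
    errors = dict.fromkeys(names2, float("nan"))
    try:
        jtj = best.jac.T @ best.jac
        dof = max(len(t) - len(best.x), 1)
        cov = np.linalg.inv(jtj) * chi2 / dof
        for name, var in zip(names, np.diag(cov)):
            errors[name] = float(np.sqrt(max(var, 0.0)))
    except np.linalg.LinAlgError:
        converged = False

    if n_exp == 2:
        b, a_f, tau_f, a_s, tau_s = best.x
        if tau_f > tau_s:  # enforce fast < slow ordering
            a_f, a_s = a_s, a_f
            tau_f, tau_s = tau_s, tau_f
            errors["a_fast"], errors["a_slow"] = errors["a_slow"], errors["a_fast"]
            errors["tau_fast"], errors["tau_slow"] = (
                errors["tau_slow"],
                errors["tau_fast"],
            )
    else:
        b, a_s, tau_s = best.x
        a_f, tau_f = 0.0, float("nan")
    if not fit_baseline:
        b = 0.0

    total_amp = a_f + a_s
    degenerate = n_exp == 2 and total_amp > 0 and min(a_f, a_s) < 0.01 * total_amp
    if not converged:
        warnings.warn("kinetic fit did not converge cleanly", stacklevel=2)
    return BiexpFit(
        a_fast=float(a_f),
        tau_fast=float(tau_f),
        a_slow=float(a_s),
        tau_slow=float(tau_s),
        baseline=float(b),
        errors=errors,
        chi2=chi2,
        converged=converged,
        degenerate=degenerate,
        n_exp=n_exp,
    )


def compare_traces(nr: KineticTrace, ftir: KineticTrace, seed: int | None = 0) -> dict:
    """Agreement report between NR- and FTIR-derived kinetics.

    Both traces are min-max normalized; the FTIR trace is averaged over each
    NR point's collection window (or interpolated at the NR time if no
    window is recorded) and the Pearson correlation of the overlaid traces
    is reported, together with the ratio of independently fitted slow time
    constants (NR fitted single-exponential, FTIR biexponential).
    """
    if nr.t[-1] < ftir.t[0] or ftir.t[-1] < nr.t[0]:
        raise ValueError("traces have no overlapping time range")

    def norm(y):
        span = y.max() - y.min()
        return (y - y.min()) / (span if span > 0 else 1.0)

    ftir_n = norm(ftir.y)
    nr_n = norm(nr.y)
    ftir_at_nr = np.empty(len(nr))
    for i, t0 in enumerate(nr.t):
        if nr.t_window is not None:
            half = nr.t_window[i] / 2.0
            mask = (ftir.t >= t0 - half) & (ftir.t <= t0 + half)
            ftir_at_nr[i] = (
                float(np.mean(ftir_n[mask])) if mask.any() else np.interp(t0, ftir.t, ftir_n)
            )
        else:
            ftir_at_nr[i] = np.interp(t0, ftir.t, ftir_n)

    corr = float(pearsonr(nr_n, ftir_at_nr).statistic)
    fit_ftir = fit_biexponential(ftir, seed=seed, n_exp=2)
    # coarse traces cannot support two constants; fall back to the slow one
    n_exp_nr = 2 if len(nr) >= 20 else 1
    fit_nr = fit_biexponential(nr, seed=seed, n_exp=n_exp_nr)
    ratio = fit_nr.tau_slow / fit_ftir.tau_slow
    return {
        "correlation": corr,
        "tau_slow_nr": fit_nr.tau_slow,
        "tau_slow_ftir": fit_ftir.tau_slow,
        "tau_slow_ratio": float(ratio),
        "fit_nr": fit_nr,
        "fit_ftir": fit_ftir,
        "nr_normalized": nr_n,
        "ftir_on_nr_times": ftir_at_nr,
    }
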