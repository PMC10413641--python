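"""Co-refinement of one interfacial structure against multiple contrasts.

A single contrast-independent volume-fraction model must reproduce every
reflectivity curve simultaneously; only the material SLDs (and per-curve
scale factor and flat background) differ between contrasts.  Fitting is a
bounded global search (differential evolution) followed by ensemble MCMC
(emcee) around the optimum; uncertainties are reported as the central 65%
credible interval of the posterior, the convention used throughout the
structural results.

Volume-fraction validity (component sums <= 1 per layer) is enforced by
rejection: parameter vectors that violate it receive infinite chi-square /
zero posterior mass, which keeps the sampler inside the simplex without a
reparametrization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
from scipy.optimize import differential_evolution, minimize_scalar

from .materials import SolventContrast
from .reflectivity import smeared_reflectivity
from .structure import InterfaceModel

__all__ = [
    "ContrastDataset",
    "FitResult",
    "chi_squared",
    "corefine",
    "credible_interval",
    "scale_ratio_fit",
    "model_reflectivity",
]

_INVALID_CHI2 = 1.0e12


@dataclass
class ContrastDataset:
    """One reflectivity curve bound to a solvent contrast and isotope form."""

    q: np.ndarray
    r: np.ndarray
    dr: np.ndarray
    contrast: SolventContrast
    dq: np.ndarray | None = None
    protein_isotope: str = "h"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.dr = np.asarray(self.dr, dtype=float)
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
        n = len(self.q)
        if len(self.r) != n or len(self.dr) != n or (
            self.dq is not None and len(self.dq) != n
        ):
            raise ValueError("Q, R, dR (and dQ) must have equal lengths")
        if np.any(self.dr <= 0):
            raise ValueError("dR must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("Q must be strictly increasing")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class FitResult:
    """Optimizer + MCMC output for a co-refinement.

    ``chain`` has shape (n_samples, n_params) after burn-in; ``ci65`` maps
    parameter names to the central 65% credible interval; ``best_params``
    are the chi-square optimum and ``median_params`` the posterior medians.
    ``model`` is the fitted model with best parameters applied.
    """

    param_names: list[str]
    best_params: dict[str, float]
    median_params: dict[str, float]
    chi2: float
    chain: np.ndarray
    ci65: dict[str, tuple[float, float]]
    model: InterfaceModel
    seed: int | None = None
    bounds: dict[str, tuple[float, float]] | None = None
    flat_posterior: bool = False

    def model_at(self, theta: np.ndarray) -> InterfaceModel:
        """Rebuild the model at an arbitrary posterior draw."""
        m = self.model.copy()
        for name, value in zip(self.param_names, theta):
            m.set(name, value)
        return m


def model_reflectivity(
    model: InterfaceModel, dataset: ContrastDataset, dq_over_q: float = 0.04
) -> np.ndarray:
    """Smeared forward reflectivity of ``model`` on a dataset's Q grid."""
    sld, thick, rough = model.slab_arrays(dataset.contrast, dataset.protein_isotope)
    scale = model.scales.get(dataset.contrast.name, 1.0)
    bkg = model.backgrounds.get(dataset.contrast.name, 1.0e-6)
    return smeared_reflectivity(
        dataset.q, sld, thick, rough, scale=scale, background=bkg,
        dq_over_q=dq_over_q, dq=dataset.dq,
    )


def chi_squared(model: InterfaceModel, datasets: list[ContrastDataset]) -> float:
    """Sum over datasets and points of ((R_model - R) / dR)^2."""
    total = 0.0
    for ds in datasets:
        rm = model_reflectivity(model, ds)
        total += float(np.sum(((rm - ds.r) / ds.dr) ** 2))
    return total


class _Objective:
    """chi2(theta) for a free-parameter vector, with validity rejection."""

    def __init__(
        self,
        model: InterfaceModel,
        datasets: list[ContrastDataset],
        free_params: dict[str, tuple[float, float]],
    ):
        self.model = model.copy()
        self.datasets = sorted(datasets, key=lambda d: d.contrast.name)
        self.names = list(free_params)
        self.bounds = [tuple(free_params[n]) for n in self.names]
        for lo, hi in self.bounds:
            if lo >= hi:
                raise ValueError("bound low must be < high")

    def set_theta(self, theta: np.ndarray) -> bool:
        for name, value in zip(self.names, theta):
            self.model.set(name, value)
        try:
            self.model.validate()
        except ValueError:
            return False
        return True

    def chi2(self, theta: np.ndarray) -> float:
        for value, (lo, hi) in zip(theta, self.bounds):
            if not lo <= value <= hi:
                return _INVALID_CHI2
        if not self.set_theta(theta):
            return _INVALID_CHI2
        return chi_squared(self.model, self.datasets)

    def log_prob(self, theta: np.ndarray) -> float:
        c2 = self.chi2(theta)
        if c2 >= _INVALID_CHI2:
            return -np.inf
        return -0.5 * c2


def corefine(
    model: InterfaceModel,
    datasets: list[ContrastDataset],
    free_params: dict[str, tuple[float, float]],
    seed: int | None = 0,
    n_steps: int = 5000,
    n_walkers: int | None = None,
    burn_fraction: float = 0.3,
    de_maxiter: int = 60,
    progress: bool = False,
) -> FitResult:
    """Simultaneously fit one model to all datasets.

    Parameters
    ----------
    model :
        Starting structure; copied, not mutated.
    free_params :
        Mapping of dotted parameter paths (see
        :meth:`~nrpore.structure.InterfaceModel.set`) to (low, high) bounds.
    seed :
        Seeds both the global optimizer and the MCMC sampler.
    n_steps, n_walkers, burn_fraction :
        Ensemble-sampler settings; walkers default to max(2*ndim + 2, 16)
        rounded even.

    A flat (non-identifiable) posterior is flagged on the result, not
    raised: it is detected when a credible interval spans most of its prior
    bound.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    obj = _Objective(model, datasets, free_params)
    ndim = len(obj.names)
    rng = np.random.default_rng(seed)

    de = differential_evolution(
        obj.chi2,
        bounds=obj.bounds,
        seed=int(rng.integers(2**31 - 1)),
        maxiter=de_maxiter,
        popsize=15,
        tol=0.005,
        polish=True,
    )
    best = np.asarray(de.x, dtype=float)
    chi2_best = float(de.fun)

    if n_walkers is None:
        n_walkers = max(2 * ndim + 2, 16)
    n_walkers += n_walkers % 2

    widths = np.array([hi - lo for lo, hi in obj.bounds])
    p0 = best[None, :] + 1e-3 * widths[None, :] * rng.standard_normal((n_walkers, ndim))
    p0 = np.clip(p0, [lo for lo, _ in obj.bounds], [hi for _, hi in obj.bounds])
    # nudge any invalid starting points back to the optimum
    for i in range(n_walkers):
        if not np.isfinite(obj.log_prob(p0[i])):
            p0[i] = best

    sampler = emcee.EnsembleSampler(n_walkers, ndim, obj.log_prob)
    mcmc_seed = int(rng.integers(2**31 - 1))
    sampler._random = np.random.RandomState(mcmc_seed)  # deterministic chains
    sampler.run_mcmc(p0, n_steps, progress=progress)
    burn = int(burn_fraction * n_steps)
    chain = sampler.get_chain(discard=burn, flat=True)

    # keep the best point seen anywhere
    lp = sampler.get_log_prob(discard=burn, flat=True)
    i_best = int(np.argmax(lp))
    if -2.0 * lp[i_best] < chi2_best:
        best = chain[i_best]
        chi2_best = float(-2.0 * lp[i_best])

    ci65 = {
        name: credible_interval(chain[:, i], level=0.65)
        for i, name in enumerate(obj.names)
    }
    medians = {name: float(np.median(chain[:, i])) for i, name in enumerate(obj.names)}
    flat = any(
        (hi_ci - lo_ci) > 0.9 * (hi - lo)
        for (lo_ci, hi_ci), (lo, hi) in zip(ci65.values(), obj.bounds)
    )
    for i, name in enumerate(obj.names):
        lo_ci, hi_ci = ci65[name]
        if not lo_ci <= best[i] <= hi_ci:
            warnings.warn(
                f"best-fit {name} outside its 65% credible interval; "
                "chain may be poorly mixed",
                stacklevel=2,
            )

    fitted = model.copy()
    for name, value in zip(obj.names, best):
        fitted.set(name, value)
    return FitResult(
        param_names=obj.names,
        best_params={n: float(v) for n, v in zip(obj.names, best)},
        median_params=medians,
        chi2=chi2_best,
        chain=chain,
        ci65=ci65,
        model=fitted,
        seed=seed,
        bounds=dict(zip(obj.names, obj.bounds)),
        flat_posterior=flat,
    )


def credible_interval(chain: np.ndarray, level: float = 0.65) -> tuple[float, float]:
    """Central posterior interval: the (1-level)/2 .. (1+level)/2 quantiles.

    ``level=0.65`` gives the 17.5th-82.5th percentile band; ``level=1``
    clips to the chain extrema.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must be in [0, 1]")
    chain = np.asarray(chain, dtype=float)
    lo = 50.0 * (1.0 - level)
    return (float(np.percentile(chain, lo)), float(np.percentile(chain, 100.0 - lo)))


# ---------------------------------------------------------------------------
# Time-resolved scale-ratio model
# ---------------------------------------------------------------------------

def _blend_models(
    before: InterfaceModel, after: InterfaceModel, alpha: float
) -> InterfaceModel:
    """Layerwise mixture: fractions (1-a)*phi_b + a*phi_a, thickness linear."""
    mixed = after.copy()
    for layer_a in mixed.layers:
        layer_b = before.layer(layer_a.name)
        layer_a.thickness = (1 - alpha) * layer_b.thickness + alpha * layer_a.thickness
        names = set(layer_a.components) | set(layer_b.components)
        layer_a.components = {
            n: (1 - alpha) * layer_b.components.get(n, 0.0)
            + alpha * layer_a.components.get(n, 0.0)
            for n in names
        }
    return mixed


def align_topology(
    before: InterfaceModel, after: InterfaceModel
) -> InterfaceModel:
    """Give a bare-bilayer 'before' model the complex geometry of 'after'
    at zero occupancy, so the two endpoints share a layer topology."""
    if before.has_complex or not after.has_complex:
        return before.copy()
    aligned = before.copy()
    for name in ("cluster1", "cluster2", "cluster3"):
        src = after.layer(name)
        aligned.layers.append(
            type(src)(name, src.thickness, src.roughness, {})
        )
    return aligned


def scale_ratio_fit(
    model_before: InterfaceModel,
    model_after: InterfaceModel,
    dataset_t: ContrastDataset,
    seed: int | None = 0,
    n_steps: int = 800,
) -> FitResult:
    """Fit a single mixing coefficient alpha between two endpoint structures.

    The time-resolved structure is modelled as the scale ratio between the
    surface structure before protein interaction (alpha=0) and the structure
    at equilibrium (alpha=1): every layer's volume fractions mix linearly
    and thicknesses interpolate linearly.  Returns a one-parameter
    :class:`FitResult` with the posterior for ``alpha``.
    """
    before = align_topology(model_before, model_after)
    names_b = [l.name for l in before.layers]
    names_a = [l.name for l in model_after.layers]
    if names_b != names_a:
        raise ValueError(f"layer topology mismatch: {names_b} vs {names_a}")

    def chi2_of(alpha: float) -> float:
        if not 0.0 <= alpha <= 1.0:
            return _INVALID_CHI2
        mixed = _blend_models(before, model_after, alpha)
        return chi_squared(mixed, [dataset_t])

    opt = minimize_scalar(chi2_of, bounds=(0.0, 1.0), method="bounded")
    best = float(opt.x)

    rng = np.random.default_rng(seed)
    n_walkers = 8
    p0 = np.clip(best + 0.01 * rng.standard_normal((n_walkers, 1)), 0.0, 1.0)
    sampler = emcee.EnsembleSampler(
        n_walkers, 1, lambda th: -0.5 * chi2_of(float(th[0]))
    )
    sampler._random = np.random.RandomState(int(rng.integers(2**31 - 1)))
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_steps // 3, flat=True)

    mixed = _blend_models(before, model_after, best)
    return FitResult(
        param_names=["alpha"],
        best_params={"alpha": best},
        median_params={"alpha": float(np.median(chain))},
        chi2=float(opt.fun),
        chain=chain,
        ci65={"alpha": credible_interval(chain[:, 0], 0.65)},
        model=mixed,
        seed=seed,
        bounds={"alpha": (0.0, 1.0)},
    )
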