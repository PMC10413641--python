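"""Canonical synthetic-recovery experiments.

Each function generates synthetic data from a packaged fixture structure
under the standard measurement conditions (three solvent contrasts, 4%
dQ/Q, counting-statistics-like noise; FTIR/NR kinetic schedules), runs the
corresponding analysis stage, and returns the fit.  They are the
reproducible end-to-end workflows behind the package's validation: every
reported quantity is recomputed from scratch from (fixture, seed).

Chain lengths default to sizes that resolve the posteriors of these
well-conditioned synthetic problems; they can be raised for production use.
"""

from __future__ import annotations

import numpy as np

from .inference import FitResult, corefine
from .kinetics import BiexpFit, fit_biexponential
from .synthetic import (
    fixture_catalog,
    ftir_schedule,
    generate_contrast_set,
    generate_kinetic_trace,
    nr_schedule,
)

__all__ = [
    "BEFORE_FREE_PARAMS",
    "AFTER_FREE_PARAMS",
    "before_bilayer_experiment",
    "after_complex_experiment",
    "ftir_kinetics_experiment",
    "nr_kinetics_experiment",
    "complex_total_thickness",
]

#: Free parameters for the bare-bilayer co-refinement: tail geometry and
#: coverage, outer-headgroup hydration, and the bilayer roughness.
BEFORE_FREE_PARAMS = {
    "tails.thickness": (20.0, 40.0),
    "tails.frac.lipid_tail": (0.5, 1.0),
    "head_out.frac.lipid_head": (0.4, 1.0),
    "tails.roughness": (0.5, 8.0),
}

#: Free parameters for the porated-membrane fit: thinned bilayer plus the
#: symmetric three-layer surface complex (cluster3 is tied to cluster1).
AFTER_FREE_PARAMS = {
    "tails.thickness": (20.0, 35.0),
    "tails.frac.lipid_tail": (0.5, 1.0),
    "tails.frac.protein": (0.0, 0.2),
    "cluster1.thickness": (10.0, 40.0),
    "cluster1.frac.protein": (0.0, 0.5),
    "cluster2.thickness": (10.0, 45.0),
    "cluster2.frac.protein": (0.0, 0.6),
    "cluster2.frac.lipid_full": (0.0, 0.5),
}


def _split_seed(seed: int | None, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31 - 1, size=n)]


def before_bilayer_experiment(
    seed: int = 0,
    fixture: str = "10CL_before",
    n_steps: int = 600,
    de_maxiter: int = 40,
    free_params: dict | None = None,
) -> FitResult:
    """Three-contrast co-refinement of a synthetic bare-bilayer dataset."""
    data_seed, fit_seed = _split_seed(seed, 2)
    model = fixture_catalog()[fixture]
    datasets = generate_contrast_set(model, seed=data_seed)
    return corefine(
        model,
        datasets,
        free_params or BEFORE_FREE_PARAMS,
        seed=fit_seed,
        n_steps=n_steps,
        de_maxiter=de_maxiter,
    )


def after_complex_experiment(
    seed: int = 0,
    fixture: str = "10CL_after",
    n_steps: int = 600,
    de_maxiter: int = 40,
) -> FitResult:
    """Co-refinement of a synthetic porated membrane with its symmetric
    surface complex."""
    data_seed, fit_seed = _split_seed(seed, 2)
    model = fixture_catalog()[fixture]
    datasets = generate_contrast_set(model, seed=data_seed)
    return corefine(
        model,
        datasets,
        AFTER_FREE_PARAMS,
        seed=fit_seed,
        n_steps=n_steps,
        de_maxiter=de_maxiter,
    )


def complex_total_thickness(result: FitResult) -> tuple[float, tuple[float, float]]:
    """Posterior median and 65% interval of the summed complex thickness.

    With the symmetry constraint the total is 2 x cluster1 + cluster2,
    evaluated draw-by-draw on the chain.
    """
    from .inference import credible_interval

    i1 = result.param_names.index("cluster1.thickness")
    i2 = result.param_names.index("cluster2.thickness")
    total = 2.0 * result.chain[:, i1] + result.chain[:, i2]
    return float(np.median(total)), credible_interval(total, 0.65)


def ftir_kinetics_experiment(
    seed: int = 0,
    tau_fast: float = 10.0,
    tau_slow: float = 175.0,
    amplitude_split: tuple[float, float] = (0.6, 0.4),
    t_max: float = 600.0,
    noise_frac: float = 0.02,
) -> BiexpFit:
    """Biexponential fit of a synthetic FTIR-sampled adsorption trace
    (one point every 80 s)."""
    a_f, a_s = amplitude_split
    trace = generate_kinetic_trace(
        a_f, tau_fast, a_s, tau_slow, ftir_schedule(t_max),
        noise_frac=noise_frac, seed=seed,
    )
    return fit_biexponential(trace, seed=seed, n_exp=2)


def nr_kinetics_experiment(
    seed: int = 0,
    tau_slow: float = 110.0,
    t_max: float = 600.0,
    bin_min: float = 50.0,
    noise_frac: float = 0.05,
) -> BiexpFit:
    """Single-exponential (slow-process) fit of a trace sampled on the
    coarse reflectometry schedule (bin midpoints, 50-min bins)."""
    mids, spans = nr_schedule(t_max, bin_min)
    trace = generate_kinetic_trace(
        0.0, 1.0, 1.0, tau_slow, mids,
        noise_frac=noise_frac, seed=seed, t_window=spans,
    )
    return fit_biexponential(trace, seed=seed, n_exp=1)
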