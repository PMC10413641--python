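"""Before/after bookkeeping of lipid extraction and membrane poration.

After the fits, the biology lives in simple differences: how much lipid
left the bilayer core (pore area), how much the membrane thinned, how much
lipid and protein sit in the surface clusters, and whether the lipid lost
from the membrane balances the lipid found in the clusters — the mass-
balance argument that the clusters are built from extracted membrane
lipid.  Uncertainties are propagated by resampling the posterior chains of
the underlying fits.

Accounting convention for the balance: lipid lost from the tail region
plus lipid lost from the outer headgroups is compared against the total
lipid inventory of all three complex layers (volume per unit area,
Å^3/Å^2).  The inner headgroups, facing the substrate, are assumed
undisturbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import FitResult, credible_interval
from .structure import InterfaceModel, lipid_inventory

__all__ = ["PorationSummary", "poration_summary", "cl_trend"]


@dataclass
class PorationSummary:
    """Structural bookkeeping for one cardiolipin composition.

    Coverages and removal are tail-region lipid volume percent; thinning is
    the tail-thickness decrease in Å; inventories are Å^3 per Å^2;
    ``balance_ratio`` is removed-lipid volume per area divided by the
    complex lipid inventory.  ``intervals`` holds 65% credible intervals
    for each field when chains were available.
    """

    x_cl: float
    coverage_before: float
    coverage_after: float
    lipid_removed: float
    thinning: float
    complex_lipid: float
    complex_protein: float
    balance_ratio: float
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)


def _summary_fields(before: InterfaceModel, after: InterfaceModel) -> dict[str, float]:
    tails_b, tails_a = before.layer("tails"), after.layer("tails")
    head_b, head_a = before.layer("head_out"), after.layer("head_out")
    phi_b = sum(v for k, v in tails_b.components.items() if k.startswith("lipid"))
    phi_a = sum(v for k, v in tails_a.components.items() if k.startswith("lipid"))
    inv_a = lipid_inventory(after)

    removed_tail = tails_b.thickness * phi_b - tails_a.thickness * phi_a
    head_lipid_b = sum(v for k, v in head_b.components.items() if k.startswith("lipid"))
    head_lipid_a = sum(v for k, v in head_a.components.items() if k.startswith("lipid"))
    removed_head = head_b.thickness * head_lipid_b - head_a.thickness * head_lipid_a
    removed = removed_tail + removed_head
    complex_lipid = inv_a["complex"]["lipid"]
    return {
        "coverage_before": 100.0 * phi_b,
        "coverage_after": 100.0 * phi_a,
        "lipid_removed": 100.0 * (phi_b - phi_a),
        "thinning": tails_b.thickness - tails_a.thickness,
        "complex_lipid": complex_lipid,
        "complex_protein": inv_a["complex"]["protein"],
        "balance_ratio": removed / complex_lipid if complex_lipid > 0 else float("nan"),
    }


def poration_summary(
    fit_before: FitResult,
    fit_after: FitResult,
    x_cl: float,
    n_resample: int = 300,
    seed: int | None = 0,
) -> PorationSummary:
    """Combine before/after fits into the poration bookkeeping.

    Accepts either :class:`~nrpore.inference.FitResult` objects (intervals
    propagated by drawing ``n_resample`` joint samples from each posterior
    chain) or bare :class:`~nrpore.structure.InterfaceModel` endpoints
    (central values only).
    """
    before = fit_before.model if isinstance(fit_before, FitResult) else fit_before
    after = fit_after.model if isinstance(fit_after, FitResult) else fit_after
    if before.layer("tails") is None or after.layer("tails") is None:  # pragma: no cover
        raise ValueError("both structures need a tail layer")

    central = _summary_fields(before, after)
    intervals: dict[str, tuple[float, float]] = {}
    if isinstance(fit_before, FitResult) and isinstance(fit_after, FitResult):
        rng = np.random.default_rng(seed)
        idx_b = rng.integers(len(fit_before.chain), size=n_resample)
        idx_a = rng.integers(len(fit_after.chain), size=n_resample)
        draws: dict[str, list[float]] = {k: [] for k in central}
        for ib, ia in zip(idx_b, idx_a):
            mb = fit_before.model_at(fit_before.chain[ib])
            ma = fit_after.model_at(fit_after.chain[ia])
            for k, v in _summary_fields(mb, ma).items():
                draws[k].append(v)
        intervals = {k: credible_interval(np.array(v), 0.65) for k, v in draws.items()}

    return PorationSummary(x_cl=x_cl, intervals=intervals, **central)


def cl_trend(summaries: list[PorationSummary]) -> dict:
    """Test whether lipid removal rises with cardiolipin content.

    Returns the orderings, a strict-monotonicity flag and the fitted linear
    slope of lipid removed (volume %) versus CL content (mol %).  A single
    summary yields a trivial report with no trend.
    """
    if len(summaries) >= 2:
        x = np.array([s.x_cl for s in summaries])
        if len(np.unique(np.round(x, 12))) != len(x):
            raise ValueError("duplicate x_cl values")
    ordered = sorted(summaries, key=lambda s: s.x_cl)
    removed = np.array([s.lipid_removed for s in ordered])
    x_pct = 100.0 * np.array([s.x_cl for s in ordered])
    report = {
        "x_cl_mol_pct": x_pct.tolist(),
        "lipid_removed_pct": removed.tolist(),
        "n": len(ordered),
    }
    if len(ordered) < 2:
        report.update({"monotonic_increasing": None, "slope": None})
        return report
    report["monotonic_increasing"] = bool(np.all(np.diff(removed) > 0))
    report["slope"] = float(np.polyfit(x_pct, removed, 1)[0])
    return report
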