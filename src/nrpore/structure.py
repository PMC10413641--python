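"""Contrast-independent volume-fraction slab models of the interface.

The interfacial structure is a stack of layers, each described by a
thickness, a roughness to the layer below, and the volume fractions of the
materials it contains; the remainder of each layer is solvent.  The stack
runs from bulk silicon (z < 0), through the native oxide, a thin water gap,
the supported lipid bilayer (inner headgroups / tails / outer headgroups),
and — after protein interaction — an optional three-layer protein-lipid
surface complex, into bulk solvent.  The same structure, rendered with
contrast-specific material SLDs, must reproduce every measured reflectivity
curve simultaneously; that is what breaks the degeneracy of single-contrast
fitting.

Partial coverage of the surface complex is expressed through the solvent
fraction inside each complex layer rather than as a separate coverage
parameter.  The complex is optionally constrained symmetric: layers 1 and 3
share thickness and composition.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .materials import (
    Material,
    SolventContrast,
    default_materials,
    lipid_mixture,
    material_sld,
    mixture_sld,
)

__all__ = [
    "Layer",
    "InterfaceModel",
    "build_membrane_model",
    "sld_profile",
    "volume_fraction_profile",
    "area_per_molecule",
    "lipid_inventory",
]

_FRACTION_TOL = 1e-9


@dataclass
class Layer:
    """One slab: thickness, interfacial roughness and material occupancies.

    ``components`` maps material names to volume fractions; the implicit
    remainder is solvent.  ``roughness`` is the error-function interfacial
    width to the *previous* (substrate-side) layer.
    """

    name: str
    thickness: float
    roughness: float
    components: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.thickness < 0:
            raise ValueError(f"layer {self.name}: negative thickness")
        if self.roughness < 0:
            raise ValueError(f"layer {self.name}: negative roughness")
        total = 0.0
        for mat, phi in self.components.items():
            if not 0.0 <= phi <= 1.0:
                raise ValueError(
                    f"layer {self.name}: fraction of {mat} = {phi} outside [0, 1]"
                )
            total += phi
        if total > 1.0 + _FRACTION_TOL:
            raise ValueError(
                f"layer {self.name}: component fractions sum to {total:.6f} > 1"
            )

    @property
    def solvent_fraction(self) -> float:
        return max(0.0, 1.0 - sum(self.components.values()))


_COMPLEX_NAMES = ("cluster1", "cluster2", "cluster3")


@dataclass
class InterfaceModel:
    """Ordered slab stack with per-contrast scale factors and backgrounds.

    Parameters are addressed by dotted paths for fitting:

    - ``"<layer>.thickness"``, ``"<layer>.roughness"``
    - ``"<layer>.frac.<material>"`` — a component volume fraction
    - ``"scale.<contrast>"``, ``"background.<contrast>"``

    When ``symmetric_complex`` is set, cluster1 and cluster3 share thickness
    and composition: setting either updates both.
    """

    layers: list[Layer]
    materials: dict[str, Material]
    x_cl: float = 0.0
    symmetric_complex: bool = True
    scales: dict[str, float] = field(default_factory=dict)
    backgrounds: dict[str, float] = field(default_factory=dict)
    substrate_roughness: float = 3.0  # Si/SiO2 interface, Å
    notes: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.substrate_roughness < 0:
            raise ValueError("negative substrate roughness")
        for layer in self.layers:
            layer.validate()
        if self.symmetric_complex and self.has_complex:
            c1, c3 = self.layer("cluster1"), self.layer("cluster3")
            if abs(c1.thickness - c3.thickness) > 1e-9 or c1.components != c3.components:
                raise ValueError("symmetric complex requires cluster1 == cluster3")

    # -- layer access -------------------------------------------------------
    def layer(self, name: str) -> Layer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(f"no layer named {name!r}")

    @property
    def has_complex(self) -> bool:
        names = {l.name for l in self.layers}
        return all(n in names for n in _COMPLEX_NAMES)

    def copy(self) -> "InterfaceModel":
        return copy.deepcopy(self)

    # -- dotted-path parameter access ---------------------------------------
    def get(self, path: str) -> float:
        parts = path.split(".")
        if parts[0] == "scale":
            return self.scales[parts[1]]
        if parts[0] == "background":
            return self.backgrounds[parts[1]]
        layer = self.layer(parts[0])
        if parts[1] == "thickness":
            return layer.thickness
        if parts[1] == "roughness":
            return layer.roughness
        if parts[1] == "frac":
            return layer.components[parts[2]]
        raise KeyError(f"bad parameter path {path!r}")

    def set(self, path: str, value: float) -> None:
        parts = path.split(".")
        if parts[0] == "scale":
            self.scales[parts[1]] = value
            return
        if parts[0] == "background":
            self.backgrounds[parts[1]] = value
            return
        targets = [parts[0]]
        if self.symmetric_complex and parts[0] in ("cluster1", "cluster3"):
            targets = ["cluster1", "cluster3"]
        for name in targets:
            layer = self.layer(name)
            if parts[1] == "thickness":
                layer.thickness = value
            elif parts[1] == "roughness":
                layer.roughness = value
            elif parts[1] == "frac":
                layer.components[parts[2]] = value
            else:
                raise KeyError(f"bad parameter path {path!r}")

    # -- rendering ----------------------------------------------------------
    def material_for(self, name: str, protein_isotope: str) -> Material:
        if name == "protein":
            return self.materials[f"protein_{protein_isotope}"]
        return self.materials[name]

    def slab_arrays(
        self, contrast: SolventContrast, protein_isotope: str = "h"
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(sld, thickness, roughness) arrays, fronting Si to backing solvent.

        Layer SLDs are the volume-fraction mixtures of the component
        material SLDs under this contrast, with solvent filling the
        remainder.  Roughness[i] is the width of the interface between slab
        i-1 and slab i.
        """
        rho_solvent = contrast.sld
        slds = [material_sld(self.materials["silicon"], contrast)]
        thicks = [0.0]
        roughs = [0.0]
        for i, layer in enumerate(self.layers):
            comps = [
                (material_sld(self.material_for(n, protein_isotope), contrast), phi)
                for n, phi in layer.components.items()
            ]
            comps.append((rho_solvent, layer.solvent_fraction))
            slds.append(mixture_sld(comps))
            thicks.append(layer.thickness)
            roughs.append(self.substrate_roughness if i == 0 else layer.roughness)
        # backing solvent half-space; its roughness is that to the last layer
        slds.append(rho_solvent)
        thicks.append(0.0)
        last_rough = self.layers[-1].roughness if self.layers else self.substrate_roughness
        roughs.append(last_rough)
        return np.array(slds), np.array(thicks), np.array(roughs)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

DEFAULT_GEOMETRY = {
    "sio2_thickness": 12.0,
    "sio2_solvent": 0.0,
    "water_gap": 4.0,  # thin hydration layer between oxide and bilayer, Å
    "bilayer_roughness": 3.0,
    "complex_roughness": 5.0,
}


def build_membrane_model(
    x_cl: float,
    params: dict,
    materials: dict[str, Material] | None = None,
    symmetric_complex: bool = True,
) -> InterfaceModel:
    """Assemble a supported-bilayer model for a POPC/TOCL membrane.

    ``x_cl`` is the cardiolipin mole fraction; the lipid head/tail SLDs used
    throughout the stack are the mole-weighted POPC/TOCL mixtures.  ``params``
    gives the structural values::

        head_in_thickness, head_in_lipid, tail_thickness, tail_lipid,
        tail_protein, head_out_thickness, head_out_lipid, head_out_protein,
        cluster1_thickness, cluster1_protein, cluster2_thickness,
        cluster2_protein, cluster2_lipid

    Cluster keys are optional: omit them for a bare bilayer.  Geometry
    defaults (oxide, water gap, roughnesses) can be overridden with the same
    keys as :data:`DEFAULT_GEOMETRY`.
    """
    if not 0.0 <= x_cl <= 1.0:
        raise ValueError(f"x_cl must be in [0, 1], got {x_cl}")
    mats = dict(materials or default_materials())
    mats["lipid_head"] = lipid_mixture(mats, "head", x_cl)
    mats["lipid_tail"] = lipid_mixture(mats, "tail", x_cl)
    mats["lipid_full"] = lipid_mixture(mats, "full", x_cl)

    geo = dict(DEFAULT_GEOMETRY)
    for k in geo:
        if k in params:
            geo[k] = params[k]
    rb = geo["bilayer_roughness"]

    layers = [
        Layer("sio2", geo["sio2_thickness"], 0.0, {"sio2": 1.0 - geo["sio2_solvent"]}),
        Layer("water_gap", geo["water_gap"], rb, {}),
        Layer(
            "head_in",
            params["head_in_thickness"],
            rb,
            _frac({"lipid_head": params["head_in_lipid"],
                   "protein": params.get("head_in_protein", 0.0)}),
        ),
        Layer(
            "tails",
            params["tail_thickness"],
            rb,
            _frac({"lipid_tail": params["tail_lipid"],
                   "protein": params.get("tail_protein", 0.0)}),
        ),
        Layer(
            "head_out",
            params["head_out_thickness"],
            rb,
            _frac({"lipid_head": params["head_out_lipid"],
                   "protein": params.get("head_out_protein", 0.0)}),
        ),
    ]
    if "cluster2_thickness" in params:
        rc = geo["complex_roughness"]
        wing = Layer(
            "cluster1",
            params["cluster1_thickness"],
            rc,
            _frac({"protein": params["cluster1_protein"],
                   "lipid_full": params.get("cluster1_lipid", 0.0)}),
        )
        core = Layer(
            "cluster2",
            params["cluster2_thickness"],
            rc,
            _frac({"protein": params["cluster2_protein"],
                   "lipid_full": params.get("cluster2_lipid", 0.0)}),
        )
        wing2 = Layer("cluster3", wing.thickness, rc, dict(wing.components))
        layers += [wing, core, wing2]

    model = InterfaceModel(
        layers=layers,
        materials=mats,
        x_cl=x_cl,
        symmetric_complex=symmetric_complex,
        scales={},
        backgrounds={},
    )
    model.validate()
    return model


def _frac(d: dict[str, float]) -> dict[str, float]:
    return {k: v for k, v in d.items() if v > 0.0}


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _layer_weights(model: InterfaceModel, z: np.ndarray) -> tuple[np.ndarray, list]:
    """Smooth occupancy weight w_i(z) of every slab (incl. half-spaces).

    Each interface is an error-function step of width equal to its
    roughness; slab i occupies the region between interfaces i-1 and i.  The
    weights sum to 1 at every z by construction.
    """
    n_layers = len(model.layers)
    # interface positions: z=0 at Si/SiO2
    positions = [0.0]
    for layer in model.layers:
        positions.append(positions[-1] + layer.thickness)
    roughs = [model.substrate_roughness] + [l.roughness for l in model.layers[1:]]
    roughs.append(model.layers[-1].roughness if model.layers else 3.0)
    # step_k(z): 0 -> 1 across interface k
    steps = []
    for pos, sig in zip(positions, roughs):
        if sig <= 0:
            steps.append((z >= pos).astype(float))
        else:
            steps.append(0.5 * (1.0 + erf((z - pos) / (np.sqrt(2.0) * sig))))
    weights = [1.0 - steps[0]]  # silicon half-space
    for i in range(n_layers):
        weights.append(steps[i] - steps[i + 1])
    weights.append(steps[n_layers])  # solvent half-space
    return np.array(weights), positions


def volume_fraction_profile(
    model: InterfaceModel,
    z: np.ndarray,
    protein_isotope: str = "h",
) -> dict[str, np.ndarray]:
    """Per-component occupancy versus depth; components sum to 1 everywhere.

    Returns a mapping of component name ('silicon', 'sio2', 'lipid', i.e.
    head+tail pooled, 'protein', 'solvent', ...) to its profile on ``z``.
    """
    z = np.asarray(z, dtype=float)
    weights, _ = _layer_weights(model, z)
    profiles: dict[str, np.ndarray] = {
        "silicon": weights[0].copy(),
        "solvent": weights[-1].copy(),
    }
    for i, layer in enumerate(model.layers):
        w = weights[i + 1]
        for name, phi in layer.components.items():
            key = _component_key(name)
            profiles.setdefault(key, np.zeros_like(z))
            profiles[key] += phi * w
        profiles["solvent"] += layer.solvent_fraction * w
    return profiles


def _component_key(material_name: str) -> str:
    if material_name.startswith("lipid"):
        return "lipid"
    if material_name.startswith("protein"):
        return "protein"
    return material_name


def sld_profile(
    model: InterfaceModel,
    contrast: SolventContrast,
    z: np.ndarray,
    protein_isotope: str = "h",
) -> np.ndarray:
    """Smoothed SLD depth profile rho(z) under one solvent contrast.

    Computed as the pointwise volume-fraction mixture of the slab SLDs using
    the same error-function interface weights as
    :func:`volume_fraction_profile`, so the two are exactly consistent.
    """
    z = np.asarray(z, dtype=float)
    slds, _, _ = model.slab_arrays(contrast, protein_isotope)
    weights, _ = _layer_weights(model, z)
    return np.einsum("i,ij->j", slds, weights)


# ---------------------------------------------------------------------------
# Derived structural quantities
# ---------------------------------------------------------------------------

def area_per_molecule(
    t_tail: float,
    phi_lipid: float,
    x_cl: float,
    materials: dict[str, Material] | None = None,
    v_tails: float | None = None,
) -> float:
    """Average lipid area per molecule from the tail-layer geometry.

    APM = 2 * V_tails / (t_tail * phi_lipid) for a two-leaflet tail region of
    thickness ``t_tail`` filled to lipid fraction ``phi_lipid``; V_tails is
    the x_cl mole-weighted mean tail volume (pass ``v_tails`` to override the
    materials table).
    """
    if t_tail <= 0:
        raise ValueError("tail thickness must be positive")
    if not 0.0 < phi_lipid <= 1.0:
        raise ValueError("lipid fraction must be in (0, 1]")
    if v_tails is None:
        mats = materials or default_materials()
        v_tails = lipid_mixture(mats, "tail", x_cl).volume
    return 2.0 * v_tails / (t_tail * phi_lipid)


def lipid_inventory(model: InterfaceModel) -> dict[str, dict[str, float]]:
    """Component volume per unit area (Å^3/Å^2) by region.

    Gamma = sum over layers of thickness * volume fraction, reported for the
    bilayer (headgroups + tails) and the surface complex separately, for the
    lipid and protein components.
    """
    regions = {
        "bilayer": ("head_in", "tails", "head_out"),
        "complex": _COMPLEX_NAMES,
    }
    out: dict[str, dict[str, float]] = {}
    for region, names in regions.items():
        inv = {"lipid": 0.0, "protein": 0.0}
        for name in names:
            try:
                layer = model.layer(name)
            except KeyError:
                continue
            for mat, phi in layer.components.items():
                key = _component_key(mat)
                if key in inv:
                    inv[key] += layer.thickness * phi
        out[region] = inv
    return out
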