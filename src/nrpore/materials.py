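"""Neutron scattering length densities of solvents, lipids and proteins.

The contrast quantity specular neutron reflectometry senses is the coherent
scattering length density (SLD),

    rho = sum_i b_i / V    [Å^-2],

summed over the atoms occupying a molecular volume V.  Because hydrogen
(b_H = -3.74 fm) and deuterium (b_D = +6.67 fm) differ so strongly, the SLD
of any species with labile (exchangeable) hydrogens depends on the H2O/D2O
composition of the solvent, and a perdeuterated protein can be rendered
nearly invisible in D2O.  This module computes those contrast-dependent
SLDs for arbitrary materials, with labile-H exchange and partial
deuteration of non-labile hydrogens handled explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "B_COH",
    "Material",
    "SolventContrast",
    "D2O",
    "SI_MW",
    "H2O",
    "solvent_sld",
    "material_sld",
    "mixture_sld",
    "protein_material",
    "lipid_mixture",
    "load_materials",
    "default_materials",
    "BAX_HUMAN_SEQUENCE",
]

# Coherent neutron scattering lengths, fm (Sears 1992).
B_COH = {
    "H": -3.7406,
    "D": 6.671,
    "C": 6.6511,
    "N": 9.36,
    "O": 5.803,
    "P": 5.13,
    "S": 2.847,
    "Si": 4.1491,
}

# 1 fm = 1e-5 Å; SLD [Å^-2] = b [fm] * FM_TO_ANG / V [Å^3]
FM_TO_ANG = 1.0e-5

#: Molecular volume of one water molecule, Å^3 (both isotopologues).
V_WATER = 30.0

_SLD_D2O = (2 * B_COH["D"] + B_COH["O"]) * FM_TO_ANG / V_WATER
_SLD_H2O = (2 * B_COH["H"] + B_COH["O"]) * FM_TO_ANG / V_WATER


@dataclass(frozen=True)
class SolventContrast:
    """An aqueous solvent defined by its D2O volume fraction.

    Buffer salts are dilute and ignored; the SLD is the linear mix of the
    pure H2O and pure D2O endpoints.
    """

    name: str
    x_d2o: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_d2o <= 1.0:
            raise ValueError(f"x_d2o must be in [0, 1], got {self.x_d2o}")

    @property
    def sld(self) -> float:
        return solvent_sld(self)


def solvent_sld(contrast: SolventContrast) -> float:
    """SLD (Å^-2) of an H2O/D2O mixture: linear in the D2O fraction."""
    return (1.0 - contrast.x_d2o) * _SLD_H2O + contrast.x_d2o * _SLD_D2O


#: The three solution contrasts used for bilayer characterisation.
D2O = SolventContrast("D2O", 1.0)
SI_MW = SolventContrast("Si-MW", 0.38)  # silicon-matched water
H2O = SolventContrast("H2O", 0.0)


@dataclass(frozen=True)
class Material:
    """A chemical species with fixed (non-labile) and exchangeable hydrogens.

    Parameters
    ----------
    b_nonexchangeable :
        Coherent scattering length (fm) summed over all atoms that do not
        exchange with solvent, with any deuteration already folded in.
    n_exchangeable_h :
        Number of labile hydrogens whose isotope follows the solvent.
    volume :
        Molecular volume, Å^3.
    deuteration :
        Fraction of non-labile H replaced by D (bookkeeping only; the
        substitution is already included in ``b_nonexchangeable``).
    """

    name: str
    b_nonexchangeable: float
    n_exchangeable_h: float
    volume: float
    deuteration: float = 0.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"{self.name}: volume must be positive, got {self.volume}")
        if not 0.0 <= self.deuteration <= 1.0:
            raise ValueError(f"{self.name}: deuteration must be in [0, 1]")
        if self.n_exchangeable_h < 0:
            raise ValueError(f"{self.name}: n_exchangeable_h must be >= 0")

    def sld(self, contrast: SolventContrast) -> float:
        return material_sld(self, contrast)


def material_sld(m: Material, contrast: SolventContrast) -> float:
    """SLD of a material with its labile hydrogens equilibrated to solvent.

    rho = [b_fix + n_exch * (x * b_D + (1 - x) * b_H)] / V, with x the D2O
    fraction.  Affine in x; the slope is n_exch * (b_D - b_H) / V.
    """
    b_labile = m.n_exchangeable_h * (
        contrast.x_d2o * B_COH["D"] + (1.0 - contrast.x_d2o) * B_COH["H"]
    )
    return (m.b_nonexchangeable + b_labile) * FM_TO_ANG / m.volume


def mixture_sld(components: list[tuple[float, float]]) -> float:
    """Volume-fraction-weighted SLD of a mixed layer.

    ``components`` is a list of (sld, volume_fraction) pairs.  Fractions must
    be non-negative and sum to at most 1 (any remainder is vacuum unless the
    solvent is passed explicitly as a component).
    """
    total = 0.0
    sld = 0.0
    for rho, phi in components:
        if phi < 0:
            raise ValueError(f"negative volume fraction {phi}")
        total += phi
        sld += rho * phi
    if total > 1.0 + 1e-9:
        raise ValueError(f"volume fractions sum to {total:.6f} > 1")
    return sld


# ---------------------------------------------------------------------------
# Proteins from sequence
# ---------------------------------------------------------------------------

# Residue composition within a peptide chain (amino acid minus water):
# (C, H_total, N, O, S, labile H).  Labile H = backbone amide (0 for Pro)
# plus side-chain OH/NH/SH; Asp/Glu carboxyls counted labile (Jacrot-style).
AMINO_ACIDS: dict[str, tuple[int, int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0, 1),
    "A": (3, 5, 1, 1, 0, 1),
    "S": (3, 5, 1, 2, 0, 2),
    "P": (5, 7, 1, 1, 0, 0),
    "V": (5, 9, 1, 1, 0, 1),
    "T": (4, 7, 1, 2, 0, 2),
    "C": (3, 5, 1, 1, 1, 2),
    "L": (6, 11, 1, 1, 0, 1),
    "I": (6, 11, 1, 1, 0, 1),
    "N": (4, 6, 2, 2, 0, 3),
    "D": (4, 5, 1, 3, 0, 2),
    "Q": (5, 8, 2, 2, 0, 3),
    "K": (6, 12, 2, 1, 0, 4),
    "E": (5, 7, 1, 3, 0, 2),
    "M": (5, 9, 1, 1, 1, 1),
    "H": (6, 7, 3, 1, 0, 2),
    "F": (9, 9, 1, 1, 0, 1),
    "R": (6, 12, 4, 1, 0, 5),
    "Y": (9, 9, 1, 2, 0, 2),
    "W": (11, 10, 2, 1, 0, 2),
}

# Average atomic masses for the molecular-weight -> volume conversion.
_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}

#: Specific volume of globular protein, Å^3 per Da (0.73 cm^3/g).
PROTEIN_SPECIFIC_VOLUME = 1.21

#: Fraction of labile hydrogens that actually exchange with solvent.
DEFAULT_EXCHANGE_COMPLETENESS = 0.9

#: Human Bax, UniProt Q07812 (192 residues).
BAX_HUMAN_SEQUENCE = (
    "MDGSGEQPRGGGPTSSEQIMKTGALLLQGFIQDRAGRMGGEAPELALDPVPQDASTKKLS"
    "ECLKRIGDELDSNMELQRMIAAVDTDSPREVFFRVAADMFSDGNFNWGRVVALFYFASKL"
    "VLKALCTKVPELIRTIMGWTLDFLRERLLGWIQDQGGWDGLLSYFGTPTWQTVTIFVAGV"
    "LTASLTIWKKMG"
)


def protein_material(
    sequence: str,
    name: str = "protein",
    deuteration: float = 0.0,
    exchange_completeness: float = DEFAULT_EXCHANGE_COMPLETENESS,
) -> Material:
    """Build a :class:`Material` for a protein from its amino-acid sequence.

    Non-labile hydrogens carry ``deuteration`` (fraction replaced by D in
    expression medium); labile hydrogens follow the solvent, but only a
    fraction ``exchange_completeness`` of them is assumed to actually
    exchange — the remainder stays protonated (buried amides).  The
    molecular volume uses the standard 1.21 Å^3/Da protein specific volume
    computed from the hydrogenous mass.
    """
    counts = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0}
    n_labile_total = 0
    for aa in sequence.upper():
        try:
            c, h, n, o, s, labile = AMINO_ACIDS[aa]
        except KeyError:
            raise ValueError(f"unknown amino acid code {aa!r}") from None
        counts["C"] += c
        counts["H"] += h
        counts["N"] += n
        counts["O"] += o
        counts["S"] += s
        n_labile_total += labile
    # terminal H2O of the chain: one extra O, two extra H (both labile: OH + extra amine H)
    counts["O"] += 1
    counts["H"] += 2
    n_labile_total += 2

    n_exch = exchange_completeness * n_labile_total
    n_h_fixed = counts["H"] - n_exch  # includes never-exchanging labile remainder

    b = (
        counts["C"] * B_COH["C"]
        + counts["N"] * B_COH["N"]
        + counts["O"] * B_COH["O"]
        + counts["S"] * B_COH["S"]
    )
    n_nonlabile = counts["H"] - n_labile_total
    # deuteration applies to non-labile H only; non-exchanging labile H stay H
    b += n_nonlabile * (
        (1.0 - deuteration) * B_COH["H"] + deuteration * B_COH["D"]
    )
    b += (n_labile_total - n_exch) * B_COH["H"]

    mass = sum(counts[el] * _ATOMIC_MASS[el] for el in counts)
    volume = PROTEIN_SPECIFIC_VOLUME * mass
    return Material(
        name=name,
        b_nonexchangeable=b,
        n_exchangeable_h=n_exch,
        volume=volume,
        deuteration=deuteration,
    )


# ---------------------------------------------------------------------------
# Materials database
# ---------------------------------------------------------------------------

_DB_PATH = Path(__file__).with_name("data") / "materials.yaml"


def load_materials(path: str | Path | None = None) -> dict[str, Material]:
    """Load the materials table (name, b, V, n_exch per entry) from YAML."""
    with open(path or _DB_PATH) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, Material] = {}
    for name, entry in raw.items():
        out[name] = Material(
            name=name,
            b_nonexchangeable=float(entry["b"]),
            n_exchangeable_h=float(entry.get("n_exch", 0)),
            volume=float(entry["volume"]),
        )
    return out


def default_materials(
    bax_deuteration: float = 0.9,
) -> dict[str, Material]:
    """Shipped materials table plus h- and d-Bax built from sequence.

    d-Bax defaults to 90% deuteration of non-labile hydrogens.
    """
    mats = load_materials()
    mats["protein_h"] = protein_material(BAX_HUMAN_SEQUENCE, name="protein_h")
    mats["protein_d"] = protein_material(
        BAX_HUMAN_SEQUENCE, name="protein_d", deuteration=bax_deuteration
    )
    return mats


def lipid_mixture(
    mats: dict[str, Material], part: str, x_cl: float, name: str | None = None
) -> Material:
    """Mole-fraction-weighted POPC/TOCL pseudo-material.

    ``part`` is ``"head"``, ``"tail"`` or ``"full"`` (head + tail combined,
    used for lipid sequestered in the surface clusters where headgroups are
    not resolved separately).  Scattering length, volume and labile-H count
    are mole-weighted; the SLD is then b/V of the average molecule.
    """
    if not 0.0 <= x_cl <= 1.0:
        raise ValueError(f"x_cl must be in [0, 1], got {x_cl}")
    if part == "full":
        popc = _combine(mats["popc_head"], mats["popc_tail"], "popc")
        tocl = _combine(mats["tocl_head"], mats["tocl_tail"], "tocl")
    else:
        popc = mats[f"popc_{part}"]
        tocl = mats[f"tocl_{part}"]
    return Material(
        name=name or f"lipid_{part}",
        b_nonexchangeable=(1 - x_cl) * popc.b_nonexchangeable
        + x_cl * tocl.b_nonexchangeable,
        n_exchangeable_h=(1 - x_cl) * popc.n_exchangeable_h
        + x_cl * tocl.n_exchangeable_h,
        volume=(1 - x_cl) * popc.volume + x_cl * tocl.volume,
    )


def _combine(a: Material, b: Material, name: str) -> Material:
    return Material(
        name=name,
        b_nonexchangeable=a.b_nonexchangeable + b.b_nonexchangeable,
        n_exchangeable_h=a.n_exchangeable_h + b.n_exchangeable_h,
        volume=a.volume + b.volume,
    )
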