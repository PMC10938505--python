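"""Idealized A-form geometry: template access, helix builder and the
internal-coordinate (NeRF) chain builder used by the synthetic generators.

The frozen per-nucleotide template lives in :mod:`rnagrow._templates` in the
helix frame: residue ``i`` of an ideal chain is the template rotated by
``i * TWIST`` about z and shifted by ``i * RISE`` along z.  The internal
coordinates consumed by the torsion-space builder are measured once from
such an ideal chain, so building with unperturbed torsions reproduces the
ideal helix to floating-point accuracy.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from . import geom
from ._templates import RISE, TWIST, TEMPLATE_COORDS
from .errors import InputError
from .model import BASE_HEAVY_ATOMS, Conformation, PURINES

__all__ = ["RISE", "TWIST", "template_nucleotide", "build_ideal_aform",
           "build_chain_from_torsions", "ideal_internal_coords", "ATOM_ORDER"]

#: Atom order used for all generated residues (5' P group first).
ATOM_ORDER = {
    base: ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
           "C2'", "O2'", "C1'") + BASE_HEAVY_ATOMS[base]
    for base in "AUGC"
}

_SUGAR_RIGID = ("O4'", "C3'", "O3'", "C2'", "O2'", "C1'")
_TRIAD = ("C5'", "C4'", "C3'")


def template_nucleotide(base: str) -> dict:
    """Template heavy-atom coordinates (helix frame) for one nucleotide."""
    try:
        table = TEMPLATE_COORDS[base]
    except KeyError:
        raise InputError(f"unknown base {base!r}") from None
    return {name: np.array(xyz) for name, xyz in table.items()}


def _glyco_axis_atoms(base: str):
    return ("C1'", "N9" if base in PURINES else "N1")


def _residue_atoms(base: str, include_phosphate: bool) -> tuple:
    order = ATOM_ORDER[base]
    if include_phosphate:
        return order
    return tuple(a for a in order if a not in ("P", "OP1", "OP2"))


def _element(name: str) -> str:
    return name[0]


def _assemble(sequence: str, placed: list, provenance=None) -> Conformation:
    names, res_index, elements, coords = [], [], [], []
    for i, (base, pos) in enumerate(zip(sequence, placed), start=1):
        for name in _residue_atoms(base, include_phosphate=(i > 1)):
            names.append(name)
            res_index.append(i)
            elements.append(_element(name))
            coords.append(pos[name])
    return Conformation(sequence, names, res_index, elements,
                        np.array(coords), provenance=provenance)


def build_ideal_aform(sequence: str, provenance=None) -> Conformation:
    """Single-stranded ideal A-form helix for an arbitrary sequence.

    The 5'-terminal residue carries no phosphate group (protonated 5'-OH).
    """
    sequence = str(sequence).upper()
    if not sequence or any(b not in "AUGC" for b in sequence):
        raise InputError(f"invalid sequence {sequence!r}")
    placed = []
    for i, base in enumerate(sequence):
        rot = geom.rotation_about_axis([0.0, 0.0, 1.0], TWIST * i)
        tr = np.array([0.0, 0.0, RISE * i])
        tpl = template_nucleotide(base)
        placed.append({a: rot @ xyz + tr for a, xyz in tpl.items()})
    prov = provenance or {"builder": "ideal_aform"}
    return _assemble(sequence, placed, provenance=prov)


@lru_cache(maxsize=1)
def ideal_internal_coords() -> dict:
    """Internal coordinates of the ideal helix, measured from a built chain."""
    tpl0 = template_nucleotide("A")
    rot = geom.rotation_about_axis([0.0, 0.0, 1.0], TWIST)
    tr = np.array([0.0, 0.0, RISE])
    tpl1 = {a: rot @ xyz + tr for a, xyz in tpl0.items()}
    p0, p1 = tpl0, tpl1
    ic = {
        "bond_o3_p": np.linalg.norm(p1["P"] - p0["O3'"]),
        "bond_p_o5": np.linalg.norm(p1["O5'"] - p1["P"]),
        "bond_o5_c5": np.linalg.norm(p1["C5'"] - p1["O5'"]),
        "bond_c5_c4": np.linalg.norm(p1["C4'"] - p1["C5'"]),
        "bond_c4_c3": np.linalg.norm(p1["C3'"] - p1["C4'"]),
        "ang_c3_o3_p": geom.angle_between(p0["C3'"], p0["O3'"], p1["P"]),
        "ang_o3_p_o5": geom.angle_between(p0["O3'"], p1["P"], p1["O5'"]),
        "ang_p_o5_c5": geom.angle_between(p1["P"], p1["O5'"], p1["C5'"]),
        "ang_o5_c5_c4": geom.angle_between(p1["O5'"], p1["C5'"], p1["C4'"]),
        "ang_c5_c4_c3": geom.angle_between(p1["C5'"], p1["C4'"], p1["C3'"]),
        "epsilon": geom.dihedral(p0["C4'"], p0["C3'"], p0["O3'"], p1["P"]),
        "zeta": geom.dihedral(p0["C3'"], p0["O3'"], p1["P"], p1["O5'"]),
        "alpha": geom.dihedral(p0["O3'"], p1["P"], p1["O5'"], p1["C5'"]),
        "beta": geom.dihedral(p1["P"], p1["O5'"], p1["C5'"], p1["C4'"]),
        "gamma": geom.dihedral(p1["O5'"], p1["C5'"], p1["C4'"], p1["C3'"]),
    }
    return ic


def _place_phosphate_oxygens(pos: dict, o3_prev: np.ndarray) -> None:
    """OP1/OP2 from the P substituent bisector (tetrahedral completion)."""
    u1 = pos["O5'"] - pos["P"]
    u1 /= np.linalg.norm(u1)
    u2 = o3_prev - pos["P"]
    u2 /= np.linalg.norm(u2)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    half = np.radians(119.6 / 2.0)
    for name, sgn in (("OP1", 1.0), ("OP2", -1.0)):
        d = np.cos(half) * bis + sgn * np.sin(half) * perp
        pos[name] = pos["P"] + 1.485 * d / np.linalg.norm(d)


def build_chain_from_torsions(sequence: str, torsions: dict | None = None,
                              chi_offsets=None, provenance=None) -> Conformation:
    """Build a chain in internal coordinates with per-residue torsions.

    ``torsions`` maps any of ``alpha, beta, gamma, epsilon, zeta`` to
    (n_res,) arrays; missing entries (or NaNs) fall back to the ideal A-form
    values.  Junction torsions ``epsilon(i)``/``zeta(i)`` act on the bond
    between residues i and i+1 (stored at index i-1, like
    :func:`rnagrow.model.backbone_torsions`).  ``chi_offsets`` rotates each
    base about its glycosidic bond relative to the template orientation.

    Bond lengths, bond angles and the sugar-ring geometry are those of the
    frozen template (the sugar is rigid; delta is fixed by the C3'-endo
    pucker).  With all-default torsions the result equals
    :func:`build_ideal_aform` up to floating-point error.
    """
    sequence = str(sequence).upper()
    if not sequence or any(b not in "AUGC" for b in sequence):
        raise InputError(f"invalid sequence {sequence!r}")
    n = len(sequence)
    ic = ideal_internal_coords()
    torsions = torsions or {}

    def tors(name, i, default):
        arr = torsions.get(name)
        if arr is None:
            return default
        v = arr[i - 1]
        return default if np.isnan(v) else float(v)

    chi_offsets = np.zeros(n) if chi_offsets is None else np.asarray(chi_offsets, float)

    templates = {b: template_nucleotide(b) for b in set(sequence)}
    placed = []
    for i, base in enumerate(sequence, start=1):
        tpl = templates[base]
        if i == 1:
            pos = {a: xyz.copy() for a, xyz in tpl.items()}
        else:
            prev = placed[-1]
            pos = {}
            pos["P"] = geom.nerf_place(
                prev["C4'"], prev["C3'"], prev["O3'"], ic["bond_o3_p"],
                ic["ang_c3_o3_p"], tors("epsilon", i - 1, ic["epsilon"]))
            pos["O5'"] = geom.nerf_place(
                prev["C3'"], prev["O3'"], pos["P"], ic["bond_p_o5"],
                ic["ang_o3_p_o5"], tors("zeta", i - 1, ic["zeta"]))
            pos["C5'"] = geom.nerf_place(
                prev["O3'"], pos["P"], pos["O5'"], ic["bond_o5_c5"],
                ic["ang_p_o5_c5"], tors("alpha", i, ic["alpha"]))
            pos["C4'"] = geom.nerf_place(
                pos["P"], pos["O5'"], pos["C5'"], ic["bond_c5_c4"],
                ic["ang_o5_c5_c4"], tors("beta", i, ic["beta"]))
            pos["C3'"] = geom.nerf_place(
                pos["O5'"], pos["C5'"], pos["C4'"], ic["bond_c4_c3"],
                ic["ang_c5_c4_c3"], tors("gamma", i, ic["gamma"]))
            # rigid sugar + base via the congruent C5'/C4'/C3' triad
            src = np.array([tpl[a] for a in _TRIAD])
            dst = np.array([pos[a] for a in _TRIAD])
            rot, tr, _ = geom.weighted_superposition(src, dst)
            for a in _SUGAR_RIGID + BASE_HEAVY_ATOMS[base]:
                pos[a] = rot @ tpl[a] + tr
            _place_phosphate_oxygens(pos, prev["O3'"])
        if chi_offsets[i - 1] != 0.0:
            c1, nref = _glyco_axis_atoms(base)
            axis = pos[nref] - pos[c1]
            rot = geom.rotation_about_axis(axis, chi_offsets[i - 1])
            pivot = pos[c1]
            for a in BASE_HEAVY_ATOMS[base]:
                pos[a] = rot @ (pos[a] - pivot) + pivot
        placed.append(pos)
    return _assemble(sequence, placed,
                     provenance=provenance or {"builder": "torsion_chain"})
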