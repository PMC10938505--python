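"""Fluorophore mapping onto chain termini for FRET forward modelling.

A dye conformer is a mock (or MD-derived) fluorophore attached to a
dideoxy-adenosine dinucleotide anchor.  Labeling aligns the sugar+base heavy
atoms of the chain's terminal nucleotide onto the corresponding terminal
nucleotide of the anchor (5' chain end onto the anchor's 3' nucleotide and
vice versa), then transplants the dye atoms if the alignment RMSD and a
clash search pass.  Chain atoms are never moved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geom
from .errors import InputError
from .model import BASE_HEAVY_ATOMS, Conformation, detect_clashes
from .templates import build_ideal_aform

__all__ = ["DyeConformer", "DyeLibrary", "DyePlacement", "LabeledChain",
           "attach_dye", "remap_dye_pair", "synth_dye_library"]

_SUGAR_ALIGN = ("C1'", "C2'", "C3'", "C4'", "O4'", "C5'")


@dataclass
class DyeConformer:
    """One dye conformer: anchor dinucleotide + fluorophore atoms.

    ``anchor`` is a 2-residue Conformation; ``dye_atom_names``/``dye_coords``
    hold the fluorophore; ``center_atom`` names the oxygen used for interdye
    distances and ``dipole_atoms`` the ordered pair defining the transition
    dipole direction.
    """

    dye_name: str
    anchor: Conformation
    dye_atom_names: np.ndarray
    dye_coords: np.ndarray
    center_atom: str
    dipole_atoms: tuple

    def __post_init__(self):
        if self.anchor.n_residues != 2:
            raise InputError("dye anchor must be a dinucleotide")
        names = list(self.dye_atom_names)
        if self.center_atom not in names:
            raise InputError(f"center atom {self.center_atom!r} not in dye atoms")
        for a in self.dipole_atoms:
            if a not in names:
                raise InputError(f"dipole atom {a!r} not in dye atoms")

    def dye_atom(self, name: str) -> np.ndarray:
        idx = list(self.dye_atom_names).index(name)
        return self.dye_coords[idx]


@dataclass
class DyeLibrary:
    """Pool of conformers of one dye."""

    dye_name: str
    conformers: list
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.conformers)


@dataclass(frozen=True)
class DyePlacement:
    """An accepted dye placement, reduced to what FRET models need."""

    center: np.ndarray       # center-oxygen position, Angstrom
    dipole: np.ndarray       # unit transition-dipole vector
    conformer_index: int
    rmsd: float


@dataclass
class LabeledChain:
    """A chain with dye placements at its termini (chain coords untouched)."""

    chain: Conformation
    placements: dict         # end -> DyePlacement (or lists for remapping)


def _terminal_align_atoms(chain: Conformation, end: str, anchor: Conformation,
                          anchor_res: int):
    """Matched (chain_idx, anchor_idx) arrays over sugar+base heavy atoms."""
    res = 1 if end == "5prime" else chain.n_residues
    base = chain.sequence[res - 1]
    names = list(_SUGAR_ALIGN) + list(BASE_HEAVY_ATOMS[base])
    ci, ai = [], []
    for nm in names:
        if chain.has_atom(res, nm) and anchor.has_atom(anchor_res, nm):
            ci.append(chain.atom_index(res, nm))
            ai.append(anchor.atom_index(anchor_res, nm))
    if len(ci) < 3:
        raise InputError(
            f"not enough shared sugar/base atoms to align the {end} terminus")
    return np.array(ci), np.array(ai)


def attach_dye(chain: Conformation, dye: DyeConformer, end: str,
               rmsd_cutoff: float = 0.8, clash_cutoff: float = 2.0,
               conformer_index: int = -1):
    """Align one dye conformer onto a chain terminus.

    Returns a :class:`DyePlacement` on acceptance or a string rejection
    reason (``"rmsd"`` / ``"clash"``).  The anchor's 3' nucleotide is used
    for 5' labeling and its 5' nucleotide for 3' labeling, so the
    fluorophore extends beyond the chain end.
    """
    if end not in ("5prime", "3prime"):
        raise InputError("end must be '5prime' or '3prime'")
    anchor_res = 2 if end == "5prime" else 1
    ci, ai = _terminal_align_atoms(chain, end, dye.anchor, anchor_res)
    rot, trans, wrmsd = geom.weighted_superposition(
        dye.anchor.coords[ai], chain.coords[ci])
    if wrmsd >= rmsd_cutoff:
        return "rmsd"
    dye_xyz = geom.apply_transform(dye.dye_coords, rot, trans)
    # clash search: dye heavy atoms against all chain heavy atoms except the
    # labeled terminal nucleotide (the linkage region)
    res = 1 if end == "5prime" else chain.n_residues
    chain_mask = chain.heavy_mask & (chain.res_index != res)
    if detect_clashes(chain.coords[chain_mask], dye_xyz, clash_cutoff) > 0:
        return "clash"
    names = list(dye.dye_atom_names)
    center = dye_xyz[names.index(dye.center_atom)]
    d1 = dye_xyz[names.index(dye.dipole_atoms[0])]
    d2 = dye_xyz[names.index(dye.dipole_atoms[1])]
    dip = d2 - d1
    dip = dip / np.linalg.norm(dip)
    return DyePlacement(center, dip, conformer_index, wrmsd)


def remap_dye_pair(chain: Conformation, donor_lib: DyeLibrary,
                   acceptor_lib: DyeLibrary, n_attempts: int = 1000,
                   rng=None, max_placements: int = 20,
                   rmsd_cutoff: float = 0.8, clash_cutoff: float = 2.0,
                   acceptor_end: str = "5prime"):
    """Repeatedly try to place a donor/acceptor pair simultaneously.

    Per attempt one conformer is drawn from each library and both must pass
    alignment and clash tests (including a dye-dye clash check).  Returns
    (placements, acceptance_weight) where ``placements`` holds up to
    ``max_placements`` accepted (donor, acceptor) placement pairs and the
    weight is the raw acceptance rate successes / n_attempts.
    """
    rng = np.random.default_rng(rng)
    donor_end = "3prime" if acceptor_end == "5prime" else "5prime"
    successes = 0
    kept = []
    for _ in range(n_attempts):
        di = int(rng.integers(len(donor_lib)))
        aj = int(rng.integers(len(acceptor_lib)))
        pd = attach_dye(chain, donor_lib.conformers[di], donor_end,
                        rmsd_cutoff, clash_cutoff, conformer_index=di)
        if isinstance(pd, str):
            continue
        pa = attach_dye(chain, acceptor_lib.conformers[aj], acceptor_end,
                        rmsd_cutoff, clash_cutoff, conformer_index=aj)
        if isinstance(pa, str):
            continue
        # dye-dye steric check via the placed center/ring proxies
        if np.linalg.norm(pd.center - pa.center) < clash_cutoff:
            continue
        successes += 1
        if len(kept) < max_placements:
            kept.append((pd, pa))
    return kept, successes / n_attempts


# ------------------------------------------------------------ mock library

def synth_dye_library(dye_name: str, n_conformers: int = 100, seed=None,
                      end: str = "donor") -> DyeLibrary:
    """Synthesize a mock dye library with a dideoxy-A2 anchor.

    The fluorophore is a rigid planar six-carbon ring with a central oxygen
    (the distance reference) and an in-plane dipole axis, connected to the
    anchor terminus by a three-carbon linker whose torsions are randomized
    per conformer.  Donor-style dyes hang off the anchor's 5' end (used for
    3' chain labeling), acceptor-style dyes off the 3' end.
    """
    if end not in ("donor", "acceptor"):
        raise InputError("end must be 'donor' or 'acceptor'")
    rng = np.random.default_rng(seed)
    anchor_full = build_ideal_aform("AA")
    # dideoxy: strip the 2'-OH oxygens
    mask = ~np.isin(anchor_full.atom_names, ["O2'"])
    anchor = Conformation("AA", anchor_full.atom_names[mask],
                          anchor_full.res_index[mask],
                          anchor_full.elements[mask],
                          anchor_full.coords[mask],
                          provenance={"builder": "dye_anchor"})
    # linker start: 5'-O5' of residue 1 (donor) or 3'-O3' of residue 2
    if end == "donor":
        a = anchor.atom_coords(1, "C5'")
        b = anchor.atom_coords(1, "O5'")
        c0 = anchor.atom_coords(1, "C4'")
    else:
        a = anchor.atom_coords(2, "C3'")
        b = anchor.atom_coords(2, "O3'")
        c0 = anchor.atom_coords(2, "C4'")
    conformers = []
    ring_local = _hex_ring()
    for k in range(n_conformers):
        tors = rng.uniform(-180.0, 180.0, size=3)
        l1 = geom.nerf_place(c0, a, b, 1.43, 115.0, tors[0])
        l2 = geom.nerf_place(a, b, l1, 1.52, 112.0, tors[1])
        l3 = geom.nerf_place(b, l1, l2, 1.52, 112.0, tors[2])
        # ring plane from the last linker bond
        axis = l3 - l2
        axis /= np.linalg.norm(axis)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, axis)) > 0.95:
            ref = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(axis, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        centre = l3 + 1.8 * axis
        names, coords = ["L1", "L2", "L3", "OX"], [l1, l2, l3, centre]
        for i, (x, y) in enumerate(ring_local):
            names.append(f"C{i + 1}R")
            coords.append(centre + x * axis + y * e1)
        conformers.append(DyeConformer(
            dye_name, anchor, np.array(names, dtype="U4"), np.array(coords),
            center_atom="OX", dipole_atoms=("C1R", "C4R")))
    return DyeLibrary(dye_name, conformers,
                      meta={"generator": "synth_dye_library", "seed": seed,
                            "end": end, "n_conformers": n_conformers})


def _hex_ring(bond: float = 1.40):
    r = bond
    return [(r * np.cos(np.pi / 3 * i), r * np.sin(np.pi / 3 * i))
            for i in range(6)]
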