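"""Core domain types and geometry operations for RNA conformations.

Holds the array-backed :class:`Conformation` (the central currency of the
package), weighted superposition, junction alignment specifications, clash
detection, backbone/glycosidic torsions and simple size metrics.

Conventions: coordinates in Angstrom, angles in degrees, residues indexed
1-based, atom names follow PDB v3 RNA conventions (primed names, ``O5'``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import geom
from .errors import GeometryError, InputError, SequenceMismatchError

__all__ = [
    "AtomRecord",
    "NucleotideUnit",
    "Conformation",
    "AlignmentSpec",
    "weighted_superposition",
    "junction_alignment_spec",
    "detect_clashes",
    "backbone_torsions",
    "radius_of_gyration",
    "end_to_end_distance",
    "normalize_atom_name",
    "normalize_residue_name",
    "BASE_HEAVY_ATOMS",
    "PURINES",
    "PYRIMIDINES",
    "TORSION_NAMES",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("UC")

#: Heavy atoms of each nucleobase (PDB v3 names).
BASE_HEAVY_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
}

#: Backbone atoms expected in every nucleotide (P group absent at 5' termini).
BACKBONE_ATOMS = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")

TORSION_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")

_NAME_ALIASES = {"O5*": "O5'", "C5*": "C5'", "C4*": "C4'", "O4*": "O4'",
                 "C3*": "C3'", "O3*": "O3'", "C2*": "C2'", "O2*": "O2'",
                 "C1*": "C1'", "OP3": "OP3", "O1P": "OP1", "O2P": "OP2"}

_RESNAME_ALIASES = {"ADE": "A", "URA": "U", "URI": "U", "GUA": "G", "CYT": "C",
                    "RA": "A", "RU": "U", "RG": "G", "RC": "C",
                    "A": "A", "U": "U", "G": "G", "C": "C"}


def normalize_atom_name(name: str) -> str:
    """Map legacy atom names (``O5*``, ``O1P``) to PDB v3 names."""
    name = name.strip()
    return _NAME_ALIASES.get(name, name)


def normalize_residue_name(name: str) -> str:
    """Map residue-name variants (``ADE``, ``RA``) to single letters."""
    key = name.strip().upper()
    try:
        return _RESNAME_ALIASES[key]
    except KeyError:
        raise InputError(f"unrecognized residue name {name!r}") from None


def _element_of(atom_name: str) -> str:
    name = atom_name.strip()
    if name.startswith(("H", "1H", "2H", "3H")):
        return "H"
    return name[0]


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: name, element, residue assignment and position."""

    name: str
    element: str
    residue_index: int
    residue_name: str
    coords: np.ndarray

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass(frozen=True)
class NucleotideUnit:
    """One nucleotide: base identity plus its ordered atoms."""

    base: str
    atoms: tuple
    role: str = "retained"  # retained | cap | overlap

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)


class Conformation:
    """One full-atom conformation of an RNA chain.

    Atoms are stored in flat numpy arrays, grouped by residue in 5'->3'
    order with 1-based consecutive residue indices.  This layout makes the
    chain-growth inner loops (superposition, clash search, merging) cheap.
    """

    __slots__ = ("sequence", "atom_names", "res_index", "elements", "coords",
                 "provenance", "_index", "_bounds")

    def __init__(self, sequence, atom_names, res_index, elements, coords,
                 provenance=None, validate=True):
        self.sequence = str(sequence)
        self.atom_names = np.asarray(atom_names, dtype="U4")
        self.res_index = np.asarray(res_index, dtype=np.int32)
        self.elements = np.asarray(elements, dtype="U2")
        self.coords = np.asarray(coords, dtype=float)
        self.provenance = provenance
        self._index = None
        self._bounds = None
        if validate:
            self._validate_layout()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_atoms(cls, sequence: str, atoms: Iterable[AtomRecord],
                   provenance=None) -> "Conformation":
        atoms = list(atoms)
        return cls(
            sequence,
            [a.name for a in atoms],
            [a.residue_index for a in atoms],
            [a.element for a in atoms],
            np.array([a.coords for a in atoms], float),
            provenance=provenance,
        )

    def _validate_layout(self):
        n = len(self.sequence)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError("coords must be (n_atoms, 3)")
        if not (len(self.atom_names) == len(self.res_index) == len(self.elements)
                == len(self.coords)):
            raise InputError("atom array lengths disagree")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates")
        if n == 0 or len(self.coords) == 0:
            raise InputError("empty conformation")
        uniq = np.unique(self.res_index)
        if uniq[0] != 1 or uniq[-1] != n or len(uniq) != n:
            raise InputError("residue indices must be consecutive 1..n")
        if np.any(np.diff(self.res_index) < 0):
            raise InputError("atoms must be grouped by residue in order")

    # -- indexing ----------------------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def _build_index(self):
        if self._index is None:
            self._index = {(int(r), n): i for i, (r, n)
                           in enumerate(zip(self.res_index, self.atom_names))}
        return self._index

    def atom_index(self, residue: int, name: str) -> int:
        """Flat index of atom ``name`` in 1-based ``residue``; KeyError if absent."""
        return self._build_index()[(residue, name)]

    def has_atom(self, residue: int, name: str) -> bool:
        return (residue, name) in self._build_index()

    def atom_coords(self, residue: int, name: str) -> np.ndarray:
        return self.coords[self.atom_index(residue, name)]

    def residue_bounds(self) -> np.ndarray:
        """(n_res + 1,) start offsets of each residue's atom block."""
        if self._bounds is None:
            self._bounds = np.searchsorted(
                self.res_index, np.arange(1, self.n_residues + 2))
        return self._bounds

    def residue_atom_indices(self, residue: int) -> np.ndarray:
        b = self.residue_bounds()
        return np.arange(b[residue - 1], b[residue])

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    # -- views -------------------------------------------------------------
    @property
    def nucleotides(self) -> list:
        out = []
        for i in range(1, self.n_residues + 1):
            idx = self.residue_atom_indices(i)
            atoms = tuple(
                AtomRecord(self.atom_names[j], self.elements[j], int(self.res_index[j]),
                           self.sequence[i - 1], self.coords[j].copy())
                for j in idx
            )
            out.append(NucleotideUnit(self.sequence[i - 1], atoms))
        return out

    def atoms(self):
        for j in range(self.n_atoms):
            yield AtomRecord(self.atom_names[j], self.elements[j],
                             int(self.res_index[j]),
                             self.sequence[self.res_index[j] - 1],
                             self.coords[j])

    # -- geometry ----------------------------------------------------------
    def transformed(self, rot, trans) -> "Conformation":
        new = Conformation.__new__(Conformation)
        new.sequence = self.sequence
        new.atom_names = self.atom_names
        new.res_index = self.res_index
        new.elements = self.elements
        new.coords = geom.apply_transform(self.coords, rot, trans)
        new.provenance = self.provenance
        new._index = self._index
        new._bounds = self._bounds
        return new

    def copy(self) -> "Conformation":
        new = self.transformed(np.eye(3), np.zeros(3))
        new.coords = new.coords.copy()
        return new

    def check_continuity(self, max_o3p: float = 2.5) -> None:
        """Raise unless every internal O3'(i)-P(i+1) distance is < ``max_o3p``."""
        for i in range(1, self.n_residues):
            if not self.has_atom(i + 1, "P"):
                raise InputError(f"residue {i + 1} lacks a phosphate")
            d = np.linalg.norm(self.atom_coords(i, "O3'") - self.atom_coords(i + 1, "P"))
            if d >= max_o3p:
                raise GeometryError(
                    f"chain break at junction {i}-{i + 1}: O3'-P = {d:.2f} A")

    def __repr__(self):
        return (f"<Conformation {self.sequence if self.n_residues <= 12 else self.sequence[:10] + '...'}"
                f" ({self.n_residues} nt, {self.n_atoms} atoms)>")


@dataclass
class AlignmentSpec:
    """Atom pairing used for a rigid-body superposition with a cutoff.

    ``atom_pairs`` holds ((residue, atom_name), (residue, atom_name)) tuples
    referring to the two conformations to be aligned; ``weights`` the per-pair
    fit weights; ``rmsd_cutoff`` the acceptance threshold on the weighted RMSD.
    """

    atom_pairs: list
    weights: np.ndarray
    rmsd_cutoff: float = 0.64

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if len(self.atom_pairs) < 3:
            raise InputError("alignment needs at least 3 atom pairs")
        if len(self.weights) != len(self.atom_pairs):
            raise InputError("weights must match atom pairs")
        if np.any(self.weights <= 0):
            raise InputError("alignment weights must be positive")
        if self.rmsd_cutoff <= 0:
            raise InputError("rmsd_cutoff must be positive")

    def indices(self, conf1: Conformation, conf2: Conformation):
        """Flat atom indices of the pairs in the two conformations."""
        i1 = np.array([conf1.atom_index(r, n) for (r, n), _ in self.atom_pairs])
        i2 = np.array([conf2.atom_index(r, n) for _, (r, n) in self.atom_pairs])
        return i1, i2


def weighted_superposition(mobile, target, weights=None):
    """Weighted Kabsch superposition; see :func:`rnagrow.geom.weighted_superposition`."""
    return geom.weighted_superposition(mobile, target, weights)


def junction_alignment_spec(piece1: Conformation, piece2: Conformation,
                            rmsd_cutoff: float = 0.64,
                            backbone_weight: float = 2.0) -> AlignmentSpec:
    """Alignment specification for merging two chain pieces.

    Pairs the O3' of piece1's next-to-last nucleotide with the O3' of
    piece2's first, the P and O5' of piece1's last nucleotide with those of
    piece2's second (all with doubled weight), and the full heavy-atom base
    plus C1' of piece1's last nucleotide with piece2's second (unit weight).
    """
    n1 = piece1.n_residues
    if n1 < 2 or piece2.n_residues < 2:
        raise InputError("both pieces need at least 2 nucleotides")
    b1 = piece1.sequence[n1 - 1]
    b2 = piece2.sequence[1]
    if b1 != b2:
        raise SequenceMismatchError(
            f"overlap base mismatch: piece1 ends ...{piece1.sequence[-2:]} "
            f"(aligned base {b1}) but piece2 starts {piece2.sequence[:2]}... "
            f"(aligned base {b2})")
    pairs = [((n1 - 1, "O3'"), (1, "O3'")),
             ((n1, "P"), (2, "P")),
             ((n1, "O5'"), (2, "O5'"))]
    weights = [backbone_weight] * 3
    for name in BASE_HEAVY_ATOMS[b1] + ("C1'",):
        pairs.append(((n1, name), (2, name)))
        weights.append(1.0)
    return AlignmentSpec(pairs, np.array(weights), rmsd_cutoff)


def detect_clashes(coords1, coords2, cutoff: float = 2.0,
                   excluded_pairs: set | None = None,
                   excluded1: Sequence[int] = (), excluded2: Sequence[int] = ()) -> int:
    """Count inter-set atom pairs strictly closer than ``cutoff``.

    Uses a KD-tree neighbor search; the result equals the brute-force
    all-pairs count.  ``excluded1``/``excluded2`` are indices into the
    respective coordinate sets to skip entirely; ``excluded_pairs`` holds
    (i, j) index pairs exempted individually.  Distances exactly equal to
    the cutoff do not count (strict less-than).
    """
    if cutoff <= 0:
        raise InputError("clash cutoff must be positive")
    c1 = np.asarray(coords1, float).reshape(-1, 3)
    c2 = np.asarray(coords2, float).reshape(-1, 3)
    keep1 = np.setdiff1d(np.arange(len(c1)), np.asarray(excluded1, int))
    keep2 = np.setdiff1d(np.arange(len(c2)), np.asarray(excluded2, int))
    if len(keep1) == 0 or len(keep2) == 0:
        return 0
    t1 = cKDTree(c1[keep1])
    t2 = cKDTree(c2[keep2])
    # fast path: count_neighbors uses <=; exact filtering only when hits exist
    if t1.count_neighbors(t2, cutoff) == 0:
        return 0
    count = 0
    for ii, neigh in enumerate(t1.query_ball_tree(t2, cutoff)):
        i = keep1[ii]
        for jj in neigh:
            j = keep2[jj]
            if excluded_pairs and (i, j) in excluded_pairs:
                continue
            if np.linalg.norm(c1[i] - c2[j]) < cutoff:
                count += 1
    return count


#: bridging phosphate-group atoms owned by a residue's 5' side
P_GROUP_ATOMS = ("P", "OP1", "OP2", "O5'")


def count_residual_clashes(conf: Conformation, cutoff: float = 2.0) -> int:
    """Heavy-atom pairs closer than ``cutoff`` between different residues.

    Pairs covered by the junction-exclusion pattern used during growth are
    exempt: within a two-residue window, pairs involving an upstream O3' or
    a downstream phosphate group (which includes the covalent O3'-P link).
    """
    mask = conf.heavy_mask
    coords = conf.coords[mask]
    res = conf.res_index[mask]
    names = conf.atom_names[mask]
    tree = cKDTree(coords)
    n_clash = 0
    for i, j in tree.query_pairs(cutoff):
        if np.linalg.norm(coords[i] - coords[j]) >= cutoff:
            continue
        ri, rj = int(res[i]), int(res[j])
        if ri == rj:
            continue
        if ri > rj:
            i, j = j, i
            ri, rj = rj, ri
        if rj - ri <= 2 and (names[i] == "O3'" or names[j] in P_GROUP_ATOMS):
            continue
        n_clash += 1
    return n_clash


def _torsion_or_nan(conf: Conformation, spec) -> float:
    try:
        pts = [conf.atom_coords(r, n) for r, n in spec]
    except KeyError:
        return np.nan
    return geom.dihedral(*pts)


def backbone_torsions(conf: Conformation) -> dict:
    """Standard nucleic-acid torsions per residue.

    Returns a dict of (n_residues,) float arrays keyed by
    ``alpha, beta, gamma, delta, epsilon, zeta, chi``; entries whose defining
    atoms are missing (chain termini) are NaN.
    """
    n = conf.n_residues
    out = {k: np.full(n, np.nan) for k in TORSION_NAMES}
    for i in range(1, n + 1):
        out["alpha"][i - 1] = _torsion_or_nan(
            conf, [(i - 1, "O3'"), (i, "P"), (i, "O5'"), (i, "C5'")]) if i > 1 else np.nan
        out["beta"][i - 1] = _torsion_or_nan(
            conf, [(i, "P"), (i, "O5'"), (i, "C5'"), (i, "C4'")])
        out["gamma"][i - 1] = _torsion_or_nan(
            conf, [(i, "O5'"), (i, "C5'"), (i, "C4'"), (i, "C3'")])
        out["delta"][i - 1] = _torsion_or_nan(
            conf, [(i, "C5'"), (i, "C4'"), (i, "C3'"), (i, "O3'")])
        if i < n:
            out["epsilon"][i - 1] = _torsion_or_nan(
                conf, [(i, "C4'"), (i, "C3'"), (i, "O3'"), (i + 1, "P")])
            out["zeta"][i - 1] = _torsion_or_nan(
                conf, [(i, "C3'"), (i, "O3'"), (i + 1, "P"), (i + 1, "O5'")])
        base = conf.sequence[i - 1]
        if base in PURINES:
            spec = [(i, "O4'"), (i, "C1'"), (i, "N9"), (i, "C4")]
        else:
            spec = [(i, "O4'"), (i, "C1'"), (i, "N1"), (i, "C2")]
        out["chi"][i - 1] = _torsion_or_nan(conf, spec)
    return out


def radius_of_gyration(conf: Conformation, mass_weighted: bool = False) -> float:
    """RMS distance of heavy atoms from their centroid, in Angstrom."""
    mask = conf.heavy_mask
    if not mask.any():
        raise InputError("no heavy atoms")
    xyz = conf.coords[mask]
    if mass_weighted:
        masses = np.array([{"C": 12.011, "N": 14.007, "O": 15.999,
                            "P": 30.974}.get(e, 12.0) for e in conf.elements[mask]])
    else:
        masses = np.ones(len(xyz))
    com = (masses[:, None] * xyz).sum(0) / masses.sum()
    d2 = np.einsum("ij,ij->i", xyz - com, xyz - com)
    return float(np.sqrt((masses * d2).sum() / masses.sum()))


def end_to_end_distance(conf: Conformation) -> float:
    """Distance between O5' of the first and O3' of the last residue."""
    try:
        a = conf.atom_coords(1, "O5'")
        b = conf.atom_coords(conf.n_residues, "O3'")
    except KeyError as exc:
        raise InputError(f"terminal atom missing: {exc}") from None
    return float(np.linalg.norm(a - b))
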