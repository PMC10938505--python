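"""Readers and writers: multi-model PDB ensembles, SAXS .dat files, weights.

PDB I/O is delegated to biotite; this module converts between biotite's
AtomArray stacks and the package's :class:`~rnagrow.model.Conformation`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .errors import InputError, ValidationError
from .model import Conformation, normalize_atom_name, normalize_residue_name

__all__ = [
    "RunConfig",
    "read_ensemble_pdb",
    "write_ensemble_pdb",
    "read_saxs_dat",
    "write_saxs_dat",
    "read_weights",
    "write_weights",
    "write_profile_matrix",
    "read_profile_matrix",
]


class RunConfig(dict):
    """Command configuration with a lossless file round-trip.

    A thin dict wrapper: ``RunConfig.load(RunConfig(...).dump(path)) == self``.
    Always carries a ``version`` stamp.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        from . import __version__
        self.setdefault("version", __version__)

    def dump(self, path) -> str:
        Path(path).write_text(json.dumps(self, indent=2, sort_keys=True) + "\n")
        return str(path)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls(json.loads(Path(path).read_text()))


def _conformation_from_atom_array(arr, model_index=0, source=None) -> Conformation:
    names = [normalize_atom_name(n) for n in arr.atom_name]
    res_ids = np.asarray(arr.res_id, int)
    # remap residue ids to consecutive 1..n
    uniq = np.unique(res_ids)
    remap = {int(r): i + 1 for i, r in enumerate(uniq)}
    res_index = np.array([remap[int(r)] for r in res_ids], int)
    seq_letters = {}
    for rid, rname in zip(res_index, arr.res_name):
        seq_letters.setdefault(int(rid), normalize_residue_name(rname))
    sequence = "".join(seq_letters[i] for i in range(1, len(uniq) + 1))
    elements = np.asarray(arr.element, dtype="U2")
    return Conformation(sequence, names, res_index, elements,
                        np.asarray(arr.coord, float),
                        provenance={"source": source, "model": model_index})


def read_ensemble_pdb(path) -> list[Conformation]:
    """Read a (multi-model) PDB file into a list of conformations."""
    path = str(path)
    pdb = PDBFile.read(path)
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise InputError(f"no models in {path}")
    out = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m)
        out.append(_conformation_from_atom_array(arr, m, source=path))
    ref = out[0]
    for i, conf in enumerate(out[1:], start=2):
        if conf.sequence != ref.sequence or conf.n_atoms != ref.n_atoms or \
                not np.array_equal(conf.atom_names, ref.atom_names):
            raise ValidationError(
                f"model {i} of {path} disagrees with model 1 "
                f"(sequence or atom inventory)")
    return out


def _atom_array_from_conformation(conf: Conformation):
    n = conf.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(conf.coords, np.float32)
    arr.atom_name = conf.atom_names
    arr.res_id = conf.res_index
    arr.res_name = np.array([conf.sequence[r - 1] for r in conf.res_index], dtype="U3")
    arr.element = conf.elements
    arr.chain_id = np.full(n, "A", dtype="U1")
    arr.hetero = np.zeros(n, bool)
    return arr


def write_ensemble_pdb(members, path, weights=None) -> None:
    """Write conformations as a multi-model PDB (MODEL 1..N).

    With ``weights`` given, a two-column sidecar ``<path>.weights.txt`` is
    written alongside.
    """
    members = list(members)
    if not members:
        raise InputError("refusing to write an empty ensemble")
    stack = bst.stack([_atom_array_from_conformation(c) for c in members])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    if weights is not None:
        write_weights(weights, str(path) + ".weights.txt")


def read_saxs_dat(path) -> tuple:
    """Read a whitespace-separated (q, I[, sigma]) profile; '#' comments."""
    data = np.loadtxt(str(path), comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise InputError(f"{path}: expected at least 2 columns (q, I)")
    q = data[:, 0]
    inten = data[:, 1]
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return q, inten, sigma


def write_saxs_dat(path, q, intensity, sigma=None, header="q[1/nm] I sigma") -> None:
    cols = [q, intensity] + ([sigma] if sigma is not None else [])
    np.savetxt(str(path), np.column_stack(cols), header=header)


def read_weights(path) -> np.ndarray:
    """Read an (index, weight) two-column file, sorted by index."""
    data = np.loadtxt(str(path), comments="#", ndmin=2)
    order = np.argsort(data[:, 0])
    return data[order, 1]


def write_weights(weights, path) -> None:
    w = np.asarray(weights, float)
    idx = np.arange(1, len(w) + 1)
    np.savetxt(str(path), np.column_stack([idx, w]),
               fmt=("%d", "%.10e"), header="index weight")


def write_profile_matrix(path, q, intensity_matrix) -> None:
    """Write per-member intensities as a matrix with a q header row."""
    mat = np.vstack([np.asarray(q, float)[None, :], np.asarray(intensity_matrix, float)])
    np.savetxt(str(path), mat, header="row 0: q [1/nm]; rows 1..N: member intensities")


def read_profile_matrix(path) -> tuple:
    mat = np.loadtxt(str(path), comments="#", ndmin=2)
    return mat[0], mat[1:]


def write_json_report(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")
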