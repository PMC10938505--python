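"""Fragment libraries: loading, validation, synthesis, and sequence tiling.

A fragment library is a pool of conformers of one short sequence (tetramers
here).  Heteropolymer libraries use keys ``G + XYZ`` with a fixed 5' guanine
cap; when tiled onto a target sequence each fragment contributes its X and Y
nucleotides, and consecutive fragments must agree at the overlap
(Z of fragment k == X of fragment k+1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError, PlanningError, ValidationError
from .model import Conformation, count_residual_clashes
from .templates import build_chain_from_torsions, build_ideal_aform, ideal_internal_coords

__all__ = ["FragmentLibrary", "TilingPlan", "load_library", "save_library",
           "plan_tiling", "synth_fragment_library", "build_ideal_aform"]


@dataclass
class FragmentLibrary:
    """Conformer pool for one fragment sequence."""

    key: str
    conformers: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.conformers:
            raise ValidationError(f"library {self.key!r} has no conformers")
        bad = [i for i, c in enumerate(self.conformers) if c.sequence != self.key]
        if bad:
            raise ValidationError(
                f"library {self.key!r}: conformers {bad[:10]} have a different sequence")
        ref = self.conformers[0]
        bad = [i for i, c in enumerate(self.conformers)
               if c.n_atoms != ref.n_atoms or not np.array_equal(c.atom_names, ref.atom_names)]
        if bad:
            raise ValidationError(
                f"library {self.key!r}: conformers {bad[:10]} have a different atom inventory")

    def __len__(self):
        return len(self.conformers)


@dataclass
class TilingPlan:
    """How fragment keys tile a target sequence.

    ``contributed`` lists, per fragment, the 0-based local nucleotide indices
    that survive into the untrimmed assembled chain; ``trim_head``/
    ``trim_tail`` say whether the terminal cap nucleotides are removed after
    growth.  The concatenated retained bases equal the target sequence.
    """

    sequence: str
    mode: str
    fragment_keys: list
    contributed: list
    trim_head: bool
    trim_tail: bool
    notes: dict = field(default_factory=dict)

    def assembled_sequence(self) -> str:
        """Sequence of the untrimmed assembled chain."""
        out = []
        for key, idx in zip(self.fragment_keys, self.contributed):
            out.extend(key[i] for i in idx)
        return "".join(out)

    def retained_sequence(self) -> str:
        s = self.assembled_sequence()
        if self.trim_head:
            s = s[1:]
        if self.trim_tail:
            s = s[:-1]
        return s

    def validate(self) -> None:
        if self.retained_sequence() != self.sequence:
            raise PlanningError(
                f"tiling does not reproduce the target: {self.retained_sequence()!r}"
                f" != {self.sequence!r}")
        for k in range(len(self.fragment_keys) - 1):
            if self.fragment_keys[k][-1] != self.fragment_keys[k + 1][1]:
                raise PlanningError(
                    f"junction constraint violated between fragments {k} and {k + 1}: "
                    f"{self.fragment_keys[k]} / {self.fragment_keys[k + 1]}")


def plan_tiling(sequence: str, mode: str = "heteropolymer",
                final_cap_base: str = "A", keep_caps: bool = False) -> TilingPlan:
    """Resolve a target sequence into fragment keys and retained positions.

    Homopolymer mode tiles the repeated 4-mer key (e.g. ``AAAA``); each
    pairwise merge removes one nucleotide from each side, so k fragments
    yield 2k+2 nucleotides and odd target lengths retain one terminal cap.
    Heteropolymer mode tiles ``G + s[2k] s[2k+1] s[2k+2]`` keys whose X/Y
    positions concatenate to the target; the 5' G cap (and for even lengths
    the 3' cap, chosen as ``final_cap_base``) are trimmed after growth.
    """
    sequence = str(sequence).upper()
    n = len(sequence)
    if n < 4:
        raise PlanningError("target sequence must have at least 4 nucleotides")
    if any(b not in "AUGC" for b in sequence):
        raise InputError(f"invalid sequence {sequence!r}")

    if mode in ("homopolymer", "homo"):
        if len(set(sequence)) != 1:
            raise PlanningError("homopolymer mode requires a single-letter sequence")
        base = sequence[0]
        key = base * 4
        if keep_caps:
            raise PlanningError("keep_caps is implicit in homopolymer mode")
        if n % 2 == 0:
            m = (n - 2) // 2
            trim_head = trim_tail = False
        else:
            m = (n - 1) // 2
            trim_head, trim_tail = False, True
        if m < 1:
            raise PlanningError(f"no homopolymer tiling for length {n}")
        contributed = _contributed(m)
        plan = TilingPlan(sequence, "homopolymer", [key] * m, contributed,
                          trim_head, trim_tail,
                          notes={"odd_length_cap_retained": n % 2 == 1})
    elif mode in ("heteropolymer", "hetero"):
        odd = n % 2 == 1
        if odd:
            # the 3' cap of the final fragment is sequence-specified and kept
            m = (n - 1) // 2
            z_last = sequence[n - 1]
            trim_tail = False
        else:
            m = n // 2
            z_last = final_cap_base
            trim_tail = not keep_caps
        if m < 1:
            raise PlanningError(f"no heteropolymer tiling for length {n}")
        keys = []
        for k in range(m):
            x = sequence[2 * k]
            y = sequence[2 * k + 1]
            z = sequence[2 * k + 2] if k < m - 1 else z_last
            keys.append("G" + x + y + z)
        contributed = _contributed(m)
        plan = TilingPlan(sequence, "heteropolymer", keys, contributed,
                          trim_head=not keep_caps, trim_tail=trim_tail,
                          notes={"final_cap_base": z_last,
                                 "odd_length": n % 2 == 1})
    else:
        raise InputError(f"unknown tiling mode {mode!r}")
    plan.validate()
    return plan


def _contributed(m: int) -> list:
    """Retained local indices per fragment after all pairwise merges."""
    if m == 1:
        return [[0, 1, 2, 3]]
    out = []
    for k in range(m):
        if k == 0:
            out.append([0, 1, 2])       # loses nt 4 at its right junction
        elif k == m - 1:
            out.append([1, 2, 3])       # loses nt 1 at its left junction
        else:
            out.append([1, 2])
    return out


# --------------------------------------------------------------- synthesis

_JUNCTION_TORSIONS = ("epsilon", "zeta")
_INTERNAL_TORSIONS = ("alpha", "beta", "gamma")


def synth_fragment_library(key: str, n_conformers: int, noise: float = 5.0,
                           unstack_prob: float = 0.0,
                           interior_unstack_scale: float = 0.25,
                           chi_noise: float | None = None,
                           kink_prob: float = 0.0,
                           reject_self_clashes: bool = True,
                           seed=None) -> FragmentLibrary:
    """Synthesize a fragment library around the ideal A-form geometry.

    Conformers are built in internal coordinates from the idealized
    per-residue templates with i.i.d. Gaussian noise (sd ``noise`` degrees)
    on the backbone torsions alpha/beta/gamma/epsilon/zeta and on chi
    (sd ``chi_noise``, default equal to ``noise``).  With probability
    ``unstack_prob`` per terminal residue (scaled down by
    ``interior_unstack_scale`` for interior residues) the base is flipped by
    120-240 degrees about the glycosidic bond, mimicking the unstacked /
    inverted states of MD fragment libraries.  With probability ``kink_prob``
    per conformer the backbone torsions at the central junction get a large
    perturbation, mimicking the bent/looplike minority states that give
    assembled chains their compact conformations.  Deterministic given
    ``seed``.
    """
    key = str(key).upper()
    if any(b not in "AUGC" for b in key):
        raise InputError(f"invalid fragment key {key!r}")
    if n_conformers < 1:
        raise InputError("n_conformers must be >= 1")
    if noise < 0 or unstack_prob < 0 or unstack_prob > 1:
        raise InputError("noise must be >= 0 and unstack_prob in [0, 1]")
    chi_noise = noise if chi_noise is None else chi_noise
    rng = np.random.default_rng(seed)
    n = len(key)
    ic = ideal_internal_coords()
    conformers = []
    attempts = 0
    max_total_attempts = max(200, 100 * n_conformers)
    while len(conformers) < n_conformers:
        attempts += 1
        if attempts > max_total_attempts:
            raise ValidationError(
                f"library synthesis for {key!r} rejected too many self-clashing "
                f"conformers ({attempts} attempts); lower the noise")
        torsions = {}
        for name in _INTERNAL_TORSIONS:
            torsions[name] = np.full(n, ic[name]) + rng.normal(0.0, noise, n)
        for name in _JUNCTION_TORSIONS:
            torsions[name] = np.full(n, ic[name]) + rng.normal(0.0, noise, n)
        if kink_prob > 0 and n >= 3 and rng.random() < kink_prob:
            # sharp bend at the central junction: the affected residues are
            # the retained (non-aligned) ones, so kinks survive assembly
            mid = n // 2
            for name, idx in (("epsilon", mid - 1), ("zeta", mid - 1),
                              ("alpha", mid)):
                torsions[name][idx] += rng.choice([-1.0, 1.0]) * rng.uniform(40.0, 150.0)
        chi = rng.normal(0.0, chi_noise, n)
        # unstacking events: large chi flips, mostly at the termini
        for i in range(n):
            p = unstack_prob if i in (0, n - 1) else unstack_prob * interior_unstack_scale
            if p > 0 and rng.random() < p:
                chi[i] += rng.choice([-1.0, 1.0]) * rng.uniform(120.0, 240.0)
        conf = build_chain_from_torsions(
            key, torsions, chi_offsets=chi,
            provenance={"library": key, "conformer": len(conformers)})
        # MD libraries contain no self-overlapping structures; emulate that
        # (the filter slightly truncates the torsion distributions)
        if reject_self_clashes and count_residual_clashes(conf) > 0:
            continue
        conformers.append(conf)
    meta = {"generator": "synth_fragment_library", "key": key,
            "reject_self_clashes": reject_self_clashes, "kink_prob": kink_prob,
            "n_conformers": n_conformers, "noise": noise,
            "unstack_prob": unstack_prob,
            "interior_unstack_scale": interior_unstack_scale,
            "chi_noise": chi_noise, "seed": seed}
    return FragmentLibrary(key, conformers, meta)


# ----------------------------------------------------------------- file I/O

def load_library(path) -> FragmentLibrary:
    """Load a library from a multi-model PDB file or directory of PDBs.

    A JSON sidecar ``<path>.meta.json`` is read when present.
    """
    from .io import read_ensemble_pdb

    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.pdb"))
        if not files:
            raise InputError(f"no PDB files in {p}")
        conformers = []
        for f in files:
            conformers.extend(read_ensemble_pdb(f))
    else:
        conformers = read_ensemble_pdb(p)
    key = conformers[0].sequence
    meta = {"source": str(p), "n_conformers": len(conformers)}
    sidecar = Path(str(p) + ".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return FragmentLibrary(key, conformers, meta)


def save_library(lib: FragmentLibrary, path) -> None:
    """Write a library as a multi-model PDB plus a JSON metadata sidecar."""
    from .io import write_ensemble_pdb

    write_ensemble_pdb(lib.conformers, path)
    sidecar = Path(str(path) + ".meta.json")
    meta = {k: v for k, v in lib.meta.items()}
    meta.setdefault("key", lib.key)
    meta["n_conformers"] = len(lib)
    sidecar.write_text(json.dumps(meta, indent=2, default=str) + "\n")
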