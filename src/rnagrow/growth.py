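"""Hierarchical chain growth: pairwise fragment merging with alignment and
clash rejection, scheduled over a binary merge tree to full-length chains.

A merge aligns the junction atoms of two pieces (weighted Kabsch with
doubled backbone weights), rejects pairs whose weighted RMSD exceeds the
cutoff, removes the two overlap nucleotides, takes the bridging phosphate
from the downstream piece, and rejects merged pairs with heavy-atom clashes
outside the junction-exclusion region.  Pools are combined level by level
until the target sequence is reached; ensembles carry uniform weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import geom
from .errors import GrowthFailureError, InputError, ValidationError
from .fragments import FragmentLibrary, TilingPlan
from .model import Conformation, detect_clashes, junction_alignment_spec

__all__ = ["GrowthConfig", "ChainEnsemble", "MergeRejection", "attempt_merge",
           "grow_level", "grow_ensemble", "assemble_mixed", "validate_member",
           "validate_ensemble"]

#: atoms of the bridging phosphate group owned by the downstream piece
_P_GROUP = ("P", "OP1", "OP2", "O5'")


@dataclass(frozen=True)
class GrowthConfig:
    """Cutoffs and bookkeeping for one growth run."""

    rmsd_cutoff: float = 0.64
    clash_cutoff: float = 2.0
    n_chains: int = 10000
    max_attempts: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.rmsd_cutoff <= 0 or self.clash_cutoff <= 0:
            raise InputError("cutoffs must be positive")
        if self.n_chains < 1 or self.max_attempts < 1:
            raise InputError("n_chains and max_attempts must be >= 1")


@dataclass
class ChainEnsemble:
    """Grown chains with per-member statistical weights (uniform after growth)."""

    members: list
    weights: np.ndarray
    config: GrowthConfig | None = None
    merge_statistics: list = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if len(self.weights) != len(self.members):
            raise InputError("weights must match members")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise InputError("weights must be nonnegative and sum to 1")
        seqs = {m.sequence for m in self.members}
        if len(seqs) > 1:
            raise InputError("ensemble members must share one sequence")

    def __len__(self):
        return len(self.members)

    @property
    def sequence(self) -> str:
        return self.members[0].sequence


@dataclass(frozen=True)
class MergeRejection:
    """Stochastic rejection of a fragment pairing (not an error)."""

    reason: str          # "rmsd" | "clash"
    value: float


def _junction_indices(piece1: Conformation, piece2: Conformation, spec):
    i1, i2 = spec.indices(piece1, piece2)
    return i1, i2


def _clash_sets(piece1: Conformation, piece2: Conformation):
    """Atom index sets and junction exemptions for the merge clash search.

    The dropped overlap nucleotides (last of piece1, first of piece2) are
    excluded entirely, as are piece1's bridging O3' against the first
    retained residues of piece2 and piece2's bridging phosphate group
    against the last retained residues of piece1.
    """
    n1 = piece1.n_residues
    keep1 = np.flatnonzero((piece1.res_index != n1) & piece1.heavy_mask)
    keep2 = np.flatnonzero((piece2.res_index != 1) & piece2.heavy_mask)
    o3_idx = piece1.atom_index(n1 - 1, "O3'")
    pgroup_idx = [piece2.atom_index(2, nm) for nm in _P_GROUP if piece2.has_atom(2, nm)]
    return keep1, keep2, o3_idx, pgroup_idx


def _count_junction_clashes(piece1, piece2, coords2, cfg, keep1, keep2,
                            o3_idx, pgroup_idx):
    cutoff = cfg.clash_cutoff
    c1 = piece1.coords[keep1]
    c2 = coords2[keep2]
    t1 = cKDTree(c1)
    t2 = cKDTree(c2)
    if t1.count_neighbors(t2, cutoff) == 0:
        return 0
    n1 = piece1.n_residues
    res1 = piece1.res_index[keep1]
    res2 = piece2.res_index[keep2]
    names1 = keep1  # flat indices into piece1
    count = 0
    for ii, neigh in enumerate(t1.query_ball_tree(t2, cutoff)):
        if not neigh:
            continue
        gi = keep1[ii]
        for jj in neigh:
            gj = keep2[jj]
            d = np.linalg.norm(piece1.coords[gi] - coords2[gj])
            if d >= cutoff:
                continue
            # junction exemptions (windows of 2 retained residues)
            if gi == o3_idx and piece2.res_index[gj] <= 3:
                continue
            if gj in pgroup_idx and piece1.res_index[gi] >= n1 - 2:
                continue
            count += 1
    return count


def attempt_merge(piece1: Conformation, piece2: Conformation,
                  cfg: GrowthConfig | None = None, _cache=None):
    """Try to merge two pieces; returns a Conformation or a MergeRejection.

    On success piece2 is rigidly aligned onto piece1 at the junction, the
    overlap nucleotides are removed and the pieces concatenated; the merged
    chain keeps piece1 up to the O3' of its next-to-last nucleotide while
    the bridging phosphate group comes from piece2's second nucleotide.
    """
    cfg = cfg or GrowthConfig()
    if _cache is None:
        spec = junction_alignment_spec(piece1, piece2, rmsd_cutoff=cfg.rmsd_cutoff)
        i1, i2 = _junction_indices(piece1, piece2, spec)
        clash_sets = _clash_sets(piece1, piece2)
        weights = spec.weights
    else:
        i1, i2, weights, clash_sets = _cache
    rot, trans, wrmsd = geom.weighted_superposition(
        piece2.coords[i2], piece1.coords[i1], weights)
    if wrmsd >= cfg.rmsd_cutoff:
        return MergeRejection("rmsd", wrmsd)
    coords2 = geom.apply_transform(piece2.coords, rot, trans)
    n_clash = _count_junction_clashes(piece1, piece2, coords2, cfg, *clash_sets)
    if n_clash > 0:
        return MergeRejection("clash", float(n_clash))
    return _concatenate(piece1, piece2, coords2)


def _concatenate(piece1: Conformation, piece2: Conformation,
                 coords2: np.ndarray) -> Conformation:
    n1 = piece1.n_residues
    m1 = piece1.res_index != n1
    m2 = piece2.res_index != 1
    seq = piece1.sequence[:-1] + piece2.sequence[1:]
    res2 = piece2.res_index[m2] + (n1 - 2)
    prov = None
    if piece1.provenance is not None or piece2.provenance is not None:
        prov = ("merge", piece1.provenance, piece2.provenance)
    return Conformation(
        seq,
        np.concatenate([piece1.atom_names[m1], piece2.atom_names[m2]]),
        np.concatenate([piece1.res_index[m1], res2]),
        np.concatenate([piece1.elements[m1], piece2.elements[m2]]),
        np.vstack([piece1.coords[m1], coords2[m2]]),
        provenance=prov, validate=False)


def grow_level(pool1, pool2, n_out: int, cfg: GrowthConfig, rng,
               level: int = 0):
    """Merge two pools into ``n_out`` conformations by rejection sampling.

    Members are drawn uniformly with replacement; each output slot retries
    up to ``cfg.max_attempts`` times before raising a growth failure.
    Returns (merged list, acceptance_rate).
    """
    if not pool1 or not pool2:
        raise InputError("pools must be nonempty")
    # all members of a pool share a layout, so the alignment/clash indexing
    # is computed once per pool pair
    spec = junction_alignment_spec(pool1[0], pool2[0], rmsd_cutoff=cfg.rmsd_cutoff)
    i1, i2 = _junction_indices(pool1[0], pool2[0], spec)
    clash_sets = _clash_sets(pool1[0], pool2[0])
    cache = (i1, i2, spec.weights, clash_sets)
    out = []
    attempts = 0
    for _ in range(n_out):
        for trial in range(cfg.max_attempts):
            attempts += 1
            a = pool1[int(rng.integers(len(pool1)))]
            b = pool2[int(rng.integers(len(pool2)))]
            res = attempt_merge(a, b, cfg, _cache=cache)
            if isinstance(res, Conformation):
                out.append(res)
                break
        else:
            rate = len(out) / attempts if attempts else 0.0
            raise GrowthFailureError(
                f"level {level}: exhausted {cfg.max_attempts} attempts "
                f"(acceptance {rate:.3g}, rmsd_cutoff {cfg.rmsd_cutoff}, "
                f"clash_cutoff {cfg.clash_cutoff})",
                level=level, acceptance_rate=rate)
    return out, len(out) / attempts


def _trim_terminal(conf: Conformation, head: bool) -> Conformation:
    """Drop the first or last nucleotide (cap removal after growth)."""
    n = conf.n_residues
    if head:
        mask = conf.res_index != 1
        seq = conf.sequence[1:]
        res = conf.res_index[mask] - 1
    else:
        mask = conf.res_index != n
        seq = conf.sequence[:-1]
        res = conf.res_index[mask]
    return Conformation(seq, conf.atom_names[mask], res, conf.elements[mask],
                        conf.coords[mask], provenance=conf.provenance,
                        validate=False)


def grow_ensemble(plan: TilingPlan, libraries: dict, cfg: GrowthConfig | None = None,
                  rng=None) -> ChainEnsemble:
    """Grow a full ensemble for a tiling plan from fragment libraries.

    Fragments are merged along a deterministic left-to-right binary tree
    (an odd piece at any level carries over unmerged); every level draws
    fresh members with replacement.  Caps are trimmed per the plan.
    """
    cfg = cfg or GrowthConfig()
    missing = [k for k in plan.fragment_keys if k not in libraries]
    if missing:
        raise InputError(f"libraries missing for keys {sorted(set(missing))}")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    pools = [list(libraries[k].conformers) for k in plan.fragment_keys]
    stats = []
    level = 0
    while len(pools) > 1:
        level += 1
        nxt = []
        for k in range(0, len(pools) - 1, 2):
            try:
                merged, rate = grow_level(pools[k], pools[k + 1], cfg.n_chains,
                                          cfg, rng, level=level)
            except GrowthFailureError as exc:
                raise GrowthFailureError(
                    f"growth failed at level {level}, node {k // 2}: {exc}",
                    level=level, acceptance_rate=exc.acceptance_rate) from exc
            stats.append({"level": level, "node": k // 2, "acceptance": rate})
            nxt.append(merged)
        if len(pools) % 2 == 1:
            nxt.append(pools[-1])
        pools = nxt
    members = pools[0]
    if len(members) > cfg.n_chains:
        members = [members[int(i)] for i in rng.integers(len(members), size=cfg.n_chains)]
    elif len(members) < cfg.n_chains:
        members = [members[int(i)] for i in rng.integers(len(members), size=cfg.n_chains)]
    if plan.trim_head:
        members = [_trim_terminal(m, head=True) for m in members]
    if plan.trim_tail:
        members = [_trim_terminal(m, head=False) for m in members]
    for m in members[:1]:
        if m.sequence != plan.sequence:
            raise ValidationError(
                f"grown sequence {m.sequence!r} != target {plan.sequence!r}")
    w = np.full(len(members), 1.0 / len(members))
    return ChainEnsemble(members, w, cfg, stats)


def assemble_mixed(segments, cfg: GrowthConfig | None = None,
                   libraries: dict | None = None, rng=None) -> ChainEnsemble:
    """Assemble alternating structured and flexible segments into chains.

    ``segments`` is an ordered list of dicts: ``{"structured": FragmentLibrary}``
    entries contribute rigid conformers drawn at random, while
    ``{"flexible": TilingPlan}`` entries are grown by HCG (with caps kept so
    that the plan's assembled sequence overlaps each neighbor by two
    nucleotides).  Adjacent segments are joined with the same
    alignment/clash/merge machinery, hierarchically; the default RMSD cutoff
    in this mode is 1.0 A.
    """
    if cfg is None:
        cfg = GrowthConfig(rmsd_cutoff=1.0)
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    pools = []
    stats = []
    for seg in segments:
        if "structured" in seg:
            lib = seg["structured"]
            if len(lib) < 1:
                raise InputError("structured segment with empty library")
            pools.append(list(lib.conformers))
        elif "flexible" in seg:
            plan: TilingPlan = seg["flexible"]
            sub = grow_ensemble(
                replace(plan, trim_head=False, trim_tail=False,
                        sequence=plan.assembled_sequence()),
                libraries or {}, replace(cfg, rmsd_cutoff=0.64), rng=rng)
            stats.extend(sub.merge_statistics)
            pools.append(sub.members)
        else:
            raise InputError("segment must be 'structured' or 'flexible'")
    level = 100  # segment-join levels follow fragment levels in the stats
    while len(pools) > 1:
        level += 1
        nxt = []
        for k in range(0, len(pools) - 1, 2):
            merged, rate = grow_level(pools[k], pools[k + 1], cfg.n_chains,
                                      cfg, rng, level=level)
            stats.append({"level": level, "node": k // 2, "acceptance": rate})
            nxt.append(merged)
        if len(pools) % 2 == 1:
            nxt.append(pools[-1])
        pools = nxt
    members = pools[0]
    if len(members) != cfg.n_chains:
        members = [members[int(i)] for i in rng.integers(len(members), size=cfg.n_chains)]
    w = np.full(len(members), 1.0 / len(members))
    return ChainEnsemble(members, w, cfg, stats)


# ------------------------------------------------------------- validation

def validate_member(conf: Conformation, clash_cutoff: float = 2.0,
                    max_o3p: float = 2.5) -> dict:
    """Post-hoc whole-chain validation: continuity and residual clashes.

    See :func:`rnagrow.model.count_residual_clashes` for the exemption
    pattern, which mirrors the junction exclusions applied during growth.
    """
    from .model import count_residual_clashes

    conf.check_continuity(max_o3p)
    return {"n_clashes": count_residual_clashes(conf, clash_cutoff),
            "continuous": True}


def validate_ensemble(ens: ChainEnsemble, clash_cutoff: float | None = None) -> dict:
    """Validate every member; returns totals."""
    cutoff = clash_cutoff or (ens.config.clash_cutoff if ens.config else 2.0)
    total = 0
    worst = 0
    for m in ens.members:
        r = validate_member(m, cutoff)
        total += r["n_clashes"]
        worst = max(worst, r["n_clashes"])
    return {"total_clashes": total, "worst_member_clashes": worst,
            "n_members": len(ens)}
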