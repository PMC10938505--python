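"""Forward models and ensemble analyses.

SAXS: Debye-sum intensities with tabulated atomic form factors, Guinier
radius of gyration, ensemble averaging, scale/offset fitting and reduced
chi-squared.  FRET: transfer efficiencies under three dye-dynamics models
with explicit orientation factors.  Structure: base-stacking detection with
per-base stacking scores, and pairwise-RMSD ensemble comparison.

Units: q grids are in nm^-1 (the native unit of the data files), coordinates
in Angstrom, FRET distances in nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import geom
from .errors import GeometryError, InputError
from .model import Conformation, PURINES

__all__ = [
    "ScatteringProfile",
    "FretParams",
    "StackRecord",
    "debye_intensity",
    "guinier_rg",
    "ensemble_average_intensity",
    "rms_rg",
    "fit_scale_offset",
    "reduced_chi2",
    "fret_model1",
    "fret_model2",
    "kappa2",
    "fret_model3",
    "detect_stacks",
    "q_stacking",
    "pairwise_rmsd_distribution",
    "StackCriteria",
]

# 4-Gaussian Cromer-Mann form-factor coefficients (a1..a4, b1..b4, c); the
# argument is s = q/(4 pi) in A^-1.  Hydrogens are not tabulated: the models
# here are heavy-atom only.
_CROMER_MANN = {
    "C": ((2.3100, 1.0200, 1.5886, 0.8650),
          (20.8439, 10.2075, 0.5687, 51.6512), 0.2156),
    "N": ((12.2126, 3.1322, 2.0125, 1.1663),
          (0.0057, 9.8933, 28.9975, 0.5826), -11.5290),
    "O": ((3.0485, 2.2868, 1.5463, 0.8670),
          (13.2771, 5.7011, 0.3239, 32.9089), 0.2508),
    "P": ((6.4345, 4.1791, 1.7800, 1.4908),
          (1.9067, 27.1570, 0.5260, 68.1645), 1.1149),
}


@dataclass
class ScatteringProfile:
    """A SAXS profile: q grid (nm^-1), intensities and optional errors."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.q.ndim != 1 or self.intensity.shape != self.q.shape:
            raise InputError("q and intensity must be matching 1-d arrays")
        if np.any(np.diff(self.q) <= 0) or np.any(self.q < 0):
            raise InputError("q must be nonnegative and strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
            if self.sigma.shape != self.q.shape:
                raise InputError("sigma must match q")
            if np.any(self.sigma <= 0):
                raise InputError("sigma must be positive")

    def __len__(self):
        return len(self.q)


@dataclass
class FretParams:
    """Forster-theory parameters: R0 (nm), donor lifetime (ns), fixed kappa^2."""

    r0: float = 5.4
    tau_d: float = 4.0
    kappa2_fixed: float = 2.0 / 3.0

    def __post_init__(self):
        if self.r0 <= 0 or self.tau_d <= 0:
            raise InputError("R0 and tau_D must be positive")


@dataclass
class StackCriteria:
    """Geometric thresholds for calling two bases stacked.

    Two bases stack when their ring centers are within ``max_center_dist``,
    the ring normals agree within ``max_normal_angle``, and the center of one
    ring sits 2-5 A above/below the other's plane with a small lateral offset.
    """

    max_center_dist: float = 5.0
    max_lateral_offset: float = 2.5
    min_axis_offset: float = 2.0
    max_axis_offset: float = 5.0
    max_normal_angle: float = 40.0


@dataclass
class StackRecord:
    """Detected base stacks for one conformation."""

    stacked_pairs: list            # (i, j) 1-based, i < j
    runs: list                     # lengths of maximal consecutive stacks
    q_per_base: np.ndarray         # per-base stacking factor
    n: int                         # chain length

    @property
    def n_stacked_bases(self) -> int:
        return int(np.sum(self.q_per_base > 0))


# --------------------------------------------------------------------- SAXS

def atomic_form_factor(element: str, q_nm: np.ndarray) -> np.ndarray:
    """Cromer-Mann form factor at q (nm^-1) for C/N/O/P."""
    try:
        a, b, c = _CROMER_MANN[element]
    except KeyError:
        raise InputError(f"no form factor tabulated for element {element!r}") from None
    s = (np.asarray(q_nm, float) / 10.0) / (4.0 * np.pi)  # A^-1 / 4pi
    f = np.full_like(s, c, dtype=float)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * s * s)
    return f


def debye_intensity(conf: Conformation, q_grid, mode: str = "form_factor",
                    chunk: int = 32) -> ScatteringProfile:
    """Debye-formula scattering intensity of one conformation.

    I(q) = sum_ab f_a(q) f_b(q) sinc(q r_ab), over heavy atoms.  In
    ``point`` mode all form factors are 1, so I(0) = N^2.
    """
    q = np.asarray(q_grid, float)
    mask = conf.heavy_mask
    if not mask.any():
        raise InputError("no heavy atoms to scatter from")
    xyz = conf.coords[mask] / 10.0  # nm, to match q in nm^-1
    elements = conf.elements[mask]
    n = len(xyz)
    diff = xyz[:, None, :] - xyz[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if mode == "point":
        f = np.ones((len(q), n))
    elif mode == "form_factor":
        uniq = {e: atomic_form_factor(e, q) for e in np.unique(elements)}
        f = np.stack([uniq[e] for e in elements], axis=1)
    else:
        raise InputError(f"unknown mode {mode!r}")
    intensity = np.empty(len(q))
    for k0 in range(0, len(q), chunk):
        qs = q[k0:k0 + chunk, None, None]
        sinc = np.sinc(qs * r / np.pi)  # np.sinc(x) = sin(pi x)/(pi x)
        fk = f[k0:k0 + chunk]
        intensity[k0:k0 + chunk] = np.einsum("ki,kj,kij->k", fk, fk, sinc)
    return ScatteringProfile(q, intensity)


def guinier_rg(profile: ScatteringProfile, n_points: int = 2) -> float:
    """Guinier radius of gyration (Angstrom) from the low-q limit.

    The slope of ln I versus q^2 at q -> 0 is evaluated as a numerical
    first difference over the ``n_points`` smallest q values (default: the
    two lowest points); R_G = sqrt(-3 * slope).
    """
    if len(profile) < 2 or n_points < 2:
        raise InputError("need at least two low-q points")
    q = profile.q[:n_points]
    inten = profile.intensity[:n_points]
    if np.any(inten <= 0):
        raise GeometryError("nonpositive intensity in the Guinier region")
    if n_points == 2:
        slope = (np.log(inten[1]) - np.log(inten[0])) / (q[1] ** 2 - q[0] ** 2)
    else:
        slope = np.polyfit(q ** 2, np.log(inten), 1)[0]
    if slope > 1e-12:
        raise GeometryError("positive Guinier slope: R_G undefined")
    rg_nm = float(np.sqrt(max(-3.0 * slope, 0.0)))
    return rg_nm * 10.0


def ensemble_average_intensity(profiles: Sequence[ScatteringProfile],
                               weights=None) -> ScatteringProfile:
    """Pointwise weighted mean of member profiles on a common q grid."""
    if not profiles:
        raise InputError("no profiles")
    q = profiles[0].q
    for p in profiles[1:]:
        if len(p.q) != len(q) or not np.allclose(p.q, q):
            raise InputError("profiles are not on a common q grid")
    if weights is None:
        weights = np.full(len(profiles), 1.0 / len(profiles))
    w = np.asarray(weights, float)
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise InputError("weights must be normalized")
    stack = np.stack([p.intensity for p in profiles])
    return ScatteringProfile(q, w @ stack)


def rms_rg(rg_values, weights=None) -> float:
    """Root-mean-square radius of gyration, sqrt(sum_i w_i R_G,i^2)."""
    rg = np.asarray(rg_values, float)
    if weights is None:
        weights = np.full(len(rg), 1.0 / len(rg))
    w = np.asarray(weights, float)
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise InputError("weights must be normalized")
    return float(np.sqrt(np.sum(w * rg * rg)))


def fit_scale_offset(i_sim: ScatteringProfile, exp: ScatteringProfile):
    """Weighted least-squares fit of I_exp = a * I_sim + b.

    Minimizes sum_j ((I_j - a I_sim,j - b) / sigma_j)^2 in closed form.
    """
    if exp.sigma is None:
        raise InputError("experimental profile needs sigma")
    if len(exp) != len(i_sim) or not np.allclose(exp.q, i_sim.q):
        raise InputError("profiles are not on a common q grid")
    x = i_sim.intensity
    y = exp.intensity
    wt = 1.0 / exp.sigma ** 2
    sw = wt.sum()
    sx = (wt * x).sum()
    sy = (wt * y).sum()
    sxx = (wt * x * x).sum()
    sxy = (wt * x * y).sum()
    denom = sw * sxx - sx * sx
    if abs(denom) < 1e-12 * max(sw * sxx, 1.0):
        raise GeometryError("singular fit: simulated profile is constant")
    a = (sw * sxy - sx * sy) / denom
    b = (sy - a * sx) / sw
    return float(a), float(b)


def reduced_chi2(i_sim: ScatteringProfile, exp: ScatteringProfile,
                 a: float = 1.0, b: float = 0.0) -> float:
    """(1/M) sum_j ((I_j - a I_sim,j - b)/sigma_j)^2."""
    if exp.sigma is None:
        raise InputError("experimental profile needs sigma")
    if np.any(exp.sigma == 0):
        raise InputError("zero sigma")
    resid = (exp.intensity - a * i_sim.intensity - b) / exp.sigma
    return float(np.mean(resid ** 2))


def residual_sign_summary(i_sim: ScatteringProfile, exp: ScatteringProfile,
                          a: float = 1.0, b: float = 0.0) -> dict:
    """Plain summary of residual signs (counts and number of sign runs)."""
    resid = exp.intensity - a * i_sim.intensity - b
    signs = np.sign(resid)
    signs[signs == 0] = 1
    n_runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    return {"n_positive": int(np.sum(signs > 0)),
            "n_negative": int(np.sum(signs < 0)),
            "n_sign_runs": n_runs}


# --------------------------------------------------------------------- FRET

def fret_model1(r: float, params: FretParams) -> float:
    """E = 1 / (1 + (r/R0)^6) with fast isotropic dye rotation (kappa^2 = 2/3)."""
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise InputError("interdye distance must be positive")
    out = 1.0 / (1.0 + (r / params.r0) ** 6)
    return float(out) if out.ndim == 0 else out


def fret_model2(distances, params: FretParams) -> float:
    """Average the interdye distance over dye placements, then apply model 1."""
    d = np.asarray(distances, float)
    if d.size == 0:
        raise InputError("no dye placements: efficiency undefined")
    return fret_model1(float(d.mean()), params)


def kappa2(mu_d, mu_a, r_hat) -> float:
    """Orientation factor kappa^2 = (muD.muA - 3 (muD.r)(muA.r))^2."""
    mu_d, mu_a, r_hat = (np.asarray(v, float) for v in (mu_d, mu_a, r_hat))
    for v in (mu_d, mu_a, r_hat):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise InputError("kappa2 expects unit vectors")
    val = np.dot(mu_d, mu_a) - 3.0 * np.dot(mu_d, r_hat) * np.dot(mu_a, r_hat)
    return float(val * val)


def fret_model3(r: float, k2: float, params: FretParams) -> float:
    """Static-dye efficiency from an explicit orientation factor.

    k_ET = (3 k2 / 2) tau_D^-1 (R0/r)^6 and E = k_ET/(k_ET + tau_D^-1),
    i.e. E = 1/(1 + (2/(3 k2)) (r/R0)^6).  Reduces to model 1 at k2 = 2/3.
    """
    if r <= 0:
        raise InputError("interdye distance must be positive")
    if k2 < 0:
        raise InputError("kappa^2 must be nonnegative")
    if k2 == 0.0:
        return 0.0
    k_et = 1.5 * k2 / params.tau_d * (params.r0 / r) ** 6
    return float(k_et / (k_et + 1.0 / params.tau_d))


# ----------------------------------------------------------------- stacking

_RING_ATOMS = {
    True: ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
    False: ("N1", "C2", "N3", "C4", "C5", "C6"),
}


def _ring_frames(conf: Conformation):
    """Ring center + unit normal per base; None where ring atoms are missing."""
    frames = []
    for i in range(1, conf.n_residues + 1):
        names = _RING_ATOMS[conf.sequence[i - 1] in PURINES]
        try:
            pts = np.array([conf.atom_coords(i, nm) for nm in names])
        except KeyError:
            frames.append(None)
            continue
        center = pts.mean(0)
        normal = np.linalg.svd(pts - center)[2][2]
        frames.append((center, normal))
    return frames


def _is_stacked(f1, f2, crit: StackCriteria) -> bool:
    c1, n1 = f1
    c2, n2 = f2
    dvec = c2 - c1
    d = np.linalg.norm(dvec)
    if d > crit.max_center_dist:
        return False
    cosang = abs(np.dot(n1, n2))
    if np.degrees(np.arccos(min(1.0, cosang))) >= crit.max_normal_angle:
        return False
    for c, nrm, other in ((c1, n1, c2), (c2, n2, c1)):
        z = abs(np.dot(other - c, nrm))
        rho = np.sqrt(max(d * d - z * z, 0.0))
        if crit.min_axis_offset <= z <= crit.max_axis_offset and rho < crit.max_lateral_offset:
            return True
    return False


def detect_stacks(conf: Conformation, criteria: StackCriteria | None = None,
                  neighbors_only: bool = False) -> StackRecord:
    """Detect stacked base pairs and score bases by stack-run membership."""
    crit = criteria or StackCriteria()
    frames = _ring_frames(conf)
    n = conf.n_residues
    pairs = []
    for i in range(n):
        if frames[i] is None:
            continue
        jmax = min(i + 1, n - 1) if neighbors_only else n - 1
        for j in range(i + 1, jmax + 1):
            if frames[j] is None:
                continue
            if _is_stacked(frames[i], frames[j], crit):
                pairs.append((i + 1, j + 1))
    # maximal runs of consecutively stacked bases
    consecutive = {(i, j) for i, j in pairs if j == i + 1}
    runs = []
    run_of_base = np.zeros(n, dtype=int)  # run length the base belongs to
    i = 1
    while i <= n:
        length = 1
        while i + length <= n and (i + length - 1, i + length) in consecutive:
            length += 1
        if length >= 2:
            runs.append(length)
            run_of_base[i - 1:i - 1 + length] = length
        i += length
    qpb = np.array([q_stacking_factor(int(L), n) for L in run_of_base]) if n >= 2 \
        else np.zeros(n)
    return StackRecord(pairs, runs, qpb, n)


def q_stacking_factor(n_stacked: int, n: int) -> float:
    """Per-base stacking factor for a base in a consecutive stack.

    With c = n/(n-1): 0 for unstacked bases, 0.25c for runs of 2, 0.5c for
    runs of 3, and c - c/(n_stacked - 1) for runs of >= 4.
    """
    if n < 2:
        raise InputError("chain length must be >= 2 for stacking factors")
    c = n / (n - 1.0)
    if n_stacked <= 1:
        return 0.0
    if n_stacked == 2:
        return 0.25 * c
    if n_stacked == 3:
        return 0.5 * c
    return c - c / (n_stacked - 1.0)


def q_stacking(record: StackRecord, n: int | None = None) -> np.ndarray:
    """Per-base stacking factors of a :class:`StackRecord` (already scored)."""
    n = record.n if n is None else n
    if n < 2:
        raise InputError("chain length must be >= 2")
    return record.q_per_base


# ------------------------------------------------------------ ensemble RMSD

def pairwise_rmsd_distribution(ens_a, ens_b=None, n_pairs: int = 1000,
                               rng=None, exhaustive: bool = False) -> np.ndarray:
    """Heavy-atom RMSDs after optimal superposition for sampled member pairs.

    With ``ens_b`` omitted the within-ensemble distribution is sampled
    (self-pairs excluded).  ``exhaustive`` computes all cross pairs instead.
    """
    from .growth import ChainEnsemble  # cycle guard

    members_a = ens_a.members if isinstance(ens_a, ChainEnsemble) else list(ens_a)
    same = ens_b is None
    members_b = members_a if same else (
        ens_b.members if isinstance(ens_b, ChainEnsemble) else list(ens_b))
    ref = members_a[0]
    for m in members_a + members_b:
        if m.sequence != ref.sequence or m.n_atoms != ref.n_atoms:
            raise InputError("ensembles must share sequence and atom inventory")
    mask = ref.heavy_mask
    rng = np.random.default_rng(rng)
    if exhaustive:
        idx = [(i, j) for i in range(len(members_a)) for j in range(len(members_b))
               if not (same and i == j)]
    else:
        idx = []
        while len(idx) < n_pairs:
            i = int(rng.integers(len(members_a)))
            j = int(rng.integers(len(members_b)))
            if same and i == j:
                continue
            idx.append((i, j))
    out = np.empty(len(idx))
    for k, (i, j) in enumerate(idx):
        x = members_a[i].coords[mask]
        y = members_b[j].coords[mask]
        _, _, w = geom.weighted_superposition(x, y)
        out[k] = w
    return out
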