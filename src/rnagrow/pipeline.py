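"""End-to-end synthetic demo pipeline.

Synthesizes fragment libraries, grows a small ensemble, computes SAXS, FRET
and stacking observables, generates a self-consistent "experimental" profile
from a biased sub-ensemble and reweights against it.  Everything is
deterministic for a given seed; the report is a plain dict of diagnostics.
"""

from __future__ import annotations

import numpy as np

from . import __version__
from .bioen import reweight_saxs
from .dyes import remap_dye_pair, synth_dye_library
from .fragments import plan_tiling, synth_fragment_library
from .growth import GrowthConfig, grow_ensemble, validate_ensemble
from .model import end_to_end_distance, radius_of_gyration
from .observables import (FretParams, ScatteringProfile, debye_intensity,
                          detect_stacks, ensemble_average_intensity,
                          fit_scale_offset, fret_model1, fret_model2,
                          fret_model3, guinier_rg, kappa2, reduced_chi2,
                          rms_rg)

__all__ = ["run_demo_pipeline"]


def run_demo_pipeline(seed: int = 0, n_chains: int = 200, n_lib: int = 150,
                      sequence: str = "A" * 30, noise: float = 4.0,
                      unstack_prob: float = 0.08) -> dict:
    """Run the full synthetic workflow at desk scale; returns a report dict."""
    rng = np.random.default_rng(seed)
    report = {"version": __version__, "seed": seed, "sequence": sequence,
              "n_chains": n_chains, "n_lib": n_lib}

    # 1. library + growth
    mode = "homopolymer" if len(set(sequence)) == 1 else "heteropolymer"
    plan = plan_tiling(sequence, mode)
    libs = {key: synth_fragment_library(key, n_lib, noise=noise,
                                        unstack_prob=unstack_prob,
                                        seed=int(rng.integers(2 ** 31)))
            for key in set(plan.fragment_keys)}
    cfg = GrowthConfig(n_chains=n_chains, seed=int(rng.integers(2 ** 31)))
    ens = grow_ensemble(plan, libs, cfg)
    report["growth"] = {
        "n_members": len(ens),
        "acceptance_rates": [s["acceptance"] for s in ens.merge_statistics],
        "validation": validate_ensemble(ens),
    }

    # 2. structural observables
    rgs = np.array([radius_of_gyration(m) for m in ens.members])
    e2e = np.array([end_to_end_distance(m) for m in ens.members])
    stacks = [detect_stacks(m, neighbors_only=True) for m in ens.members[:50]]
    report["structure"] = {
        "rms_rg": rms_rg(rgs, ens.weights),
        "mean_rg": float(rgs.mean()),
        "mean_end_to_end": float(e2e.mean()),
        "mean_stacked_fraction": float(np.mean(
            [s.n_stacked_bases / s.n for s in stacks])),
    }

    # 3. SAXS with a self-consistent synthetic experiment
    q = np.linspace(0.05, 3.0, 60)
    profiles = [debye_intensity(m, q) for m in ens.members]
    avg = ensemble_average_intensity(profiles, ens.weights)
    report["saxs"] = {"guinier_rg": guinier_rg(avg)}
    # biased "experiment": compact half of the ensemble, scaled and offset
    order = np.argsort(rgs)
    half = order[: max(2, len(order) // 2)]
    w_exp = np.zeros(len(ens))
    w_exp[half] = 1.0 / len(half)
    i_exp = ensemble_average_intensity(profiles, w_exp)
    a_true, b_true = 1.7, 0.3 * i_exp.intensity[-1]
    sigma = 0.01 * a_true * i_exp.intensity + 1e-9
    exp = ScatteringProfile(q, a_true * i_exp.intensity + b_true, sigma)
    # sanity: a profile generated from the ensemble average itself must fit
    # with zero residual after the scale/offset fit
    exp_self = ScatteringProfile(q, 1.3 * avg.intensity + 0.1,
                                 0.01 * avg.intensity + 1e-9)
    a_s, b_s = fit_scale_offset(avg, exp_self)
    report["saxs"]["chi2_self_consistent"] = reduced_chi2(avg, exp_self, a_s, b_s)

    a0, b0 = fit_scale_offset(avg, exp)
    chi2_before = reduced_chi2(avg, exp, a0, b0)
    res = reweight_saxs(np.stack([p.intensity for p in profiles]), exp,
                        theta=10.0, w0=ens.weights)
    report["reweight"] = {
        "chi2_before": chi2_before,
        "chi2_after": res.chi2_reduced,
        "skl": res.skl,
        "a": res.nuisance[0],
        "b": res.nuisance[1],
        "theta": res.theta,
    }

    # 4. FRET on a handful of members with mock dyes
    donor = synth_dye_library("mock-donor", 40, seed=seed + 1, end="donor")
    acceptor = synth_dye_library("mock-acceptor", 40, seed=seed + 2, end="acceptor")
    params = FretParams()
    e1, e2_vals, e3, wts = [], [], [], []
    for m in ens.members[: min(30, len(ens))]:
        placements, weight = remap_dye_pair(
            m, donor, acceptor, n_attempts=50, rng=rng)
        if not placements:
            continue
        pd, pa = placements[0]
        r_nm = float(np.linalg.norm(pd.center - pa.center)) / 10.0
        e1.append(fret_model1(r_nm, params))
        dists = [np.linalg.norm(d.center - a.center) / 10.0
                 for d, a in placements]
        e2_vals.append(fret_model2(dists, params))
        rvec = pa.center - pd.center
        rhat = rvec / np.linalg.norm(rvec)
        k2 = kappa2(pd.dipole, pa.dipole, rhat)
        e3.append(fret_model3(r_nm, k2, params))
        wts.append(weight)
    wts = np.asarray(wts, float)
    report["fret"] = {
        "n_labeled": len(e1),
        "mean_e_model1": float(np.mean(e1)) if e1 else None,
        "mean_e_model2": (float(np.average(e2_vals, weights=wts))
                          if len(e2_vals) and wts.sum() > 0 else None),
        "mean_e_model3": float(np.mean(e3)) if e3 else None,
        "mean_acceptance_weight": float(wts.mean()) if len(wts) else None,
    }
    return report
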