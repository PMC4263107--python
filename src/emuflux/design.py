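"""Tracer experimental design by the D-criterion and per-flux partial design.

The squared volume of the free-flux confidence ellipsoid for a candidate
tracer is D = det Σ_θ = det [H_SSR]⁻¹ evaluated at a supplied flux point
(θ_true in simulations, literature values otherwise); its 2p-th root reads as
an average confidence-interval length.  General design minimizes the
2p-th-root D ratio against a reference tracer over a mixture simplex of up to
three candidate isotopomers; partial design minimizes the linearized standard
deviation √([H]⁻¹)_ii of one targeted free flux.  The measured-fragment
retention (detection filter) is recomputed per candidate tracer before the
Hessian is built, because which masses clear the filter depends on the
tracer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emu import TracerSpec, simulate_mids
from .measurement import MeasurementSet, detection_filter, simulate_fragment

__all__ = ["DesignPoint", "design_measurements", "d_factor", "general_optimize", "partial_optimize", "rank_tracers"]


@dataclass
class DesignPoint:
    mixture: tuple  # fractions over the candidate tracer list
    D: float
    root_ratio: float  # 2p-th root of D / D_ref (1.0 when no reference)
    sd_lin: np.ndarray  # per-free-flux linearized sd at this design
    flagged: str = ""


def _mixture_spec(candidates, fractions, purity=0.99, background=0.0107) -> TracerSpec:
    """Mix candidate single-substrate tracer specs with molar fractions."""
    substrate_components = {}
    for frac, cand in zip(fractions, candidates):
        if frac == 0.0:
            continue
        for sp, comps in cand.mixtures.items():
            acc = substrate_components.setdefault(sp, [])
            for f, labeled in comps:
                acc.append((frac * f, labeled))
    # candidates may label different substrates; unlisted substrates of a
    # candidate are implicitly unlabeled for that mixture share
    all_species = {sp for cand in candidates for sp in cand.mixtures}
    for sp in all_species:
        present = sum(f for f, _ in substrate_components.get(sp, []))
        if present < 1.0 - 1e-12:
            substrate_components.setdefault(sp, []).append((1.0 - present, frozenset()))
    return TracerSpec(substrate_components, purity=purity, background=background)


def design_measurements(model_builder, tracer, theta_eval, sigma_mid=0.004, threshold=0.04):
    """Synthetic noise-free measurement set for a candidate tracer.

    ``model_builder`` is a callable (tracer, measurements) → FluxModel so the
    caller controls fragments and efflux layout; retention is recomputed from
    the simulated abundances at θ_eval under the 4 mol% detection filter.
    """
    probe = model_builder(tracer, None)
    sims = {}
    u = probe.partition.flux_dict(theta_eval, check=False)
    mdvs = simulate_mids(probe.emu_network, u, tracer)
    frags = probe.experiments[0].fragments
    for name, frag in frags.items():
        sims[name] = simulate_fragment(mdvs, frag, c13_background=probe.c13_background)
    retained = detection_filter(sims, threshold)
    mids = {
        name: (
            np.array(idx),
            sims[name][list(idx)],
            np.full(len(idx), sigma_mid),
        )
        for name, idx in retained.items()
        if len(idx)
    }
    effluxes = probe.experiments[0].measurements.effluxes if probe.experiments[0].measurements else {}
    return MeasurementSet(mids, dict(effluxes))


def d_factor(model, theta_eval) -> tuple:
    """(D, 2p-th root of D) at θ_eval for the model's current measurements.

    D = det [JᵀJ]⁻¹; a singular Gauss–Newton matrix yields D = +inf (the
    design leaves some flux direction unidentified).
    """
    from .statistics import residual_jacobian

    J = residual_jacobian(model, np.asarray(theta_eval, float))
    H = J.T @ J
    p = model.p
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return float("inf"), float("inf")
    logD = -logdet
    return float(np.exp(logD)), float(np.exp(logD / (2 * p)))


def _sd_lin(model, theta_eval) -> np.ndarray:
    from .statistics import residual_jacobian

    J = residual_jacobian(model, np.asarray(theta_eval, float))
    H = J.T @ J
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(model.p, np.inf)
    return np.sqrt(np.maximum(np.diag(cov), 0.0))


def _simplex_grid(k: int, step: float):
    """Lattice of mixture fractions over a k-candidate simplex."""
    m = int(round(1.0 / step))
    if k == 1:
        yield (1.0,)
        return
    if k == 2:
        for i in range(m + 1):
            yield (i / m, 1 - i / m)
        return
    for i in range(m + 1):
        for j in range(m + 1 - i):
            yield (i / m, j / m, (m - i - j) / m)


def _evaluate(problem_for, theta_eval, fractions):
    model = problem_for(fractions)
    D, root = d_factor(model, theta_eval)
    sd = _sd_lin(model, theta_eval)
    return model, D, root, sd


def general_optimize(problem_for, theta_eval, n_candidates, reference_fractions=None, step=0.02, p=None):
    """Grid scan + refinement of the 2p-th-root D ratio over the simplex.

    ``problem_for(fractions)`` builds the FluxModel for a candidate mixture.
    Returns (best DesignPoint, surface list of (fractions, D, root)).
    """
    if n_candidates > 3:
        raise ValueError("mixture space supports at most 3 candidate isotopomers")
    if reference_fractions is not None:
        _, D_ref, root_ref, _ = _evaluate(problem_for, theta_eval, reference_fractions)
    else:
        D_ref = root_ref = None

    surface = []
    best = None
    for frac in _simplex_grid(n_candidates, step):
        model, D, root, sd = _evaluate(problem_for, theta_eval, frac)
        surface.append((frac, D, root))
        if np.isfinite(D) and (best is None or D < best[1]):
            best = (frac, D, root, sd)
    if best is None:
        raise RuntimeError("all grid points produced a singular design Hessian")

    # local refinement from the best cell (coordinate descent on the simplex)
    frac = np.array(best[0])
    D_best = best[1]
    h = step / 2
    for _ in range(20):
        improved = False
        for i in range(n_candidates):
            for j in range(n_candidates):
                if i == j:
                    continue
                trial = frac.copy()
                move = min(h, trial[j])
                if move <= 0:
                    continue
                trial[i] += move
                trial[j] -= move
                _, D, root, sd = _evaluate(problem_for, theta_eval, tuple(trial))
                if D < D_best:
                    frac, D_best = trial, D
                    best = (tuple(trial), D, root, sd)
                    improved = True
        if not improved:
            h /= 2
            if h < step / 16:
                break

    frac, D, root, sd = best
    ratio = 1.0 if D_ref is None else (D / D_ref) ** (1.0 / (2 * (p or len(sd))))
    return DesignPoint(tuple(frac), D, ratio, sd), surface


def partial_optimize(problem_for, theta_eval, target_index: int, n_candidates, step=0.02, flat_tol=1e-10):
    """Minimize the linearized sd of one targeted free flux over the simplex."""
    surface = []
    best = None
    for frac in _simplex_grid(n_candidates, step):
        model, D, _, sd = _evaluate(problem_for, theta_eval, frac)
        val = sd[target_index]
        surface.append((frac, val))
        if np.isfinite(val) and (best is None or val < best[1]):
            best = (frac, val, sd, D)
    if best is None:
        raise RuntimeError("all grid points produced a singular design Hessian")
    vals = np.array([v for _, v in surface if np.isfinite(v)])
    flagged = "flat" if vals.size and vals.max() - vals.min() < flat_tol * max(1.0, vals.mean()) else ""
    frac, val, sd, D = best
    return DesignPoint(tuple(frac), D, 1.0, sd, flagged=flagged), surface


def rank_tracers(problem_for_tracer, theta_eval, tracers):
    """Stable ranking of candidate tracers by D (ties keep input order)."""
    rows = []
    for k, tr in enumerate(tracers):
        model = problem_for_tracer(tr)
        D, root = d_factor(model, theta_eval)
        rows.append({"index": k, "tracer": tr, "D": D, "root_2p": root})
    rows.sort(key=lambda r: (r["D"], r["index"]))
    return rows
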