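"""Goodness-of-fit, identifiability, linearized statistics, Monte Carlo and
profile-likelihood confidence intervals, and the normalized flux precision η.

The χ² acceptance test is two-sided: a statistically adequate fit satisfies

    χ²_{α/2}(W−p) < Ξ < χ²_{1−α/2}(W−p)

strictly — an objective far *below* the band signals overfitting just as one
above it signals model inadequacy.  Confidence intervals come from a
Monte Carlo loop (corrupt the measured data, refit, collect the flux
estimates) summarized by either tail order statistics ("discarding", robust
to stray non-global refits) or mean ± z·sd ("mean-varianced"); bound
convergence is monitored through sliding-window spreads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.linalg import null_space

from .measurement import corrupt

__all__ = [
    "chi2_gof",
    "residual_normality",
    "identifiability",
    "residual_jacobian",
    "linearized_stats",
    "monte_carlo_ci",
    "nonlinear_ci",
    "eta",
    "sum_eta",
]


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def chi2_gof(xi: float, W: int, p: int, alpha: float = 0.05) -> dict:
    """Two-sided χ² band test of the converged objective Ξ."""
    dof = W - p
    if dof <= 0:
        raise ValueError(f"W - p = {dof} <= 0: problem not identifiable, GOF undefined")
    lo = sps.chi2.ppf(alpha / 2, dof)
    hi = sps.chi2.ppf(1 - alpha / 2, dof)
    return {
        "xi": float(xi),
        "dof": dof,
        "alpha": alpha,
        "lower": float(lo),
        "upper": float(hi),
        "accept": bool(lo < xi < hi),  # strict: band edges fail
        "below": bool(xi <= lo),
        "above": bool(xi >= hi),
    }


def residual_normality(residuals, alpha: float = 0.05, line: float = 1.96) -> dict:
    """N(0,1) check of the weighted residuals plus per-residual flags.

    The Kolmogorov–Smirnov statistic is combined with two "plot" anomalies:
    individual residuals beyond the two-sided 95% reference lines (flagged)
    or far outside them (extreme, |r| > 4), and a suspiciously small overall
    spread (an overfit signal, e.g. from fitting uncorrupted data).  The
    verdict rejects when the test and the high-value anomaly agree, when the
    spread is degenerate, or when several extreme residuals appear — a
    handful of |r| > 4 values is overwhelming evidence on its own even though
    the blunt KS statistic barely moves.
    """
    r = np.asarray(residuals, float)
    ks_stat, ks_p = sps.kstest(r, "norm")
    flags = np.abs(r) > line
    extreme = np.abs(r) > 4.0
    suspicious_small = bool(r.size and np.std(r) < 0.3)
    rejected = bool(
        (ks_p < alpha and (extreme.any() or suspicious_small))
        or suspicious_small
        or extreme.sum() >= 3
    )
    return {
        "ks_stat": float(ks_stat),
        "ks_pvalue": float(ks_p),
        "flags": np.where(flags)[0],
        "extreme": np.where(extreme)[0],
        "suspicious_small": suspicious_small,
        "rejected": rejected,
    }


# ---------------------------------------------------------------------------
# linearized statistics
# ---------------------------------------------------------------------------

def residual_jacobian(model, theta, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the weighted residual vector w.r.t. θ."""
    theta = np.asarray(theta, float)
    r0 = model.residuals(theta)
    J = np.zeros((r0.size, theta.size))
    for k in range(theta.size):
        h = rel_step * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        J[:, k] = (model.residuals(tp) - model.residuals(tm)) / (2 * h)
    return J


def identifiability(J, tol: float = 1e-8):
    """Numerical null space of the residual Jacobian; empty ⇒ identifiable."""
    J = np.asarray(J, float)
    ns = null_space(J, rcond=tol)
    return ns


@dataclass
class LinStats:
    jacobian: np.ndarray
    hessian: np.ndarray  # Gauss–Newton JᵀJ (Hessian of SSR = Ξ/2)
    covariance_theta: np.ndarray
    covariance_u: np.ndarray
    contribution_matrix: np.ndarray  # n × w, rows sum to 1
    null_basis: np.ndarray
    flux_ids: list
    sd_theta: np.ndarray = field(init=False)

    def __post_init__(self):
        d = np.diag(self.covariance_theta)
        self.sd_theta = np.sqrt(np.maximum(d, 0.0))


def linearized_stats(model, theta, tol: float = 1e-8) -> LinStats:
    """Gauss–Newton covariance and measurement-contribution matrix at θ̂.

    H_SSR = JᵀJ; Σ_θ = H⁻¹; Σ_u = Z Σ_θ Zᵀ.  The contribution matrix gives
    measurement j's share of flux i's linearized variance,
    CM_ij = (Z H⁻¹ Jᵀ)²_ij / Σ_j (·)² — its rows sum to one exactly because
    Σ_u = (Z H⁻¹ Jᵀ)(Z H⁻¹ Jᵀ)ᵀ.
    """
    J = residual_jacobian(model, theta)
    H = J.T @ J
    ns = null_space(J, rcond=tol)
    if ns.shape[1] > 0:
        cov = np.linalg.pinv(H)
    else:
        cov = np.linalg.inv(H)
    Z = model.partition.Z
    cov_u = Z @ cov @ Z.T
    G = Z @ cov @ J.T  # n × w sensitivity of fluxes to (scaled) measurements
    G2 = G**2
    denom = G2.sum(axis=1, keepdims=True)
    denom[denom == 0.0] = 1.0
    CM = G2 / denom
    return LinStats(J, H, cov, cov_u, CM, ns, list(model.partition.flux_ids))


# ---------------------------------------------------------------------------
# Monte Carlo confidence intervals
# ---------------------------------------------------------------------------

def _mc1_bounds(sorted_est, gamma):
    """Discarding strategy: drop ⌊L(1−γ)/2⌋ estimates from each tail."""
    L = len(sorted_est)
    d = int(np.floor(L * (1 - gamma) / 2 + 1e-9))
    return float(sorted_est[d]), float(sorted_est[L - 1 - d])


def _mc2_bounds(est, gamma):
    """Mean-varianced strategy: mean ± z_{(1+γ)/2} · sd."""
    z = sps.norm.ppf((1 + gamma) / 2)
    m, s = float(np.mean(est)), float(np.std(est, ddof=1))
    return m - z * s, m + z * s


def _window_spreads(trace, M):
    """Sliding-window spreads of a bound trace: (Δ absolute, δ relative %)."""
    win = np.asarray(trace[-M:], float)
    delta_abs = float(win.max() - win.min())
    mean = np.abs(win.mean())
    delta_rel = float("inf") if mean == 0 else 100.0 * delta_abs / mean
    return delta_abs, delta_rel


@dataclass
class MonteCarloCIResult:
    estimates: np.ndarray  # L × n flux estimate matrix U
    flux_ids: list
    gammas: tuple
    bounds: dict  # (gamma, strategy) -> (n, 2) LB/UB
    traces: dict  # (gamma, strategy) -> list of (L, n, 2) snapshots
    convergence: dict  # (gamma, strategy) -> per-flux per-bound verdicts
    n_trials: int
    n_failed: int
    seeds: dict

    def interval(self, flux_id, gamma=0.95, strategy="MC-1"):
        i = self.flux_ids.index(flux_id)
        lb, ub = self.bounds[(gamma, strategy)][i]
        return float(lb), float(ub)

    def width(self, flux_id, gamma=0.95, strategy="MC-1"):
        lb, ub = self.interval(flux_id, gamma, strategy)
        return ub - lb


def monte_carlo_ci(
    model,
    theta_hat,
    L_max: int = 500,
    window: int = 40,
    n_as: int = 3,
    k_nr: int = 50,
    tt: float = 1e-4,
    eps: float = 1e-4,
    seed=0,
    gammas=(0.68, 0.95),
    strategies=("MC-1", "MC-2"),
    max_failure_fraction: float = 0.2,
    online_stop: bool = False,
    rigorous_rel: float = 1.0,
    relaxed_rel: float = 10.0,
    absolute_tol: float = 2.0,
) -> MonteCarloCIResult:
    """Monte Carlo flux confidence intervals with convergence control.

    Each trial corrupts the measured data with N(0, σ) noise and refits using
    a multi-runs-per-trial strategy: the first run starts from θ̂; up to
    ``n_as`` additional restarts from random feasible points are taken when a
    run fails or exceeds the trial's incumbent objective by more than ``eps``;
    individual runs are capped at ``k_nr`` iterations.  Bounds are tracked per
    flux and per strategy as L grows; a bound is declared converged when its
    relative sliding-window spread δ (window ``window``) falls below
    ``rigorous_rel`` % (rigorous) or ``relaxed_rel`` % (relaxed), or — for
    near-zero bounds where δ is meaningless — when the absolute spread Δ is
    below ``absolute_tol``.
    """
    rng = np.random.default_rng(seed)
    part = model.partition
    n = part.n
    estimates = []
    n_failed = 0
    traces = {(g, s): [] for g in gammas for s in strategies}

    originals = [le.measurements for le in model.experiments]
    trial = 0
    while trial < L_max:
        trial += 1
        trial_seed = int(rng.integers(0, 2**31 - 1))
        for k, (le, orig) in enumerate(zip(model.experiments, originals)):
            le.measurements = corrupt(orig, (trial_seed, k))
        try:
            best = None
            start = np.asarray(theta_hat, float)
            for attempt in range(1 + n_as):
                rec = model.fit_single_trial(start, tt=tt, max_iter=k_nr)
                if rec.success and (best is None or rec.xi < best.xi):
                    best = rec
                if best is not None and rec.success and rec.xi - best.xi <= eps:
                    break
                start = part.sample_feasible_point(rng)
            if best is None:
                n_failed += 1
                continue
            estimates.append(part.Z @ best.theta)
        finally:
            for le, orig in zip(model.experiments, originals):
                le.measurements = orig
        if n_failed > max_failure_fraction * max(trial, 20):
            raise RuntimeError(
                f"{n_failed} of {trial} Monte Carlo trials failed "
                f"(> {max_failure_fraction:.0%}); aborting"
            )
        U = np.asarray(estimates)
        if U.shape[0] >= max(5, window // 4):
            for g in gammas:
                for s in strategies:
                    snap = np.empty((n, 2))
                    srt = np.sort(U, axis=0)
                    for i in range(n):
                        if s == "MC-1":
                            snap[i] = _mc1_bounds(srt[:, i], g)
                        else:
                            snap[i] = _mc2_bounds(U[:, i], g)
                    traces[(g, s)].append(snap)
        if online_stop and all(
            len(tr) >= window
            and _all_converged(tr, window, rigorous_rel, relaxed_rel, absolute_tol)
            for tr in traces.values()
        ):
            break

    U = np.asarray(estimates)
    if U.shape[0] < 3:
        raise RuntimeError("too few successful Monte Carlo trials")
    bounds = {}
    convergence = {}
    srt = np.sort(U, axis=0)
    for g in gammas:
        for s in strategies:
            B = np.empty((n, 2))
            verdicts = []
            for i in range(n):
                if s == "MC-1":
                    B[i] = _mc1_bounds(srt[:, i], g)
                else:
                    B[i] = _mc2_bounds(U[:, i], g)
                verdicts.append(_bound_verdicts(traces[(g, s)], i, window, rigorous_rel, relaxed_rel, absolute_tol))
            bounds[(g, s)] = B
            convergence[(g, s)] = verdicts
    return MonteCarloCIResult(
        U, list(part.flux_ids), tuple(gammas), bounds, traces, convergence,
        n_trials=U.shape[0], n_failed=n_failed, seeds={"master": seed},
    )


def _bound_verdicts(trace, i, M, rig, rel, abs_tol):
    out = {}
    if len(trace) < M:
        return {"LB": "insufficient", "UB": "insufficient"}
    for b, key in [(0, "LB"), (1, "UB")]:
        series = [snap[i, b] for snap in trace]
        d_abs, d_rel = _window_spreads(series, M)
        if d_rel <= rig:
            out[key] = "rigorous"
        elif d_rel <= rel:
            out[key] = "relaxed"
        elif d_abs <= abs_tol:
            out[key] = "absolute"
        else:
            out[key] = "not-converged"
    return out


def _all_converged(trace_list, M, rig, rel, abs_tol):
    if len(trace_list) < M:
        return False
    n = trace_list[0].shape[0]
    for i in range(n):
        v = _bound_verdicts(trace_list, i, M, rig, rel, abs_tol)
        if "not-converged" in v.values() or "insufficient" in v.values():
            return False
    return True


# ---------------------------------------------------------------------------
# profile-likelihood ("non-linear search") confidence intervals
# ---------------------------------------------------------------------------

def nonlinear_ci(model, theta_hat, flux_id, gamma: float = 0.95, max_steps: int = 40, step0: float = None):
    """EXPERIMENTAL profile-likelihood interval for one flux.

    Walks the flux up/down from its estimate, re-optimizing all other free
    fluxes under the equality constraint u_i(θ) = c, until Ξ exceeds
    Ξ_min + χ²_γ(1); bounds then refine by bisection.  Known failure mode of
    this family of searches: premature optimizer termination can produce a
    68% interval that is NOT inside the 95% interval — callers must check the
    nesting (``check_nesting``) and treat flagged intervals as unreliable.
    """
    from scipy.optimize import minimize

    part = model.partition
    i = part.flux_ids.index(flux_id)
    z = part.Z[i]
    u_hat = float(z @ theta_hat)
    xi_min = model.xi(theta_hat)
    threshold = xi_min + sps.chi2.ppf(gamma, 1)

    def profile(c):
        cons = [
            {"type": "ineq", "fun": lambda th: part.Z @ th, "jac": lambda th: part.Z},
            {"type": "eq", "fun": lambda th: z @ th - c, "jac": lambda th: z},
        ]
        bounds = list(zip(part.lower, np.where(np.isfinite(part.upper), part.upper, None)))
        res = minimize(model.xi, theta_hat, method="SLSQP", bounds=bounds,
                       constraints=cons, options={"ftol": 1e-8, "maxiter": 200})
        if not res.success:
            return None
        return float(res.fun)

    if step0 is None:
        step0 = max(0.05 * abs(u_hat), 0.5)

    out = {}
    for sign, key in [(+1, "UB"), (-1, "LB")]:
        c_in, c_out = u_hat, None
        c = u_hat
        reliable = True
        for _ in range(max_steps):
            c = c + sign * step0
            if c < 0 and sign < 0:
                c = 0.0
            val = profile(c)
            if val is None:
                reliable = False
                c_out = c
                break
            if val > threshold:
                c_out = c
                break
            c_in = c
            if c == 0.0:
                break
        if c_out is None:
            out[key] = (c_in, False)  # ran out of steps: bound unreliable
            continue
        lo, hi = sorted((c_in, c_out))
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            val = profile(mid)
            if val is None:
                reliable = False
                break
            inside = val <= threshold
            if (mid >= u_hat) == inside:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-4 * max(1.0, abs(u_hat)):
                break
        out[key] = (0.5 * (lo + hi), reliable)
    return {
        "flux": flux_id,
        "gamma": gamma,
        "LB": out["LB"][0],
        "UB": out["UB"][0],
        "reliable": out["LB"][1] and out["UB"][1],
    }


def check_nesting(ci68: dict, ci95: dict) -> bool:
    """True when the 68% interval nests inside the 95% interval (it must)."""
    return ci95["LB"] <= ci68["LB"] and ci68["UB"] <= ci95["UB"]


# ---------------------------------------------------------------------------
# normalized flux precision
# ---------------------------------------------------------------------------

def eta(u_i: float, ci_width: float, max_eff: float, beta: float = 0.1) -> float:
    """Normalized flux precision η ∈ [0, 1].

    η = 1 − width / (u_i + β·max_eff), clamped to 0 when the confidence
    interval is wider than the scaled denominator; η = 1 iff the width is 0.
    """
    if ci_width < 0:
        raise ValueError("CI width must be non-negative")
    denom = u_i + beta * max_eff
    if ci_width > denom:
        return 0.0
    return 1.0 - ci_width / denom


def sum_eta(u, widths, max_eff: float, beta: float = 0.1) -> float:
    """Σ_η: plain sum of η over all n fluxes."""
    return float(sum(eta(ui, wi, max_eff, beta) for ui, wi in zip(u, widths)))
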