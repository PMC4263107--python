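"""Constrained least-squares flux estimation from labeling experiments.

The estimation problem follows the classic steady-state 13C-MFA formulation:
free fluxes θ parameterize the flux space (u = Zθ, S·u = 0, u ≥ 0), simulated
fragment MIDs and effluxes are compared with their measurements through the
variance-weighted residual vector, and the objective

    Ξ(θ) = Σ_j r_j(θ)²,      r = (simulated − measured) / σ,

(twice the half-sum-of-squares SSR) is minimized by a gradient-based local
method (SLSQP) under the box and non-negativity constraints, restarted from
random feasible points to locate the global minimum.

``FluxModel`` holds the problem (network + partition + one or more labeling
experiments — a single experiment is an SLE, several form a PLE sharing θ);
``fit_multistart`` returns a ``FluxFitResults`` with the trial records, the
best estimate and the statistics entry points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .emu import EMU, decompose, simulate_mids
from .measurement import MeasurementSet, simulate_fragment

__all__ = ["LabelingExperiment", "TrialRecord", "FluxModel", "FluxFitResults"]

_BIG_RESIDUAL = 1e6


@dataclass
class LabelingExperiment:
    """One tracer feeding plus the measurements it produced."""

    tracer: "TracerSpec"
    measurements: MeasurementSet
    fragments: dict  # fragment name -> MeasuredFragment

    def __post_init__(self):
        for name in self.measurements.mids:
            if name not in self.fragments:
                raise ValueError(f"measured fragment {name!r} has no registry entry")
            if (self.measurements.mids[name][2] == 0).any():
                raise ValueError(f"{name}: zero sd cannot be a least-squares weight")
        for fid, (_, sd) in self.measurements.effluxes.items():
            if sd == 0:
                raise ValueError(f"{fid}: zero sd cannot be a least-squares weight")

    @property
    def w(self) -> int:
        return self.measurements.w


class FluxModel:
    """Flux-estimation problem over one or more labeling experiments.

    Parameters
    ----------
    network, partition:
        The metabolic model and its free-flux parameterization.
    experiments:
        One ``LabelingExperiment`` (SLE) or several (PLE).  All experiments
        share the flux parameters; their residual blocks concatenate.
    input_species:
        Tracer-fed (and otherwise label-exchanging) extracellular species.
    """

    def __init__(self, network, partition, experiments, input_species, c13_background=None):
        if not experiments:
            raise ValueError("need at least one labeling experiment")
        frag_emus = {}
        ref = experiments[0].fragments
        for le in experiments:
            for name, frag in le.fragments.items():
                if name in ref and (frag.species, frag.n_backbone) != (
                    ref[name].species,
                    ref[name].n_backbone,
                ):
                    raise ValueError(f"fragment registry mismatch across experiments: {name}")
                frag_emus[name] = EMU(frag.species, frag.emu_indices)
        self.network = network
        self.partition = partition
        self.experiments = list(experiments)
        self.input_species = set(input_species)
        self.c13_background = c13_background
        self.emu_network = decompose(network, sorted(set(frag_emus.values())), self.input_species)

    # -- problem dimensions ------------------------------------------------
    @property
    def p(self) -> int:
        return self.partition.p

    @property
    def W(self) -> int:
        return sum(le.w for le in self.experiments)

    @property
    def dof(self) -> int:
        return self.W - self.p

    # -- simulation and residuals -----------------------------------------
    def simulate_measurements(self, theta, experiment_index: int = 0) -> dict:
        """Fragment name → full simulated MID vector for one experiment."""
        le = self.experiments[experiment_index]
        u = self.partition.flux_dict(theta, check=False)
        mdvs = simulate_mids(self.emu_network, u, le.tracer)
        return {
            name: simulate_fragment(mdvs, frag, c13_background=self.c13_background)
            for name, frag in le.fragments.items()
        }

    def residuals(self, theta, by_experiment: bool = False):
        """Variance-weighted residual vector (MID blocks then efflux blocks).

        Residual ordering is canonical (sorted fragment names / flux ids per
        experiment), so Ξ is invariant to measurement and experiment input
        order.  Simulation failure at θ yields a large constant block, which
        steers the optimizer away instead of crashing a line search.
        """
        theta = np.asarray(theta, float)
        u_vec = self.partition.Z @ theta
        u = dict(zip(self.partition.flux_ids, np.maximum(u_vec, 0.0)))
        blocks = []
        for le in self.experiments:
            rows = []
            try:
                mdvs = simulate_mids(self.emu_network, u, le.tracer)
                sims = {
                    name: simulate_fragment(mdvs, frag, c13_background=self.c13_background)
                    for name, frag in le.fragments.items()
                }
                for name in sorted(le.measurements.mids):
                    idx, val, sd = le.measurements.mids[name]
                    rows.append((sims[name][idx] - val) / sd)
            except (ValueError, KeyError):
                n_mid = le.measurements.w_mid
                rows.append(np.full(n_mid, _BIG_RESIDUAL))
            for fid in sorted(le.measurements.effluxes):
                v, sd = le.measurements.effluxes[fid]
                i = self.partition.flux_ids.index(fid)
                rows.append(np.atleast_1d((u_vec[i] - v) / sd))
            blocks.append(np.concatenate(rows))
        if by_experiment:
            return blocks
        return np.concatenate(blocks)

    def xi(self, theta) -> float:
        """Ξ(θ) = Σ r² — the χ²-tested objective (Ξ = 2·SSR)."""
        r = self.residuals(theta)
        return float(r @ r)

    def ssr(self, theta) -> float:
        return 0.5 * self.xi(theta)

    # -- fitting -----------------------------------------------------------
    def fit_single_trial(self, theta0, tt: float = 1e-4, max_iter: int = 200) -> "TrialRecord":
        """One constrained local minimization from θ0 (records termination)."""
        theta0 = np.asarray(theta0, float)
        part = self.partition
        cons = [
            {
                "type": "ineq",
                "fun": lambda th: part.Z @ th,
                "jac": lambda th: part.Z,
            }
        ]
        bounds = list(zip(part.lower, np.where(np.isfinite(part.upper), part.upper, None)))
        res = minimize(
            self.xi,
            theta0,
            method="SLSQP",
            bounds=bounds,
            constraints=cons,
            options={"ftol": tt, "maxiter": max_iter},
        )
        viol = float(np.maximum(0.0, -(part.Z @ res.x)).max(initial=0.0))
        ok = bool(res.success) and viol < 1e-6 and res.fun < _BIG_RESIDUAL
        return TrialRecord(theta0, res.x, float(res.fun), ok, res.message, viol, int(res.nit))

    def fit(self, theta0=None, tt: float = 1e-4, seed=0, **kw) -> "FluxFitResults":
        """Single-trial convenience wrapper returning a results object."""
        if theta0 is None:
            theta0 = self.partition.sample_feasible_point(seed)
        rec = self.fit_single_trial(theta0, tt=tt, **kw)
        return FluxFitResults(self, [rec], tt)

    def fit_multistart(self, n_trials: int = 100, seed=0, tt: float = 1e-4, **kw) -> "FluxFitResults":
        """Multi-start local search from random feasible points."""
        if n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        rng = np.random.default_rng(seed)
        records = []
        for _ in range(n_trials):
            theta0 = self.partition.sample_feasible_point(rng)
            records.append(self.fit_single_trial(theta0, tt=tt, **kw))
        if not any(r.success for r in records):
            raise RuntimeError("no successfully terminated trials; estimation failed")
        return FluxFitResults(self, records, tt)


@dataclass
class TrialRecord:
    theta0: np.ndarray
    theta: np.ndarray
    xi: float
    success: bool
    message: str
    constraint_violation: float
    n_iter: int


class FluxFitResults:
    """Best estimate, per-trial records and statistics entry points."""

    def __init__(self, model: FluxModel, trials, tt: float):
        self.model = model
        self.trials = list(trials)
        self.tt = tt
        ok = [t for t in self.trials if t.success]
        if not ok:
            raise RuntimeError("no successful trials")
        best = min(ok, key=lambda t: t.xi)
        self.theta = best.theta
        self.xi_min = best.xi
        self.xi_max = max(t.xi for t in ok)
        # trials counted as reaching the minimum: Ξ_k − Ξ_min ≤ TT
        self.n_at_min = sum(1 for t in ok if t.xi - self.xi_min <= tt)
        self.n_success = len(ok)

    # -- basic accessors ----------------------------------------------------
    @property
    def fluxes(self) -> dict:
        return self.model.partition.flux_dict(self.theta, check=False)

    @property
    def u(self) -> np.ndarray:
        return self.model.partition.Z @ self.theta

    @property
    def free_fluxes(self) -> dict:
        return dict(zip(self.model.partition.free_ids, self.theta))

    def residuals(self, **kw):
        return self.model.residuals(self.theta, **kw)

    # -- statistics (delegated) ---------------------------------------------
    def gof(self, alpha: float = 0.05):
        from . import statistics as st

        return st.chi2_gof(self.xi_min, self.model.W, self.model.p, alpha)

    def residual_normality(self, alpha: float = 0.05):
        from . import statistics as st

        return st.residual_normality(self.residuals(), alpha=alpha)

    def linearized(self, **kw):
        from . import statistics as st

        return st.linearized_stats(self.model, self.theta, **kw)

    def identifiability(self, tol: float = 1e-8):
        from . import statistics as st

        J = st.residual_jacobian(self.model, self.theta)
        return st.identifiability(J, tol=tol)

    def monte_carlo_ci(self, **kw):
        from . import statistics as st

        return st.monte_carlo_ci(self.model, self.theta, **kw)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Flux estimation summary",
            "=======================",
            f"experiments: {len(m.experiments)} "
            f"({'SLE' if len(m.experiments) == 1 else 'PLE'})",
            f"measurements W = {m.W}  (MID {sum(le.measurements.w_mid for le in m.experiments)}"
            f" + efflux {sum(le.measurements.w_eff for le in m.experiments)})",
            f"free fluxes p = {m.p};  degrees of freedom W - p = {m.dof}",
            f"trials: {len(self.trials)} ({self.n_success} successful, "
            f"{self.n_at_min} at the minimum within TT={self.tt:g})",
            f"Xi_min = {self.xi_min:.6g}   Xi_max = {self.xi_max:.6g}",
            "",
            "free flux estimates:",
        ]
        for fid, val in self.free_fluxes.items():
            lines.append(f"  {fid:20s} {val:12.5g}")
        try:
            g = self.gof()
            lines += [
                "",
                f"chi2 band (alpha=0.05, dof={m.dof}): "
                f"[{g['lower']:.2f}, {g['upper']:.2f}]  -> "
                f"{'ACCEPT' if g['accept'] else 'REJECT'}",
            ]
        except ValueError:
            pass
        return "\n".join(lines)
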