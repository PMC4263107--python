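"""Reaction-table metabolic models, stoichiometry and free-flux partitions.

A model is a table of reactions, one row per non-negative flux.  Bi-directional
reactions appear as two rows (types ``FR`` forward and ``R`` reverse); purely
label-mapping reactions (type ``S``) carry atom transitions but no
stoichiometric column; type ``B`` rows (e.g. a lumped biomass equation) carry
stoichiometry but no atom transitions.

The table dialect is delimited text with columns::

    id    equation    atoms    type    basis

``equation`` uses ``>`` as the arrow, species separated by `` + ``; a numeric
prefix is a stoichiometric coefficient (allowed on atom-free species only —
atom-mapped species must be written once per molecule instance so the atom
strings line up).  ``atoms`` mirrors the equation with one lower-case letter
per carbon; alternative transitions of a scrambling (symmetric-molecule)
reaction are separated by ``;`` and share the flux with equal weights.
Species whose name ends in ``_EX``, plus ``BIOMASS``, are extracellular and
excluded from the balanced set.  ``basis`` is ``free`` to request the flux as
a free parameter, empty otherwise.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Reaction",
    "MetabolicNetwork",
    "FreeFluxPartition",
    "ModelValidationError",
    "parse_model",
    "parse_model_text",
    "assign_free_fluxes",
]

REACTION_KINDS = {"F", "FR", "R", "S", "B"}


class ModelValidationError(ValueError):
    """Structured validation failure; ``problems`` lists every offence found."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("model validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems))


def _is_external(name: str) -> bool:
    return name.endswith("_EX") or name == "BIOMASS"


@dataclass(frozen=True)
class Reaction:
    """One row of the model table: a single non-negative flux."""

    id: str
    substrates: tuple  # ((species, coeff), ...) one entry per molecule instance
    products: tuple
    # atom_maps: tuple of (weight, substrate_strings, product_strings); strings
    # align with the substrates/products tuples, None for unmapped species.
    atom_maps: tuple
    kind: str
    basis: str = ""

    @property
    def in_balance(self) -> bool:
        return self.kind != "S"

    @property
    def mapped(self) -> bool:
        return bool(self.atom_maps)

    def carbon_count(self, species_index: int, side: str) -> int:
        strings = self.atom_maps[0][1 if side == "sub" else 2]
        s = strings[species_index]
        return len(s) if s else 0


@dataclass
class MetabolicNetwork:
    """Parsed reaction network with stoichiometry over balanced metabolites."""

    reactions: list
    balanced_metabolites: list  # sorted, stable
    externals: set
    carbons: dict  # species -> carbon count (mapped species only)

    def __post_init__(self):
        self._by_id = {r.id: r for r in self.reactions}
        self._S = None

    def reaction(self, rid: str) -> Reaction:
        return self._by_id[rid]

    @property
    def flux_ids(self):
        """Column order of S: balance-participating reactions, input order."""
        return [r.id for r in self.reactions if r.in_balance]

    @property
    def stoichiometry(self) -> pd.DataFrame:
        """Stoichiometric matrix S: rows balanced metabolites, columns fluxes."""
        if self._S is None:
            cols = self.flux_ids
            S = pd.DataFrame(0.0, index=self.balanced_metabolites, columns=cols)
            for r in self.reactions:
                if not r.in_balance:
                    continue
                for sp, c in r.substrates:
                    if sp in S.index:
                        S.loc[sp, r.id] -= c
                for sp, c in r.products:
                    if sp in S.index:
                        S.loc[sp, r.id] += c
            self._S = S
        return self._S

    @property
    def S(self) -> np.ndarray:
        return self.stoichiometry.to_numpy()

    def rank(self, tol: float = 1e-9) -> int:
        return int(np.linalg.matrix_rank(self.S, tol=tol))

    def dead_end_metabolites(self):
        """Balanced metabolites never produced or never consumed."""
        S = self.stoichiometry
        out = []
        for m in S.index:
            row = S.loc[m].to_numpy()
            if not (row > 0).any() or not (row < 0).any():
                out.append(m)
        return out

    def producers(self, species: str):
        """Reactions (mapped) with ``species`` on the product side."""
        out = []
        for r in self.reactions:
            if r.mapped and any(sp == species for sp, _ in r.products):
                out.append(r)
        return out

    def to_json(self) -> str:
        payload = {
            "reactions": [
                {
                    "id": r.id,
                    "substrates": list(map(list, r.substrates)),
                    "products": list(map(list, r.products)),
                    "atom_maps": [
                        [w, list(subs), list(prods)] for (w, subs, prods) in r.atom_maps
                    ],
                    "kind": r.kind,
                    "basis": r.basis,
                }
                for r in self.reactions
            ],
            "balanced_metabolites": self.balanced_metabolites,
            "externals": sorted(self.externals),
            "carbons": self.carbons,
        }
        return json.dumps(payload, indent=1)


def _parse_side(side: str):
    """Parse ``2 A + B`` into ((A, 2.0), (B, 1.0)) keeping instance order."""
    entries = []
    for token in side.split("+"):
        token = token.strip()
        if not token:
            continue
        parts = token.split()
        if len(parts) == 2:
            coeff, name = float(parts[0]), parts[1]
        elif len(parts) == 1:
            coeff, name = 1.0, parts[0]
        else:
            raise ValueError(f"cannot parse species token {token!r}")
        entries.append((name, coeff))
    return tuple(entries)


def _parse_atoms(atoms: str, n_sub: int, n_prod: int):
    """Parse the atom-transition cell into weighted alternative maps."""
    atoms = atoms.strip()
    if not atoms:
        return ()
    alts = [a.strip() for a in atoms.split(";") if a.strip()]
    maps = []
    for alt in alts:
        lhs, rhs = alt.split(">")
        subs = tuple(s.strip() or None for s in lhs.split("+"))
        prods = tuple(s.strip() or None for s in rhs.split("+"))
        if len(subs) != n_sub or len(prods) != n_prod:
            raise ValueError(
                f"atom map {alt!r} has {len(subs)}/{len(prods)} species, "
                f"equation has {n_sub}/{n_prod}"
            )
        maps.append((1.0 / len(alts), subs, prods))
    return tuple(maps)


def parse_model(table, externals=None) -> MetabolicNetwork:
    """Parse a reaction table (DataFrame or path to delimited text).

    Raises :class:`ModelValidationError` collecting every problem found
    (duplicate ids, unknown type flags, unbalanced carbon letters, carbon-count
    mismatches between equation coefficients and atom strings).
    """
    import os

    if isinstance(table, (str, bytes, os.PathLike)) or hasattr(table, "read"):
        df = pd.read_csv(table, sep=None, engine="python", comment="#")
    else:
        df = table.copy()
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"id", "equation", "atoms", "type"}
    missing = required - set(df.columns)
    if missing:
        raise ModelValidationError([f"missing columns: {sorted(missing)}"])
    if "basis" not in df.columns:
        df["basis"] = ""

    problems = []
    reactions = []
    seen = set()
    carbons = {}
    for _, row in df.iterrows():
        rid = str(row["id"]).strip()
        if rid in seen:
            problems.append(f"duplicate reaction id {rid!r}")
            continue
        seen.add(rid)
        kind = str(row["type"]).strip().upper()
        if kind not in REACTION_KINDS:
            problems.append(f"{rid}: unknown type flag {row['type']!r}")
            continue
        try:
            lhs, rhs = str(row["equation"]).split(">")
            subs, prods = _parse_side(lhs), _parse_side(rhs)
        except Exception as exc:  # noqa: BLE001 - collected into the report
            problems.append(f"{rid}: cannot parse equation ({exc})")
            continue
        raw_atoms = row["atoms"]
        raw_atoms = "" if pd.isna(raw_atoms) else str(raw_atoms)
        try:
            amaps = _parse_atoms(raw_atoms, len(subs), len(prods))
        except Exception as exc:  # noqa: BLE001
            problems.append(f"{rid}: bad atom map ({exc})")
            continue
        if kind != "B" and not amaps:
            problems.append(f"{rid}: type {kind} requires an atom transition")
            continue
        for w, smaps, pmaps in amaps:
            sub_letters = "".join(s for s in smaps if s)
            prod_letters = "".join(p for p in pmaps if p)
            if sorted(sub_letters) != sorted(prod_letters):
                problems.append(
                    f"{rid}: carbon letters unbalanced "
                    f"({sub_letters!r} vs {prod_letters!r})"
                )
            for (sp, coeff), letters in zip(list(subs) + list(prods), list(smaps) + list(pmaps)):
                if letters is None:
                    continue
                if coeff != 1.0:
                    problems.append(
                        f"{rid}: atom-mapped species {sp} must be written per "
                        f"instance, found coefficient {coeff}"
                    )
                n = len(letters)
                if sp in carbons and carbons[sp] != n:
                    problems.append(
                        f"{rid}: {sp} has {n} carbons here, {carbons[sp]} elsewhere"
                    )
                carbons.setdefault(sp, n)
        basis = row["basis"]
        basis = "" if pd.isna(basis) else str(basis).strip()
        reactions.append(Reaction(rid, subs, prods, amaps, kind, basis))

    if problems:
        raise ModelValidationError(problems)

    ext = {s for r in reactions for s, _ in list(r.substrates) + list(r.products) if _is_external(s)}
    if externals:
        ext |= set(externals)
    balanced = sorted(
        {
            sp
            for r in reactions
            if r.in_balance
            for sp, _ in list(r.substrates) + list(r.products)
            if sp not in ext
        }
    )
    return MetabolicNetwork(reactions, balanced, ext, carbons)


def parse_model_text(text: str, **kw) -> MetabolicNetwork:
    return parse_model(io.StringIO(text), **kw)


@dataclass
class FreeFluxPartition:
    """Partition of the flux vector into free parameters θ and dependents.

    The full flux vector is linear in θ: ``u(θ) = Z @ θ`` with ``S @ Z = 0``,
    which keeps every stoichiometric balance satisfied for any θ.
    """

    network: MetabolicNetwork
    free_ids: list
    dependent_ids: list
    Z: np.ndarray  # (n, p) map θ -> u in S-column order
    lower: np.ndarray = None  # per-θ bounds
    upper: np.ndarray = None

    def __post_init__(self):
        n, p = self.Z.shape
        if self.lower is None:
            self.lower = np.zeros(p)
        if self.upper is None:
            self.upper = np.full(p, np.inf)
        self.flux_ids = self.network.flux_ids
        self._free_idx = [self.flux_ids.index(f) for f in self.free_ids]

    @property
    def p(self) -> int:
        return len(self.free_ids)

    @property
    def n(self) -> int:
        return len(self.flux_ids)

    def set_bounds(self, flux_id: str, lo: float, hi: float):
        if lo > hi:
            raise ValueError(f"{flux_id}: lower bound {lo} exceeds upper {hi}")
        i = self.free_ids.index(flux_id)
        self.lower[i], self.upper[i] = lo, hi

    def compute_fluxes(self, theta, check: bool = True, tol: float = 1e-9) -> np.ndarray:
        """Full flux vector u(θ); flags (not clips) infeasible θ if ``check``."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.p,):
            raise ValueError(f"theta must have shape ({self.p},)")
        u = self.Z @ theta
        if check:
            if (theta < self.lower - tol).any() or (theta > self.upper + tol).any():
                raise ValueError("theta outside free-flux bounds")
            if (u < -tol).any():
                bad = [self.flux_ids[i] for i in np.where(u < -tol)[0]]
                raise ValueError(f"negative dependent fluxes at this theta: {bad}")
        return u

    def flux_dict(self, theta, **kw) -> dict:
        return dict(zip(self.flux_ids, self.compute_fluxes(theta, **kw)))

    def theta_of(self, u) -> np.ndarray:
        """Extract θ from a full flux vector."""
        u = np.asarray(u, dtype=float)
        return u[self._free_idx]

    def is_feasible(self, theta, tol: float = 1e-9) -> bool:
        try:
            self.compute_fluxes(theta, check=True, tol=tol)
            return True
        except ValueError:
            return False

    def sample_feasible_point(self, rng, max_attempts: int = 10_000) -> np.ndarray:
        """Rejection-sample θ uniform on the bound box with u(θ) ≥ 0."""
        rng = np.random.default_rng(rng)
        lo = self.lower
        hi = np.where(np.isfinite(self.upper), self.upper, np.maximum(1.0, 10 * np.abs(lo) + 10))
        for _ in range(max_attempts):
            theta = rng.uniform(lo, hi)
            if self.is_feasible(theta):
                return theta
        raise RuntimeError(
            f"no feasible point found in {max_attempts} attempts; "
            "check bounds and network consistency"
        )


def assign_free_fluxes(net: MetabolicNetwork, preferred_free=(), tol: float = 1e-9) -> FreeFluxPartition:
    """Choose p = n − rank(S) free fluxes and build the linear map u(θ).

    ``preferred_free`` fluxes are honoured first (an error names conflicting
    choices if they cannot be completed to a valid basis); remaining free
    columns are chosen by QR column pivoting so the dependent block stays
    well-conditioned.
    """
    S = net.S
    flux_ids = net.flux_ids
    n = S.shape[1]
    r = np.linalg.matrix_rank(S, tol=tol)
    p = n - r

    preferred = list(preferred_free)
    unknown = [f for f in preferred if f not in flux_ids]
    if unknown:
        raise ValueError(f"preferred free fluxes not in model: {unknown}")
    if len(preferred) > p:
        raise ValueError(f"{len(preferred)} preferred free fluxes but only p={p} degrees of freedom")

    pref_idx = [flux_ids.index(f) for f in preferred]
    # The dependent block must have full rank r.  Verify the preferred set is
    # admissible, then greedily grow it using the least pivotal columns.
    candidates = [i for i in range(n) if i not in pref_idx]
    S_dep = S[:, candidates]
    if np.linalg.matrix_rank(S_dep, tol=tol) < r:
        # find which preferred choices break the basis
        bad = []
        for i in pref_idx:
            rest = [j for j in range(n) if j != i]
            if np.linalg.matrix_rank(S[:, rest], tol=tol) < r:
                bad.append(flux_ids[i])
        raise ValueError(
            "preferred free set cannot be completed to a valid basis; "
            f"conflicting choices: {bad or preferred}"
        )

    free_idx = list(pref_idx)
    if len(free_idx) < p:
        # QR with column pivoting ranks columns by importance for spanning the
        # column space; the tail of the permutation is safest to free up.
        from scipy.linalg import qr

        _, _, perm = qr(S_dep, pivoting=True)
        order = [candidates[j] for j in perm[::-1]]  # least pivotal first
        for j in order:
            if len(free_idx) == p:
                break
            trial_dep = [i for i in range(n) if i not in free_idx + [j]]
            if np.linalg.matrix_rank(S[:, trial_dep], tol=tol) == r:
                free_idx.append(j)
    if len(free_idx) != p:
        raise RuntimeError("failed to complete the free-flux basis")

    dep_idx = [i for i in range(n) if i not in free_idx]
    # u_dep = -S_dep^+ S_free θ  (S_dep has full column rank r over dep_idx)
    S_dep = S[:, dep_idx]
    S_free = S[:, free_idx]
    sol, *_ = np.linalg.lstsq(S_dep, -S_free, rcond=None)
    Z = np.zeros((n, p))
    for k, i in enumerate(free_idx):
        Z[i, k] = 1.0
    Z[dep_idx, :] = sol
    # verify exactness (the lstsq solution must be an exact null-space map)
    resid = np.abs(S @ Z).max()
    if resid > 1e-8:
        raise RuntimeError(f"free-flux assignment inconsistent: |S Z| = {resid:.2e}")

    free_ids = [flux_ids[i] for i in free_idx]
    dep_ids = [flux_ids[i] for i in dep_idx]
    return FreeFluxPartition(net, free_ids, dep_ids, Z)
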