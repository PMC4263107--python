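"""EMU decomposition and mass-isotopomer simulation.

An EMU (elementary metabolite unit) is a subset of a metabolite's carbon
atoms.  Tracing the measured fragments backwards through the atom transitions
yields a cascade of linear systems — one per connected block of same-size
EMUs — whose unknowns are the EMUs' mass distribution vectors (MDVs).  Sizes
only ever decrease backwards (a condensation splits an EMU into smaller ones
whose MDVs convolve), so the cascade is solved smallest-size first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EMU",
    "TracerSpec",
    "EMUNetwork",
    "decompose",
    "tracer_mdv",
    "convolve",
    "simulate_mids",
]


@dataclass(frozen=True, order=True)
class EMU:
    """Carbon subset of one metabolite; indices are 1-based and sorted."""

    species: str
    indices: tuple

    def __post_init__(self):
        idx = tuple(sorted(set(self.indices)))
        if idx != tuple(self.indices):
            object.__setattr__(self, "indices", idx)
        if not idx or idx[0] < 1:
            raise ValueError(f"bad EMU indices {self.indices}")

    @property
    def size(self) -> int:
        return len(self.indices)

    def __repr__(self):
        return f"{self.species}{{{','.join(map(str, self.indices))}}}"


@dataclass
class TracerSpec:
    """Positional-isotopomer mixture feeding the input substrates.

    ``mixtures`` maps an input species to a list of ``(molar_fraction,
    labeled_positions)`` components.  Labeled positions carry ``purity`` 13C;
    every other carbon (and every unspecified input species) carries the
    natural ``background`` abundance, independently across positions.
    """

    mixtures: dict
    purity: float = 0.99
    background: float = 0.0107

    def __post_init__(self):
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        for sp, comps in self.mixtures.items():
            total = sum(f for f, _ in comps)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{sp}: mixture fractions sum to {total}, not 1")

    def position_p13(self, species: str, position: int):
        """Per-component (fraction, p13) for one carbon position."""
        comps = self.mixtures.get(species, [(1.0, frozenset())])
        return [
            (f, self.purity if position in set(labeled) else self.background)
            for f, labeled in comps
        ]


def convolve(a, b) -> np.ndarray:
    """Discrete convolution of two MDVs (the MDV of a condensation product)."""
    return np.convolve(np.asarray(a, float), np.asarray(b, float))


def tracer_mdv(spec: TracerSpec, emu: EMU) -> np.ndarray:
    """MDV of an input-substrate EMU under the tracer specification."""
    comps = spec.mixtures.get(emu.species, [(1.0, frozenset())])
    out = np.zeros(emu.size + 1)
    for frac, labeled in comps:
        labeled = set(labeled)
        mdv = np.array([1.0])
        for pos in emu.indices:
            p = spec.purity if pos in labeled else spec.background
            mdv = np.convolve(mdv, [1.0 - p, p])
        out += frac * mdv
    return out


@dataclass(frozen=True)
class _Term:
    """One production term of an EMU balance: weight·flux × ⊛(sources)."""

    flux_id: str  # None for mapping-only (S-type) reactions, flux ≡ 1
    weight: float
    sources: tuple  # EMUs; len > 1 means convolution


@dataclass
class EMUNetwork:
    """Size-ordered cascade of EMU balance blocks."""

    input_species: set
    targets: list
    balances: dict  # unknown EMU -> list[_Term]
    blocks: list  # list[(size, [EMU, ...], coupled)] in cascade solve order

    @property
    def unknown_emus(self):
        return [e for _, emus, _ in self.blocks for e in emus]

    @property
    def input_emus(self):
        seen = {}
        for terms in self.balances.values():
            for t in terms:
                for s in t.sources:
                    if s.species in self.input_species and s not in seen:
                        seen[s] = None
        return list(seen)

    @property
    def n_unknown(self) -> int:
        return len(self.balances)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_matrix_systems(self) -> int:
        """Coupled (simultaneous) linear systems in the cascade."""
        return sum(1 for _, _, coupled in self.blocks if coupled)

    @property
    def n_scalar_unknowns(self) -> int:
        """Total scalar MID variables: Σ (size + 1) over unknown EMUs."""
        return sum(e.size + 1 for e in self.balances)

    def summary(self) -> str:
        sizes = {}
        for size, emus, coupled in self.blocks:
            if coupled:
                sizes.setdefault(size, []).append(len(emus))
        lines = [
            f"EMU network: {self.n_unknown} unknown EMUs, "
            f"{self.n_matrix_systems} coupled matrix systems, "
            f"{len(self.input_emus)} input EMUs, {self.n_scalar_unknowns} scalar MID unknowns"
        ]
        for size in sorted(sizes):
            lines.append(f"  size {size}: coupled systems of {sizes[size]} EMUs")
        return "\n".join(lines)


def _production_terms(net, emu: EMU):
    """All balance terms producing ``emu`` via mapped reactions."""
    terms = []
    for r in net.producers(emu.species):
        for w, smaps, pmaps in r.atom_maps:
            for j, (sp, _) in enumerate(r.products):
                if sp != emu.species or pmaps[j] is None:
                    continue
                letters = [pmaps[j][i - 1] for i in emu.indices]
                by_sub = {}
                for letter in letters:
                    found = False
                    for k, smap in enumerate(smaps):
                        if smap and letter in smap:
                            by_sub.setdefault(k, []).append(smap.index(letter) + 1)
                            found = True
                            break
                    if not found:
                        raise ValueError(
                            f"{r.id}: carbon {letter!r} of {emu} has no substrate source"
                        )
                sources = tuple(
                    sorted(
                        EMU(r.substrates[k][0], tuple(pos)) for k, pos in by_sub.items()
                    )
                )
                flux_id = None if r.kind == "S" else r.id
                terms.append(_Term(flux_id, w, sources))
    return terms


def decompose(net, targets, input_species) -> EMUNetwork:
    """Backward EMU decomposition from target EMUs to the input substrates.

    Returns the minimal EMU set reachable backwards from ``targets``, grouped
    into same-size connected blocks ordered smallest size first (deterministic
    and independent of reaction order).
    """
    input_species = set(input_species)
    targets = sorted(targets)
    for t in targets:
        if t.species in input_species:
            continue
        if not net.producers(t.species):
            raise ValueError(f"target EMU {t} is on an unreachable metabolite ({t.species})")

    balances = {}
    queue = [t for t in targets if t.species not in input_species]
    while queue:
        emu = queue.pop(0)
        if emu in balances:
            continue
        terms = _production_terms(net, emu)
        if not terms:
            raise ValueError(f"EMU {emu} on {emu.species} has no producing reaction")
        s_terms = [t for t in terms if t.flux_id is None]
        if s_terms and len(terms) != 1:
            raise ValueError(
                f"{emu.species} is produced by a mapping-only reaction and by "
                "balance reactions; its labeling state would be ill-defined"
            )
        balances[emu] = terms
        for t in terms:
            for s in t.sources:
                if s.species not in input_species and s not in balances:
                    queue.append(s)

    # blocks: strongly-connected components of the same-size dependency
    # graph, in topological (cascade) order; a block with several EMUs (or a
    # self-dependency) is a genuine simultaneous linear system, a singleton
    # without self-dependency is a direct evaluation
    import networkx as nx

    order = sorted(balances)  # canonical
    blocks = []
    for size in sorted({e.size for e in order}):
        members = [e for e in order if e.size == size]
        G = nx.DiGraph()
        G.add_nodes_from(members)
        for e in members:
            for t in balances[e]:
                if len(t.sources) == 1:
                    s = t.sources[0]
                    if s in G and s.size == size:
                        G.add_edge(s, e)  # e depends on s
        cond = nx.condensation(G)
        for node in nx.topological_sort(cond):
            comp = sorted(cond.nodes[node]["members"])
            coupled = len(comp) > 1 or G.has_edge(comp[0], comp[0])
            blocks.append((size, comp, coupled))

    return EMUNetwork(input_species, targets, balances, blocks)


def simulate_mids(emunet: EMUNetwork, fluxes, spec: TracerSpec, atol: float = 1e-9) -> dict:
    """Solve the EMU cascade for the given flux map; returns EMU → MDV.

    ``fluxes`` maps flux id → value.  Raises on singular blocks (zero
    throughput), naming the affected EMUs.
    """

    def fval(term):
        return term.weight * (1.0 if term.flux_id is None else fluxes[term.flux_id])

    mdvs = {}

    def source_mdv(emu):
        if emu.species in emunet.input_species:
            return tracer_mdv(spec, emu)
        return mdvs[emu]

    for size, emus, _coupled in emunet.blocks:
        idx = {e: i for i, e in enumerate(emus)}
        m = len(emus)
        A = np.zeros((m, m))
        B = np.zeros((m, size + 1))
        for e in emus:
            i = idx[e]
            for t in emunet.balances[e]:
                f = fval(t)
                A[i, i] += f
                if len(t.sources) == 1 and t.sources[0] in idx:
                    A[i, idx[t.sources[0]]] -= f
                else:
                    term_mdv = source_mdv(t.sources[0])
                    for s in t.sources[1:]:
                        term_mdv = np.convolve(term_mdv, source_mdv(s))
                    B[i] += f * term_mdv
        dead = [e for e in emus if A[idx[e], idx[e]] <= 0.0]
        if dead:
            raise ValueError(f"zero throughput to EMUs {dead}; block of size {size} is singular")
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular EMU block (size {size}): {emus}") from exc
        for e in emus:
            x = X[idx[e]]
            s = x.sum()
            if not np.isfinite(s) or abs(s - 1.0) > max(atol, 1e-6):
                raise ValueError(f"MDV of {e} sums to {s}; flux map inconsistent")
            mdvs[e] = x
    return mdvs
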