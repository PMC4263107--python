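"""Full positional-isotopomer balance: a brute-force oracle for the EMU path.

Every mapped, non-input species with c carbons carries 2^c isotopomer
fractions (bit i−1 of the index is carbon i).  The steady-state labeling
state is the fixed point of the production-normalized balance map; pools are
assumed well mixed, so joint substrate states factorize into products of
marginals.  Intended for small test networks — the full C. glutamicum-scale
model is only ever *counted* here, never solved.
"""

from __future__ import annotations

import numpy as np

__all__ = ["count_isotopomer_unknowns", "simulate_isotopomers_bruteforce", "isotopomers_to_mass"]


def _mapped_species(net, input_species):
    """Mapped species carrying isotopomer unknowns (inputs excluded)."""
    out = {}
    for r in net.reactions:
        if not r.mapped:
            continue
        for (sp, _), side in [
            *[(e, "sub") for e in r.substrates],
            *[(e, "prod") for e in r.products],
        ]:
            if sp in input_species or sp in out or sp in net.externals:
                continue
            if sp in net.carbons:
                out[sp] = net.carbons[sp]
    return out


def count_isotopomer_unknowns(net, input_species) -> int:
    """Scalar unknowns of the full isotopomer model: Σ 2^carbons."""
    species = _mapped_species(net, set(input_species))
    return int(sum(2**c for c in species.values()))


def _marginal(x, positions, c):
    """P(selected positions have a given label pattern), marginalizing the rest.

    Returns an array of length 2^len(positions), index bit j = positions[j].
    """
    k = len(positions)
    out = np.zeros(2**k)
    for mask in range(2**c):
        key = 0
        for j, pos in enumerate(positions):
            if mask >> (pos - 1) & 1:
                key |= 1 << j
        out[key] += x[mask]
    return out


def _input_isotopomers(spec, species, c):
    x = np.zeros(2**c)
    comps = spec.mixtures.get(species, [(1.0, frozenset())])
    for frac, labeled in comps:
        labeled = set(labeled)
        p = np.array([spec.purity if i + 1 in labeled else spec.background for i in range(c)])
        for mask in range(2**c):
            prob = 1.0
            for i in range(c):
                prob *= p[i] if mask >> i & 1 else 1.0 - p[i]
            x[mask] += frac * prob
    return x


def simulate_isotopomers_bruteforce(
    net,
    fluxes,
    spec,
    input_species,
    max_carbons: int = 20,
    tol: float = 1e-13,
    max_iter: int = 10_000,
):
    """Fixed-point solve of the full isotopomer balance.

    Refuses (with the unknown count) when the network carries more than
    ``max_carbons`` total carbons across unknown species — the combinatorial
    model exists to verify the EMU cascade on small fixtures, not to scale.
    Returns ``(isotopomers, n_unknowns)`` where ``isotopomers`` maps species →
    2^c vector.
    """
    input_species = set(input_species)
    species = _mapped_species(net, input_species)
    total_carbons = sum(species.values())
    n_unknowns = count_isotopomer_unknowns(net, input_species)
    if total_carbons > max_carbons:
        raise ValueError(
            f"network has {total_carbons} unknown-species carbons (> {max_carbons}); "
            f"full isotopomer model would hold {n_unknowns} scalar unknowns"
        )

    inputs = {
        sp: _input_isotopomers(spec, sp, c)
        for sp, c in {s: net.carbons[s] for s in input_species if s in net.carbons}.items()
    }

    # production terms per species: (flux_id or None, weight, [(src, positions)])
    prod = {sp: [] for sp in species}
    for r in net.reactions:
        if not r.mapped:
            continue
        for w, smaps, pmaps in r.atom_maps:
            for j, (sp, _) in enumerate(r.products):
                if sp not in prod or pmaps[j] is None:
                    continue
                c = len(pmaps[j])
                by_sub = {}
                for pos_out, letter in enumerate(pmaps[j], start=1):
                    for k, smap in enumerate(smaps):
                        if smap and letter in smap:
                            by_sub.setdefault(k, []).append((pos_out, smap.index(letter) + 1))
                            break
                srcs = [
                    (r.substrates[k][0], pairs) for k, pairs in sorted(by_sub.items())
                ]
                fid = None if r.kind == "S" else r.id
                prod[sp].append((fid, w, c, srcs))

    def fval(fid):
        return 1.0 if fid is None else fluxes[fid]

    x = {sp: _input_isotopomers(TracerAllNatural(spec), sp, c) for sp, c in species.items()}

    for _ in range(max_iter):
        delta = 0.0
        new = {}
        for sp, c in species.items():
            total = 0.0
            acc = np.zeros(2**c)
            for fid, w, _, srcs in prod[sp]:
                f = w * fval(fid)
                if f == 0.0:
                    continue
                total += f
                # joint probability factorizes over independent substrate pools;
                # every product bit is owned by exactly one substrate instance
                term = np.ones(2**c)
                for src, pairs in srcs:
                    src_x = inputs[src] if src in inputs else x[src]
                    src_c = net.carbons[src]
                    marg = _marginal(src_x, [p_in for _, p_in in pairs], src_c)
                    factor = np.empty(2**c)
                    for mask in range(2**c):
                        key = 0
                        for j, (p_out, _) in enumerate(pairs):
                            if mask >> (p_out - 1) & 1:
                                key |= 1 << j
                        factor[mask] = marg[key]
                    term *= factor
                acc += f * term
            if total <= 0:
                raise ValueError(f"{sp} has zero production; isotopomer balance singular")
            new_x = acc / total
            delta = max(delta, np.abs(new_x - x[sp]).max())
            new[sp] = new_x
        x = new
        if delta < tol:
            break
    else:
        raise RuntimeError("isotopomer fixed point did not converge")
    return x, n_unknowns


class TracerAllNatural:
    """Natural-abundance start state for the fixed-point iteration."""

    def __init__(self, spec):
        self.purity = spec.purity
        self.background = spec.background
        self.mixtures = {}


def isotopomers_to_mass(x, positions) -> np.ndarray:
    """Marginalize a 2^c isotopomer vector to the MDV of an atom subset."""
    k = len(positions)
    out = np.zeros(k + 1)
    c = int(np.log2(len(x)) + 0.5)
    for mask in range(2**c):
        m = sum(mask >> (p - 1) & 1 for p in positions)
        out[m] += x[mask]
    return out
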