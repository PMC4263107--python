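"""GC-MS measurement model: natural-isotope interference, truncation,
detection filtering, noise corruption and replicate statistics.

Simulated carbon-backbone MDVs are not directly comparable with raw GC-MS
mass isotopomer abundances of derivatized fragments: the non-backbone atoms
(H, N, O, Si, S and derivatization carbons) contribute their own natural
isotope mass shifts.  Following the usual correction-matrix approach, the
backbone MDV is convolved with the natural mass-shift distribution of the
remaining atoms of the fragment's elemental formula, truncated back to the
first n+1 masses and (optionally) renormalized.  MIDs are fractions
internally; mol% only appears at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ISOTOPE_SHIFTS",
    "MeasuredFragment",
    "MeasurementSet",
    "natural_abundance_expand",
    "truncate_normalize",
    "detection_filter",
    "corrupt",
    "replicate_stats",
    "parse_formula",
]

# natural terrestrial isotope abundances as mass-shift distributions
# (index = nominal mass shift from the lightest isotope)
ISOTOPE_SHIFTS = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99632, 0.00368),
    "O": (0.99757, 0.00038, 0.00205),
    "Si": (0.92223, 0.04685, 0.03092),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}


def parse_formula(formula: str) -> dict:
    """Parse ``C11H26NO2Si2`` into {'C': 11, 'H': 26, 'N': 1, 'O': 2, 'Si': 2}."""
    import re

    out = {}
    for sym, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if not sym:
            continue
        if sym not in ISOTOPE_SHIFTS:
            raise ValueError(f"unknown element symbol {sym!r} in {formula!r}")
        out[sym] = out.get(sym, 0) + (int(num) if num else 1)
    return out


@dataclass(frozen=True)
class MeasuredFragment:
    """A derivatized GC-MS fragment carrying a metabolite's carbon backbone."""

    name: str
    species: str
    formula: str  # elemental formula of the whole fragment, backbone included
    n_backbone: int
    truncate_to: int = None  # retained masses; default n_backbone + 1
    normalize: bool = True

    def __post_init__(self):
        counts = parse_formula(self.formula)
        if counts.get("C", 0) < self.n_backbone:
            raise ValueError(
                f"{self.name}: formula {self.formula} has fewer C than the "
                f"{self.n_backbone}-carbon backbone"
            )
        if self.retained > self.n_backbone + 1:
            raise ValueError(f"{self.name}: cannot retain more than n+1 masses")

    @property
    def retained(self) -> int:
        return self.truncate_to if self.truncate_to is not None else self.n_backbone + 1

    @property
    def emu_indices(self):
        return tuple(range(1, self.n_backbone + 1))


def _element_kernel(counts: dict, c13: float = None) -> np.ndarray:
    """Mass-shift distribution of a set of atoms, convolved across elements."""
    kernel = np.array([1.0])
    for sym, n in counts.items():
        dist = np.asarray(ISOTOPE_SHIFTS[sym], float)
        if sym == "C" and c13 is not None:
            dist = np.array([1.0 - c13, c13])
        for _ in range(n):
            kernel = np.convolve(kernel, dist)
    return kernel


def natural_abundance_expand(mdv, frag: MeasuredFragment, c13_background: float = None) -> np.ndarray:
    """Convolve a backbone MDV with the fragment's non-backbone isotope kernel.

    The kernel covers every atom of the elemental formula except the backbone
    carbons themselves; output sums to the input sum (mass balance).
    """
    counts = dict(parse_formula(frag.formula))
    counts["C"] = counts.get("C", 0) - frag.n_backbone
    if counts["C"] == 0:
        del counts["C"]
    kernel = _element_kernel(counts, c13=c13_background)
    return np.convolve(np.asarray(mdv, float), kernel)


def truncate_normalize(raw, n: int, normalize: bool = True) -> np.ndarray:
    """Keep the first n+1 masses; optionally rescale them to sum to 1."""
    raw = np.asarray(raw, float)
    if raw.size < n + 1:
        raise ValueError(f"raw distribution has {raw.size} masses, need {n + 1}")
    out = raw[: n + 1].copy()
    if normalize:
        out /= out.sum()
    return out


def simulate_fragment(mdvs, frag: MeasuredFragment, c13_background: float = None) -> np.ndarray:
    """Backbone MDV → GC-MS-comparable fragment MID (expand, truncate, normalize)."""
    from .emu import EMU

    mdv = mdvs[EMU(frag.species, frag.emu_indices)]
    raw = natural_abundance_expand(mdv, frag, c13_background=c13_background)
    return truncate_normalize(raw, frag.retained - 1, frag.normalize)


def detection_filter(values: dict, threshold: float = 0.04) -> dict:
    """Retain, per fragment, the mass indices with abundance ≥ threshold.

    ``values`` maps fragment name → MID vector; returns name → sorted tuple of
    retained mass indices.  Fragments losing every mass trigger a warning
    entry (empty tuple) rather than an exception.
    """
    retained = {}
    for name, vec in values.items():
        keep = tuple(int(i) for i, v in enumerate(np.asarray(vec, float)) if v >= threshold)
        retained[name] = keep
    return retained


@dataclass
class MeasurementSet:
    """Measured MIDs and effluxes with their standard deviations.

    ``mids`` maps fragment name → (mass indices, values, sds); ``effluxes``
    maps flux id → (value, sd).  Only retained (post-filter) entries are
    stored, so ``w`` counts exactly the independent measurements.
    """

    mids: dict
    effluxes: dict

    def __post_init__(self):
        for name, (idx, val, sd) in self.mids.items():
            idx, val, sd = (np.asarray(a, float) for a in (idx, val, sd))
            if not (len(idx) == len(val) == len(sd)):
                raise ValueError(f"{name}: ragged MID block")
            if (sd < 0).any():
                raise ValueError(f"{name}: negative MID sd")
            self.mids[name] = (idx.astype(int), val, sd)
        for fid, (v, sd) in self.effluxes.items():
            if sd < 0:
                raise ValueError(f"{fid}: negative efflux sd")

    @property
    def w_mid(self) -> int:
        return sum(len(v[0]) for v in self.mids.values())

    @property
    def w_eff(self) -> int:
        return len(self.effluxes)

    @property
    def w(self) -> int:
        return self.w_mid + self.w_eff

    def copy(self) -> "MeasurementSet":
        return MeasurementSet(
            {k: (v[0].copy(), v[1].copy(), v[2].copy()) for k, v in self.mids.items()},
            dict(self.effluxes),
        )

    def flat_values(self) -> np.ndarray:
        parts = [v[1] for _, v in sorted(self.mids.items())]
        parts.append(np.array([self.effluxes[k][0] for k in sorted(self.effluxes)]))
        return np.concatenate(parts) if parts else np.array([])


def corrupt(data: MeasurementSet, seed, floor_negative: bool = True) -> MeasurementSet:
    """Add independent N(0, σ) noise to every retained measurement.

    Negative corrupted MID abundances are floored at 0 (and the event recorded
    in ``out.floored``); reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    mids = {}
    floored = []
    for name in sorted(data.mids):
        idx, val, sd = data.mids[name]
        noisy = val + rng.normal(0.0, sd)
        if floor_negative:
            neg = noisy < 0
            if neg.any():
                floored.extend((name, int(i)) for i in idx[neg])
                noisy = np.where(neg, 0.0, noisy)
        mids[name] = (idx.copy(), noisy, sd.copy())
    effluxes = {}
    for fid in sorted(data.effluxes):
        v, sd = data.effluxes[fid]
        effluxes[fid] = (float(v + rng.normal(0.0, sd)), sd)
    out = MeasurementSet(mids, effluxes)
    out.floored = floored
    return out


def replicate_stats(replicates):
    """Per-entry mean and unbiased (L−1) standard deviation across replicates.

    All replicates must share the same retained-measurement layout; refuses
    L = 1 (the unbiased variance is undefined).
    """
    L = len(replicates)
    if L < 2:
        raise ValueError("need at least two replicates for an unbiased variance")
    first = replicates[0]
    mids = {}
    for name in first.mids:
        idx = first.mids[name][0]
        stack = []
        for r in replicates:
            ridx, val, _ = r.mids[name]
            if not np.array_equal(ridx, idx):
                raise ValueError(f"{name}: replicate retained-mass layouts differ")
            stack.append(val)
        arr = np.vstack(stack)
        mids[name] = (idx.copy(), arr.mean(axis=0), arr.std(axis=0, ddof=1))
    effluxes = {}
    for fid in first.effluxes:
        vals = np.array([r.effluxes[fid][0] for r in replicates])
        effluxes[fid] = (float(vals.mean()), float(vals.std(ddof=1)))
    return mids, effluxes
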