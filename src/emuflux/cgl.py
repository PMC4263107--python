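"""Reconstructed Corynebacterium glutamicum l-lysine-producer fixture.

A central-carbon metabolic model of an l-lysine-overproducing C. glutamicum
strain grown on glucose: EMP and pentose-phosphate pathways, TCA cycle with
lumped PEP/PYR and OAA/MAL pools (carboxylation and decarboxylation between
them as single irreversible reactions), explicit CO2 balancing with an
environment-exchange reaction, biosynthesis and transport of lysine and the
excreted co-products (glycine, trehalose, lactate, α-ketoglutarate, plus the
acetaldehyde released by the threonine-aldolase glycine route), two glycine
routes (from serine and from threonine), an inactive glyoxylate shunt
(omitted), explicit biosynthesis for the amino acids that are measured or
whose synthesis carries CO2, alanine/aspartate/glutamate as label-mapping
(S-type) reactions with their anabolic demand drawn through precursors, and a
single lumped biomass equation.

The reference flux vector ``U_REF`` is a repo-chosen feasible point of this
network (the original study's true flux vector is not published); every
quantitative test against this fixture therefore targets structure (counts,
dimensions) and self-consistency (parameter recovery), not published flux
values.
"""

from __future__ import annotations

import numpy as np

from .emu import EMU, TracerSpec
from .estimation import FluxModel, LabelingExperiment
from .measurement import MeasuredFragment, MeasurementSet, corrupt, detection_filter, simulate_fragment
from .model import assign_free_fluxes, parse_model_text

__all__ = [
    "CGL_TABLE",
    "FRAGMENTS",
    "TRUNCATED_FRAGMENTS",
    "INPUT_SPECIES",
    "THETA_REF",
    "EFFLUX_SIGMA",
    "build_cgl_model",
    "build_bundle",
    "tracer",
    "generate_experiment",
    "generate_ple",
]

INPUT_SPECIES = {"GLC_EX", "CO2_EX"}

CGL_TABLE = """\
id\tequation\tatoms\ttype\tbasis
GLC_upt\tGLC_EX > GLC6P\tabcdef > abcdef\tF\tfree
GPI_f\tGLC6P > F6P\tabcdef > abcdef\tFR\t
GPI_r\tF6P > GLC6P\tabcdef > abcdef\tR\tfree
PFK\tF6P > F16BP\tabcdef > abcdef\tF\t
ALD\tF16BP > DHAP + G3P\tabcdef > cba + def\tF\t
TPI\tDHAP > G3P\tabc > abc\tF\t
GAPDH\tG3P > PG3\tabc > abc\tF\t
ENO\tPG3 > PYR\tabc > abc\tF\t
G6PDH\tGLC6P > P5P + CO2\tabcdef > bcdef + a\tF\tfree
TKT1_f\tP5P + P5P > S7P + G3P\tabcde + fghij > abfghij + cde\tFR\t
TKT1_r\tS7P + G3P > P5P + P5P\tabcdefg + hij > abhij + cdefg\tR\tfree
TAL_f\tS7P + G3P > E4P + F6P\tabcdefg + hij > defg + abchij\tFR\t
TAL_r\tE4P + F6P > S7P + G3P\tabcd + efghij > efgabcd + hij\tR\tfree
TKT2_f\tP5P + E4P > F6P + G3P\tabcde + fghi > abfghi + cde\tFR\t
TKT2_r\tF6P + G3P > P5P + E4P\tabcdef + ghi > abghi + cdef\tR\tfree
PDH\tPYR > ACCOA + CO2\tabc > bc + a\tF\t
CS\tOAA + ACCOA > CIT\tabcd + ef > dcbfea\tF\t
IDH\tCIT > AKG + CO2\tabcdef > abcde + f\tF\t
AKGDH\tAKG > SUC + CO2\tabcde > bcde + a\tF\t
SDH\tSUC > OAA\tabcd > abcd; abcd > dcba\tF\t
PC\tPYR + CO2 > OAA\tabc + d > abcd\tF\tfree
PCK\tOAA > PYR + CO2\tabcd > abc + d\tF\t
LDH\tPYR > LAC\tabc > abc\tF\t
LAC_out\tLAC > LAC_EX\tabc > abc\tF\tfree
SER_syn\tPG3 > SER\tabc > abc\tF\t
SHMT\tSER > GLY + MTHF\tabc > ab + c\tF\tfree
GCS\tGLY > CO2 + MTHF\tab > a + b\tF\t
THR_syn\tOAA > THR\tabcd > abcd\tF\t
THR_ald\tTHR > GLY + ACETAL\tabcd > ab + cd\tF\t
ACETAL_out\tACETAL > ACETAL_EX\tab > ab\tF\t
GLY_out\tGLY > GLY_EX\tab > ab\tF\tfree
CO2ex_f\tCO2 > CO2_EX\ta > a\tFR\t
CO2ex_r\tCO2_EX > CO2\ta > a\tR\tfree
TREM_syn\tGLC6P > TREM\tabcdef > abcdef\tF\t
TRE_syn\tTREM + TREM > TRE\tabcdef + ghijkl > abcdefghijkl\tF\t
TRE_out\tTRE > TRE_EX\tabcdefghijkl > abcdefghijkl\tF\tfree
VAL_syn\tPYR + PYR > VAL + CO2\tabc + def > abefc + d\tF\t
ILE_syn\tTHR + PYR > ILE + CO2\tabcd + efg > abfcdg + e\tF\t
LEU_syn\tPYR + PYR + ACCOA > LEU + CO2 + CO2\tabc + def + gh > ghbefc + a + d\tF\t
PHE_syn\tPYR + PYR + E4P > PHE + CO2\tabc + def + ghij > defbcghij + a\tF\t
TYR_syn\tPYR + PYR + E4P > TYR + CO2\tabc + def + ghij > defbcghij + a\tF\t
DAP_syn\tPYR + OAA > DAP\tabc + defg > abcdefg; abc + defg > gfedcba\tF\t
LYS_syn\tDAP > LYS + CO2\tabcdefg > abcdef + g\tF\t
LYS_out\tLYS > LYS_EX\tabcdef > abcdef\tF\tfree
AKG_out\tAKG > AKG_EX\tabcde > abcde\tF\t
ARG_syn\tAKG + CO2 > ARG\tabcde + f > abcdef\tF\t
MET_syn\tOAA + MTHF > MET\tabcd + e > abcde\tF\t
HIS_syn\tP5P + MTHF > HIS\tabcde + f > abcdef\tF\t
PRO_syn\tAKG > PRO\tabcde > abcde\tF\t
TRP_syn\tSER + PYR + E4P + P5P > TRP + CO2 + G3P\tabc + def + ghij + klmno > abcefghijkl + d + mno\tF\t
BM\t0.20 GLC6P + 0.10 F6P + 0.90 P5P + 0.40 E4P + 0.10 G3P + 1.50 PG3 + 2.80 PYR + 1.80 OAA + 1.30 AKG + 2.40 ACCOA + 0.30 MTHF + 0.60 SER + 0.90 GLY + 0.50 THR + 0.40 VAL + 0.30 ILE + 0.40 LEU + 0.20 PHE + 0.10 TYR + 0.05 TRP + 0.35 LYS + 0.10 DAP + 0.25 ARG + 0.15 MET + 0.10 HIS + 0.20 PRO > BIOMASS\t\tB\tfree
ALA_map\tPYR > ALA\tabc > abc\tS\t
ASP_map\tOAA > ASP\tabcd > abcd\tS\t
GLU_map\tAKG > GLU\tabcde > abcde\tS\t
"""

PREFERRED_FREE = [
    "GLC_upt", "BM", "LYS_out", "TRE_out", "GLY_out", "LAC_out", "AKG_out",
    "GPI_r", "TKT1_r", "TAL_r", "TKT2_r", "CO2ex_r",
    "G6PDH", "PC", "SHMT",
]

# reference free-flux point (glucose uptake normalized to 100); repo-chosen
# feasible stand-in for the unpublished true flux vector
THETA_REF = {
    "GLC_upt": 100.0,
    "BM": 2.0,
    "LYS_out": 15.0,
    "TRE_out": 1.5,
    "GLY_out": 1.0,
    "LAC_out": 1.0,
    "AKG_out": 0.5,
    "GPI_r": 10.0,
    "TKT1_r": 5.0,
    "TAL_r": 5.0,
    "TKT2_r": 5.0,
    "CO2ex_r": 20.0,
    "G6PDH": 60.0,
    "PC": 30.0,
    "SHMT": 0.8,
}

# measured-efflux standard deviations (same units as the fluxes)
EFFLUX_SIGMA = {
    "GLC_upt": 2.0,
    "BM": 0.05,
    "LYS_out": 0.5,
    "TRE_out": 0.08,
    "GLY_out": 0.05,
    "LAC_out": 0.05,
    "AKG_out": 0.03,
}

# derivatized [M-57] (TBDMS) / TMS fragment registry; formulas are standard
# compositions for these nominal masses
_FRAGMENT_DEFS = [
    ("Ala-260", "ALA", "C11H26NO2Si2", 3),
    ("Val-288", "VAL", "C13H30NO2Si2", 5),
    ("Thr-404", "THR", "C18H42NO3Si3", 4),
    ("Asp-418", "ASP", "C18H40NO4Si3", 4),
    ("Glu-432", "GLU", "C19H42NO4Si3", 5),
    ("Ser-390", "SER", "C17H40NO3Si3", 3),
    ("Phe-336", "PHE", "C17H30NO2Si2", 9),
    ("Tyr-466", "TYR", "C23H44NO3Si3", 9),
    ("Tre-361", "TRE", "C14H29O5Si3", 6),
    ("Gly-246", "GLY", "C10H24NO2Si2", 2),
]

#: full-length fragment registry (all n+1 masses before detection filtering)
FRAGMENTS = {
    name: MeasuredFragment(name, sp, formula, n) for name, sp, formula, n in _FRAGMENT_DEFS
}

#: the published-data layout: (m0, m1, m2) for nine fragments, (m0, m1) for Gly
TRUNCATED_FRAGMENTS = {
    name: MeasuredFragment(name, sp, formula, n, truncate_to=2 if name == "Gly-246" else 3)
    for name, sp, formula, n in _FRAGMENT_DEFS
}


def build_cgl_model():
    """(network, partition) with the documented free fluxes and efflux bounds."""
    net = parse_model_text(CGL_TABLE)
    part = assign_free_fluxes(net, preferred_free=PREFERRED_FREE)
    for fid, sigma in EFFLUX_SIGMA.items():
        v = THETA_REF[fid]
        part.set_bounds(fid, max(0.0, v - 1.96 * sigma), v + 1.96 * sigma)
    for fid in PREFERRED_FREE:
        if fid not in EFFLUX_SIGMA:
            part.set_bounds(fid, 0.0, 150.0)
    return net, part


def theta_ref(part) -> np.ndarray:
    return np.array([THETA_REF[f] for f in part.free_ids])


def target_emus(fragments=None):
    frags = fragments or FRAGMENTS
    return sorted({EMU(f.species, f.emu_indices) for f in frags.values()})


def tracer(kind: str, purity: float = 0.99, background: float = 0.0107) -> TracerSpec:
    """Glucose tracer presets: '1-13C' … '6-13C', 'U-13C', 'U-12C', or mixtures
    given as [(fraction, kind), ...]."""
    if isinstance(kind, (list, tuple)):
        comps = []
        for frac, k in kind:
            comps.append((frac, _glc_positions(k)))
        return TracerSpec({"GLC_EX": comps}, purity=purity, background=background)
    return TracerSpec(
        {"GLC_EX": [(1.0, _glc_positions(kind))]}, purity=purity, background=background
    )


def _glc_positions(kind: str) -> frozenset:
    if kind == "U-13C":
        return frozenset(range(1, 7))
    if kind == "U-12C":
        return frozenset()
    if kind.endswith("-13C"):
        return frozenset({int(kind.split("-")[0])})
    raise ValueError(f"unknown glucose tracer {kind!r}")


def _efflux_measurements(theta, part, rng=None):
    out = {}
    for fid, sigma in EFFLUX_SIGMA.items():
        v = float(theta[part.free_ids.index(fid)])
        if rng is not None:
            v += float(rng.normal(0.0, sigma))
        out[fid] = (v, sigma)
    return out


def generate_experiment(
    tracer_spec,
    theta=None,
    seed=None,
    corrupt_data: bool = True,
    sigma_mid: float = 0.004,
    threshold: float = 0.04,
    fragments=None,
    normalize: bool = True,
):
    """Simulate one labeling experiment at the reference (or given) fluxes.

    Pipeline (matching the study protocol): forward EMU simulation at θ →
    natural-abundance expansion per fragment formula → truncation to n+1
    masses (+ normalization) → 4 mol% detection filter on the noise-free
    values → optional N(0, σ) corruption of MIDs and effluxes.
    Returns a :class:`LabelingExperiment`.
    """
    from .emu import decompose, simulate_mids

    net, part = build_cgl_model()
    frags = fragments or FRAGMENTS
    th = theta_ref(part) if theta is None else np.asarray(theta, float)
    emunet = decompose(net, target_emus(frags), INPUT_SPECIES)
    mdvs = simulate_mids(emunet, part.flux_dict(th, check=False), tracer_spec)
    sims = {name: simulate_fragment(mdvs, f) for name, f in frags.items()}
    retained = detection_filter(sims, threshold)
    mids = {}
    for name, idx in retained.items():
        if not idx:
            continue
        mids[name] = (np.array(idx), sims[name][list(idx)], np.full(len(idx), sigma_mid))
    rng = np.random.default_rng(seed) if seed is not None else None
    effluxes = _efflux_measurements(th, part, rng=rng if corrupt_data else None)
    data = MeasurementSet(mids, effluxes)
    if corrupt_data:
        if seed is None:
            raise ValueError("corrupt_data=True requires a seed")
        data = corrupt(data, np.random.default_rng((seed, 1)))
        data = MeasurementSet(data.mids, effluxes)  # efflux noise handled above
    return LabelingExperiment(tracer_spec, data, dict(frags))


def generate_ple(tracer_specs, theta=None, seeds=None, **kw):
    """Independent labeling experiments sharing θ (efflux noise drawn per LE)."""
    if len(tracer_specs) < 2:
        raise ValueError("a PLE needs at least two labeling experiments")
    if seeds is None:
        seeds = list(range(len(tracer_specs)))
    if len(seeds) != len(tracer_specs):
        raise ValueError("one seed per labeling experiment")
    return [
        generate_experiment(tr, theta=theta, seed=s, **kw)
        for tr, s in zip(tracer_specs, seeds)
    ]


def build_bundle(experiments):
    """FluxModel over already-generated experiments."""
    net, part = build_cgl_model()
    return FluxModel(net, part, experiments, INPUT_SPECIES)
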