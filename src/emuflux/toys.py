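"""Small fully-worked networks used throughout the test-suite and docs.

``toy3c`` — a 5-reaction, 3-carbon branch network in which substrate B is
cleaved to C (carbons 1,2) and D (carbon 3) by two routes that retain
different carbons; with a positionally labeled tracer the branch split is
identifiable from the C/D mass distributions alone.

``toy_cond`` — adds a condensation (convolution node) and a scrambled cycle,
exercising within-size EMU coupling.
"""

from __future__ import annotations

import numpy as np

from .model import parse_model_text, assign_free_fluxes
from .emu import EMU, TracerSpec

__all__ = ["toy3c_model", "toy3c_fragments", "toy_cond_model", "TOY3C_TABLE", "TOY_COND_TABLE"]

# atom maps: upt feeds A_EX(abc) -> B; cleave keeps carbons 1,2 in C,
# alt keeps carbons 2,3 (the branch the free flux controls)
TOY3C_TABLE = """\
id\tequation\tatoms\ttype\tbasis
upt\tA_EX > B\tabc > abc\tF\tfree
cleave\tB > C + D\tabc > ab + c\tF\t
alt\tB > C + D\tabc > bc + a\tF\tfree
c_out\tC > C_EX\tab > ab\tF\t
d_out\tD > D_EX\ta > a\tF\t
"""

TOY_COND_TABLE = """\
id\tequation\tatoms\ttype\tbasis
upt\tA_EX > A\tabc > abc\tF\tfree
cleave\tA > C + D\tabc > ab + c\tF\t
cond\tC + D > E\tab + c > abc\tF\t
cycle\tE > A\tabc > cab; abc > abc\tF\tfree
e_out\tE > E_EX\tabc > abc\tF\t
"""


def toy3c_model():
    """(network, partition) with free fluxes (upt, alt) and box bounds."""
    net = parse_model_text(TOY3C_TABLE)
    part = assign_free_fluxes(net, preferred_free=["upt", "alt"])
    part.set_bounds("upt", 0.0, 200.0)
    part.set_bounds("alt", 0.0, 200.0)
    return net, part


def toy3c_fragments():
    """Measured EMUs of toy3c: full backbones of C and D."""
    return {"C_frag": EMU("C", (1, 2)), "D_frag": EMU("D", (1,))}


def toy3c_tracer(kind: str = "1-13C", purity: float = 0.99, background: float = 0.0107):
    labels = {
        "1-13C": [(1.0, frozenset({1}))],
        "2-13C": [(1.0, frozenset({2}))],
        "3-13C": [(1.0, frozenset({3}))],
        "U-13C": [(1.0, frozenset({1, 2, 3}))],
        "U-12C": [(1.0, frozenset())],
    }
    return TracerSpec({"A_EX": labels[kind]}, purity=purity, background=background)


def toy_cond_model():
    net = parse_model_text(TOY_COND_TABLE)
    part = assign_free_fluxes(net, preferred_free=["upt", "cycle"])
    part.set_bounds("upt", 0.0, 200.0)
    part.set_bounds("cycle", 0.0, 200.0)
    return net, part
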