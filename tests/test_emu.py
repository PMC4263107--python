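"""EMU decomposition, tracer MDVs and cascade simulation."""

import itertools

import numpy as np
import pytest

from emuflux.emu import EMU, TracerSpec, convolve, decompose, simulate_mids, tracer_mdv
from emuflux.model import parse_model_text
from emuflux.toys import TOY3C_TABLE, toy3c_model, toy3c_tracer, toy_cond_model


def brute_force_closure(net, targets, inputs):
    """Independent backward-closure oracle: exhaustive fixed-point over the
    production maps, no block machinery."""
    unknown = set()
    frontier = [t for t in targets if t.species not in inputs]
    while frontier:
        emu = frontier.pop()
        if emu in unknown:
            continue
        unknown.add(emu)
        for r in net.producers(emu.species):
            for w, smaps, pmaps in r.atom_maps:
                for j, (sp, _) in enumerate(r.products):
                    if sp != emu.species or pmaps[j] is None:
                        continue
                    letters = [pmaps[j][i - 1] for i in emu.indices]
                    for k, smap in enumerate(smaps):
                        if smap is None:
                            continue
                        pos = tuple(smap.index(c) + 1 for c in letters if c in smap)
                        if pos:
                            src = EMU(r.substrates[k][0], pos)
                            if src.species not in inputs:
                                frontier.append(src)
    return unknown


class TestDecompose:
    def test_single_identity_reaction(self):
        net = parse_model_text("id\tequation\tatoms\ttype\nr1\tA_EX > B\tab > ab\tF\n")
        emunet = decompose(net, [EMU("B", (1, 2))], {"A_EX"})
        assert emunet.unknown_emus == [EMU("B", (1, 2))]
        assert emunet.input_emus == [EMU("A_EX", (1, 2))]

    def test_toy3c_matches_bruteforce_closure(self):
        net, _ = toy3c_model()
        targets = [EMU("C", (1, 2)), EMU("D", (1,))]
        emunet = decompose(net, targets, {"A_EX"})
        oracle = brute_force_closure(net, targets, {"A_EX"})
        assert set(emunet.balances) == oracle

    def test_decomposition_independent_of_reaction_order(self):
        lines = TOY3C_TABLE.strip().splitlines()
        header, rows = lines[0], lines[1:]
        targets = [EMU("C", (1, 2)), EMU("D", (1,))]
        reference = None
        for perm in itertools.permutations(rows):
            net = parse_model_text("\n".join([header, *perm]) + "\n")
            emunet = decompose(net, targets, {"A_EX"})
            key = (set(emunet.balances), emunet.n_blocks)
            if reference is None:
                reference = key
            assert key == reference

    def test_unreachable_target_names_the_metabolite(self):
        net, _ = toy3c_model()
        with pytest.raises(ValueError, match="GHOST"):
            decompose(net, [EMU("GHOST", (1,))], {"A_EX"})


class TestTracerMDV:
    def test_natural_one_carbon(self):
        spec = TracerSpec({}, background=0.0107)
        np.testing.assert_allclose(
            tracer_mdv(spec, EMU("CO2_EX", (1,))), [0.9893, 0.0107]
        )

    def test_positionally_labeled_carbon(self):
        spec = toy3c_tracer("1-13C")
        np.testing.assert_allclose(tracer_mdv(spec, EMU("A_EX", (1,))), [0.01, 0.99])

    def test_mixture_equals_isotopomer_enumeration(self):
        spec = TracerSpec(
            {"A_EX": [(0.5, frozenset({1, 2, 3})), (0.5, frozenset())]},
            purity=0.99,
            background=0.0107,
        )
        emu = EMU("A_EX", (1, 2, 3))
        # oracle: enumerate all 2^3 isotopomers with per-position probabilities
        expected = np.zeros(4)
        for frac, labeled in spec.mixtures["A_EX"]:
            p = [0.99 if i in labeled else 0.0107 for i in (1, 2, 3)]
            for bits in itertools.product([0, 1], repeat=3):
                prob = np.prod([pi if b else 1 - pi for pi, b in zip(p, bits)])
                expected[sum(bits)] += frac * prob
        np.testing.assert_allclose(tracer_mdv(spec, emu), expected, atol=1e-12)
        halves = 0.5 * (
            tracer_mdv(toy3c_tracer("U-13C"), emu) + tracer_mdv(toy3c_tracer("U-12C"), emu)
        )
        np.testing.assert_allclose(tracer_mdv(spec, emu), halves, atol=1e-12)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="purity"):
            TracerSpec({}, purity=0.0)
        with pytest.raises(ValueError, match="sum"):
            TracerSpec({"A": [(0.6, frozenset()), (0.3, frozenset({1}))]})


class TestConvolve:
    def test_convolution_properties_hypothesis(self):
        from hypothesis import given, settings, strategies as hst

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(
            hst.lists(hst.floats(0.01, 1.0), min_size=2, max_size=6),
            hst.lists(hst.floats(0.01, 1.0), min_size=2, max_size=6),
        )
        def check(a, b):
            a = np.array(a) / np.sum(a)
            b = np.array(b) / np.sum(b)
            c = convolve(a, b)
            assert len(c) == len(a) + len(b) - 1
            assert abs(c.sum() - 1.0) < 1e-9
            np.testing.assert_allclose(c, convolve(b, a), atol=1e-12)

        check()

    def test_identity_element(self):
        a = np.array([0.2, 0.5, 0.3])
        np.testing.assert_allclose(convolve(a, [1.0, 0.0]), [0.2, 0.5, 0.3, 0.0])

    def test_binomial_square(self):
        np.testing.assert_allclose(convolve([0.5, 0.5], [0.5, 0.5]), [0.25, 0.5, 0.25])

    def test_mean_mass_additivity(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.dirichlet(np.ones(rng.integers(2, 6)))
            b = rng.dirichlet(np.ones(rng.integers(2, 6)))
            c = convolve(a, b)
            mean = lambda v: float(np.arange(len(v)) @ v)  # noqa: E731
            assert abs(mean(c) - mean(a) - mean(b)) < 1e-12
            assert abs(c.sum() - 1.0) < 1e-12


class TestSimulate:
    def test_no_label_in_no_label_out(self):
        net, part = toy3c_model()
        emunet = decompose(net, [EMU("C", (1, 2)), EMU("D", (1,))], {"A_EX"})
        spec = toy3c_tracer("U-12C", purity=1.0, background=0.0)
        spec = TracerSpec({"A_EX": [(1.0, frozenset())]}, purity=1.0, background=0.0)
        mdvs = simulate_mids(emunet, part.flux_dict([100.0, 30.0]), spec)
        for emu, mdv in mdvs.items():
            expected = np.zeros(emu.size + 1)
            expected[0] = 1.0
            np.testing.assert_allclose(mdv, expected, atol=1e-12)

    def test_flux_scaling_leaves_mdvs_unchanged(self):
        net, part = toy3c_model()
        emunet = decompose(net, [EMU("C", (1, 2)), EMU("D", (1,))], {"A_EX"})
        spec = toy3c_tracer("1-13C")
        u1 = part.flux_dict([100.0, 30.0])
        u2 = {k: 7.3 * v for k, v in u1.items()}
        m1 = simulate_mids(emunet, u1, spec)
        m2 = simulate_mids(emunet, u2, spec)
        for emu in m1:
            np.testing.assert_allclose(m1[emu], m2[emu], atol=1e-12)

    def test_mdvs_normalized_and_nonnegative_property(self):
        net, part = toy_cond_model()
        emunet = decompose(net, [EMU("E", (1, 2, 3))], {"A_EX"})
        rng = np.random.default_rng(3)
        for kind in ["1-13C", "2-13C", "U-13C"]:
            for _ in range(10):
                theta = part.sample_feasible_point(rng)
                if part.compute_fluxes(theta, check=False).min() <= 1e-6:
                    continue
                mdvs = simulate_mids(emunet, part.flux_dict(theta), toy3c_tracer(kind))
                for mdv in mdvs.values():
                    assert mdv.min() > -1e-12
                    assert abs(mdv.sum() - 1.0) < 1e-9

    def test_zero_throughput_block_reports_emus(self):
        net, part = toy3c_model()
        emunet = decompose(net, [EMU("C", (1, 2)), EMU("D", (1,))], {"A_EX"})
        u = part.flux_dict([100.0, 30.0])
        dead = {k: 0.0 for k in u}
        with pytest.raises(ValueError, match="throughput"):
            simulate_mids(emunet, dead, toy3c_tracer("1-13C"))
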