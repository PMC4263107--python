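"""Reaction-table parsing, stoichiometry and free-flux partitioning."""

import numpy as np
import pytest
import sympy

from emuflux.model import (
    ModelValidationError,
    Reaction,
    assign_free_fluxes,
    parse_model_text,
)
from emuflux.toys import TOY3C_TABLE, toy3c_model

CHAIN = """\
id\tequation\tatoms\ttype\tbasis
in\tA_EX > A\tab > ab\tF\tfree
ab\tA > B\tab > ab\tF\t
out\tB > B_EX\tab > ab\tF\t
"""


class TestParsing:
    def test_single_identity_reaction(self):
        net = parse_model_text("id\tequation\tatoms\ttype\nr1\tA_EX > B\tab > ab\tF\n")
        assert len(net.reactions) == 1
        assert net.balanced_metabolites == ["B"]
        assert net.carbons["B"] == 2

    def test_toy3c_equals_hand_built(self):
        net = parse_model_text(TOY3C_TABLE)
        expected = Reaction(
            id="cleave",
            substrates=(("B", 1.0),),
            products=(("C", 1.0), ("D", 1.0)),
            atom_maps=((1.0, ("abc",), ("ab", "c")),),
            kind="F",
            basis="",
        )
        got = net.reaction("cleave")
        for field in ("id", "substrates", "products", "atom_maps", "kind", "basis"):
            assert getattr(got, field) == getattr(expected, field)
        assert [r.id for r in net.reactions] == ["upt", "cleave", "alt", "c_out", "d_out"]

    @pytest.mark.parametrize(
        "row, message",
        [
            ("r1\tA_EX > B\tab > ab\tF\nr1\tA_EX > B\tab > ab\tF", "duplicate"),
            ("rx\tA_EX > B\tabc > ab\tF", "unbalanced"),
            ("rx\tA_EX > B\tab > ab\tQ", "unknown type"),
            ("rx\tA_EX > B + B\tab > a + b\tF\nry\tB > C\tabc > abc\tF", "carbons"),
        ],
    )
    def test_validation_errors_are_reported(self, row, message):
        text = "id\tequation\tatoms\ttype\n" + row + "\n"
        with pytest.raises(ModelValidationError) as err:
            parse_model_text(text)
        assert any(message in p for p in err.value.problems)

    def test_scrambling_maps_share_flux_with_equal_weights(self):
        net = parse_model_text(
            "id\tequation\tatoms\ttype\nsym\tA_EX > B\tab > ab; ab > ba\tF\n"
        )
        maps = net.reaction("sym").atom_maps
        assert len(maps) == 2
        assert maps[0][0] == maps[1][0] == 0.5


class TestStoichiometry:
    def test_linear_chain(self):
        net = parse_model_text(CHAIN)
        S = net.stoichiometry
        assert S.shape == (2, 3)
        assert net.rank() == 2

    def test_mapping_only_reactions_carry_no_column(self):
        text = TOY3C_TABLE + "map\tB > X\tabc > abc\tS\t\n"
        net = parse_model_text(text)
        assert "map" not in net.stoichiometry.columns
        assert "X" not in net.balanced_metabolites

    def test_toy3c_rank_two_independent_algorithms(self):
        net = parse_model_text(TOY3C_TABLE)
        by_svd = int(np.linalg.matrix_rank(net.S))
        by_rref = sympy.Matrix(net.S).rank()
        assert by_svd == by_rref == 3

    def test_dead_end_detection(self):
        text = CHAIN + "dead\tA > C\tab > ab\tF\t\n"
        net = parse_model_text(text)
        assert net.dead_end_metabolites() == ["C"]


class TestFreeFluxes:
    def test_chain_has_one_degree_of_freedom(self):
        net = parse_model_text(CHAIN)
        part = assign_free_fluxes(net, preferred_free=["in"])
        assert part.p == 1
        np.testing.assert_allclose(part.compute_fluxes([2.5]), [2.5, 2.5, 2.5])

    def test_partition_dimensions_and_nullspace(self):
        net, part = toy3c_model()
        assert part.p + net.rank() == net.S.shape[1]
        rng = np.random.default_rng(0)
        for _ in range(100):
            theta = rng.uniform(0, 50, size=2)
            theta = np.sort(theta)[::-1]  # upt >= alt keeps u >= 0
            u = part.compute_fluxes(theta, check=False)
            assert np.abs(net.S @ u).max() < 1e-10

    def test_symbolic_oracle_for_dependent_solve(self):
        net, part = toy3c_model()
        t1, t2 = sympy.symbols("t1 t2")
        S = sympy.Matrix(net.S)
        ids = net.flux_ids
        free = {ids.index("upt"): t1, ids.index("alt"): t2}
        unknowns = {i: sympy.Symbol(f"u{i}") for i in range(len(ids)) if i not in free}
        u = [free.get(i, unknowns.get(i)) for i in range(len(ids))]
        sol = sympy.solve(list(S @ sympy.Matrix(u)), list(unknowns.values()), dict=True)[0]
        theta = np.array([7.0, 2.0])
        numeric = part.compute_fluxes(theta)
        subs = {t1: 7.0, t2: 2.0}
        for i, fid in enumerate(ids):
            expr = theta[0] if fid == "upt" else theta[1] if fid == "alt" else sol[unknowns[i]]
            assert abs(float(sympy.sympify(expr).subs(subs)) - numeric[i]) < 1e-10

    def test_linearity_of_flux_map(self):
        _, part = toy3c_model()
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.uniform()
            t1, t2 = rng.uniform(0, 10, (2, part.p))
            lhs = part.compute_fluxes(a * t1 + (1 - a) * t2, check=False)
            rhs = a * part.compute_fluxes(t1, check=False) + (1 - a) * part.compute_fluxes(t2, check=False)
            np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_conflicting_preferred_set_is_named(self):
        # freeing both efflux columns leaves duplicate dependent columns
        net, _ = toy3c_model()
        with pytest.raises(ValueError, match="conflict"):
            assign_free_fluxes(net, preferred_free=["c_out", "d_out"])

    def test_oversized_preferred_set_rejected(self):
        net = parse_model_text(CHAIN)
        with pytest.raises(ValueError, match="p=1"):
            assign_free_fluxes(net, preferred_free=["in", "ab"])

    def test_infeasible_theta_is_flagged_not_clipped(self):
        _, part = toy3c_model()
        with pytest.raises(ValueError, match="negative dependent"):
            part.compute_fluxes([10.0, 50.0])  # alt > upt drives cleave < 0


class TestFeasibleSampling:
    def test_deterministic_given_seed(self):
        _, part = toy3c_model()
        a = part.sample_feasible_point(1)
        b = part.sample_feasible_point(1)
        np.testing.assert_array_equal(a, b)

    def test_all_samples_feasible(self):
        _, part = toy3c_model()
        rng = np.random.default_rng(2)
        for _ in range(100):
            theta = part.sample_feasible_point(rng)
            assert (part.compute_fluxes(theta) >= -1e-12).all()

    def test_degenerate_bounds_return_the_point(self):
        _, part = toy3c_model()
        part = type(part)(part.network, part.free_ids, part.dependent_ids, part.Z)
        part.set_bounds("upt", 50.0, 50.0)
        part.set_bounds("alt", 10.0, 10.0)
        np.testing.assert_allclose(part.sample_feasible_point(0), [50.0, 10.0])
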