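import numpy as np
import pytest

from emuflux.emu import EMU, decompose, simulate_mids
from emuflux.estimation import FluxModel, LabelingExperiment
from emuflux.measurement import MeasuredFragment, MeasurementSet, corrupt, simulate_fragment
from emuflux.toys import toy3c_model, toy3c_tracer

TOY_FRAGMENTS = {
    "C_frag": MeasuredFragment("C_frag", "C", "C2", 2),
    "D_frag": MeasuredFragment("D_frag", "D", "C1", 1),
}
TOY_THETA_TRUE = np.array([100.0, 30.0])


def make_toy_le(kind="1-13C", theta=TOY_THETA_TRUE, seed=None, sigma_mid=0.004,
                sigma_eff=2.0, effluxes=("upt",)):
    """Synthetic toy3c labeling experiment (optionally noise-corrupted)."""
    net, part = toy3c_model()
    spec = toy3c_tracer(kind)
    emunet = decompose(net, [EMU("C", (1, 2)), EMU("D", (1,))], {"A_EX"})
    mdvs = simulate_mids(emunet, part.flux_dict(theta), spec)
    sims = {n: simulate_fragment(mdvs, f) for n, f in TOY_FRAGMENTS.items()}
    mids = {n: (np.arange(len(v)), v, np.full(len(v), sigma_mid)) for n, v in sims.items()}
    u = part.flux_dict(theta)
    eff = {fid: (float(u[fid]), sigma_eff) for fid in effluxes}
    data = MeasurementSet(mids, eff)
    if seed is not None:
        data = corrupt(data, seed)
    return LabelingExperiment(spec, data, dict(TOY_FRAGMENTS))


def make_toy_model(les):
    net, part = toy3c_model()
    return FluxModel(net, part, list(les), {"A_EX"})


@pytest.fixture(scope="session")
def toy_model_noiseless():
    return make_toy_model([make_toy_le()])


@pytest.fixture(scope="session")
def cgl_model():
    from emuflux import cgl

    net, part = cgl.build_cgl_model()
    return net, part


@pytest.fixture(scope="session")
def cgl_emunet(cgl_model):
    from emuflux import cgl

    net, _ = cgl_model
    return decompose(net, cgl.target_emus(), cgl.INPUT_SPECIES)


@pytest.fixture(scope="session")
def cgl_sle_noiseless():
    """Uncorrupted fixture SLE under [1-13C] glucose with its FluxModel."""
    from emuflux import cgl

    le = cgl.generate_experiment(cgl.tracer("1-13C"), corrupt_data=False)
    return cgl.build_bundle([le])
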