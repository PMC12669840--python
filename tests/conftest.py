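import numpy as np
import pytest

from billmech import (BillParams, FEModel, assemble_configuration,
                      generate_surface, generate_volume, sample_population)
from billmech import fea
from billmech.synthetic import FEMALE_MEAN, MALE_MEAN, default_population_spec
from billmech.tetmesh import box_mesh


@pytest.fixture(scope="session")
def female_params() -> BillParams:
    return FEMALE_MEAN


@pytest.fixture(scope="session")
def male_params() -> BillParams:
    return MALE_MEAN


@pytest.fixture(scope="session")
def female_surface(female_params):
    return generate_surface(female_params, id="F_mean", sex="F")


@pytest.fixture(scope="session")
def male_surface(male_params):
    return generate_surface(male_params, id="M_mean", sex="M")


@pytest.fixture(scope="session")
def female_volume(female_params):
    sp = generate_surface(female_params, id="F_vol", sex="F")
    return generate_volume(sp)


@pytest.fixture(scope="session")
def male_volume(male_params):
    sp = generate_surface(male_params, id="M_vol", sex="M")
    return generate_volume(sp)


@pytest.fixture(scope="session")
def small_population():
    """16 contour-only specimens of the default dimorphic population."""
    return sample_population(default_population_spec(seed=11), contours_only=True, n_u=40)


@pytest.fixture(scope="session")
def beam_setup():
    """Slender cantilever (L/h = 20), quadratic tets, stiffness prefactorized."""
    L, h, E, nu = 20.0, 1.0, 1000.0, 0.0
    mesh = box_mesh(L, h, h, 24, 2, 2)
    model = FEModel(mesh, {2: fea.MaterialSpec(E, nu)}, order=2)
    K = fea.assemble(model)
    lu, _ = fea.factorize(model, K, model.node_set("xmin"))
    return {"model": model, "K": K, "lu": lu, "L": L, "h": h, "E": E,
            "I": h ** 4 / 12.0}


def make_config(points_per_curve: int = 20, jitter: float = 0.0,
                seed: int = 0, params: BillParams | None = None):
    """A landmark configuration from an analytic bill, optionally jittered."""
    from billmech.landmarks import ContourCurve, configuration_from_contours
    from billmech.synthetic import generate_contours

    params = params or FEMALE_MEAN
    contours = generate_contours(params, n_u=40)
    if jitter:
        rng = np.random.default_rng(seed)
        contours = {
            lbl: ContourCurve(lbl, c.points + jitter * rng.standard_normal(c.points.shape))
            for lbl, c in contours.items()
        }
    return configuration_from_contours(contours, points_per_curve)
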