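import pytest

from fsmatrix.catalogue import ExposureEvaluation, FireEvaluation, ItemVariant, load_fixtures
from fsmatrix.config import ThresholdConfig
from fsmatrix.synthetic import generate_catalogue, generate_evaluations


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def config():
    return ThresholdConfig()


@pytest.fixture
def make_fire():
    """Factory for consolidated fire evaluations with sensible defaults."""

    def _make(type_id="sofa", variant="high", evaluator_id="consensus", contact=3,
              junction_count=2, ornateness=3, reactive_capacity=3,
              combustible_volume=0.005, ignition_narrative="a dropped cigarette"):
        return FireEvaluation(
            item=ItemVariant(type_id=type_id, variant=variant),
            evaluator_id=evaluator_id,
            contact=contact,
            junction_count=junction_count,
            ornateness=ornateness,
            reactive_capacity=reactive_capacity,
            combustible_volume=combustible_volume,
            ignition_narrative=ignition_narrative,
        )

    return _make


@pytest.fixture
def make_exposure():
    def _make(type_id="sofa", variant="high", evaluator_id="consensus", child_use=3,
              bare_skin=3, mouthing=2, cumulative_use=4, surface_area=1.0):
        return ExposureEvaluation(
            item=ItemVariant(type_id=type_id, variant=variant),
            evaluator_id=evaluator_id,
            child_use=child_use,
            bare_skin=bare_skin,
            mouthing=mouthing,
            cumulative_use=cumulative_use,
            surface_area=surface_area,
        )

    return _make


@pytest.fixture(scope="session")
def synthetic_panel():
    """A 12-type, 3-evaluator synthetic panel shared across tests."""
    catalogue, truth = generate_catalogue(12, seed=11)
    fire, exposure = generate_evaluations(catalogue, truth, n_evaluators=3, noise_sd=0.5, seed=11)
    return catalogue, truth, fire, exposure
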