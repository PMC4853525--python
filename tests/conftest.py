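import numpy as np
import pytest

from mediareach.content_coding import FLAG_COLUMNS, CodedVideo
from mediareach.survey import Respondent
from mediareach.synthetic_data import GeneratorConfig, generate_scenario


def random_video(rng: np.random.Generator, n_intervals: int = 30, density: float = 0.15,
                 video_id: str = "v") -> CodedVideo:
    mat = rng.random((n_intervals, len(FLAG_COLUMNS))) < density
    return CodedVideo.from_flag_matrix(video_id, mat)


def make_respondent(rid: str, age: int, gender: str, weight: float, seen: dict) -> Respondent:
    return Respondent(respondent_id=rid, age=age, gender=gender, weight=weight, seen=seen)


@pytest.fixture(scope="session")
def default_scenario():
    """One default-condition synthetic scenario, shared across tests."""
    return generate_scenario(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down generator configuration for fast end-to-end checks."""
    return GeneratorConfig(seed=3, n_videos=8, total_intervals=200,
                           n_adolescents=300, n_adults=300)
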