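import numpy as np
import pytest

from emergence_pitch import SyntheticParams, generate_match


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def short_params():
    """Short, shot-dense match parameters for fast end-to-end tests."""
    return SyntheticParams(
        half_length_s=300,
        halftime_gap_s=60,
        shot_hazard=0.02,
        min_shot_gap_s=40,
    )


@pytest.fixture(scope="session")
def short_match(short_params):
    return generate_match(short_params, seed=11)


@pytest.fixture
def tiny_tracking_csv(tmp_path):
    """3-frame, 2-team, 10-player tracking fixture file."""
    lines = ["t,team,player,x,y"]
    for t in range(3):
        for team in ("home", "away"):
            for p in range(1, 11):
                x = (p - 5.5) * 2.0 + t * 0.5 * (1 if team == "home" else -1)
                y = (p % 5 - 2) * 3.0
                lines.append(f"{t},{team},{p},{x},{y}")
    path = tmp_path / "tiny.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
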