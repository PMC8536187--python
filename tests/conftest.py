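import numpy as np
import pandas as pd
import pytest

from repleteaudit.model import default_reference_ranges

EPOCH = pd.Timestamp("2140-01-01")


def make_labs(rows) -> pd.DataFrame:
    """Rows of (stay, electrolyte, minutes, value) -> canonical lab frame."""
    return pd.DataFrame(
        {
            "subject_id": [f"P-{r[0]}" for r in rows],
            "stay_id": [r[0] for r in rows],
            "electrolyte": [r[1] for r in rows],
            "charttime": [EPOCH + pd.Timedelta(minutes=r[2]) for r in rows],
            "value": [float(r[3]) for r in rows],
        }
    )


def make_repletions(rows) -> pd.DataFrame:
    """Rows of (stay, electrolyte, minutes[, dose]) -> canonical repletion frame."""
    return pd.DataFrame(
        {
            "subject_id": [f"P-{r[0]}" for r in rows],
            "stay_id": [r[0] for r in rows],
            "electrolyte": [r[1] for r in rows],
            "ordertime": [EPOCH + pd.Timedelta(minutes=r[2]) for r in rows],
            "dose": [float(r[3]) if len(r) > 3 else 40.0 for r in rows],
        }
    )


def random_event_streams(rng: np.random.Generator, n_events: int, n_stays: int = 3):
    """A random small instance for oracle-equivalence checks."""
    n_labs = rng.integers(0, n_events + 1)
    n_reps = n_events - n_labs
    stays = [f"s{i}" for i in range(n_stays)]
    elecs = ["potassium", "magnesium"]
    labs = make_labs(
        [
            (
                stays[rng.integers(0, n_stays)],
                elecs[rng.integers(0, 2)],
                int(rng.integers(0, 5000)),
                float(rng.uniform(2.5, 6.5)),
            )
            for _ in range(n_labs)
        ]
    )
    reps = make_repletions(
        [
            (
                stays[rng.integers(0, n_stays)],
                elecs[rng.integers(0, 2)],
                int(rng.integers(0, 5000)),
            )
            for _ in range(n_reps)
        ]
    )
    return labs, reps


@pytest.fixture
def ranges():
    return default_reference_ranges()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
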