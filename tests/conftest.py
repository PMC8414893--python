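import numpy as np
import pandas as pd
import pytest

from intellipheno.event_model import EventStore, default_schedule, empty_frames
from intellipheno.simulate import default_config, generate_cohort


def make_tiny_store() -> EventStore:
    """Hand-written 3-animal store: 6 visits, 4 nosepokes, 10 licks.

    Visits 1-4 fall on day 1 of free adaptation, visits 5-6 on day 2
    (visit 6 starts exactly at the 86400 s boundary).
    """
    animals = pd.DataFrame(
        {
            "animal_id": ["A01", "A02", "A03"],
            "genotype": ["NonTg", "TG", "NonTg"],
            "cage_id": [1, 1, 1],
        }
    )
    visits = pd.DataFrame(
        {
            "visit_id": [1, 2, 3, 4, 5, 6],
            "animal_id": ["A01", "A01", "A02", "A02", "A03", "A01"],
            "corner": [1, 2, 1, 3, 4, 1],
            "t_start": [100.0, 300.0, 150.0, 500.0, 86500.0, 86400.0],
            "t_end": [200.0, 400.0, 250.0, 600.0, 86600.0, 86450.0],
        }
    )
    nosepokes = pd.DataFrame(
        {
            "visit_id": [1, 1, 3, 4],
            "side": ["left", "right", "left", "right"],
            "t": [120.0, 130.0, 200.0, 550.0],
        }
    )
    licks = pd.DataFrame(
        {
            "visit_id": [1, 1, 1, 1, 1, 3, 3, 4, 4, 4],
            "t": [121.0, 122.0, 123.0, 124.0, 125.0, 201.0, 202.0, 551.0, 552.0, 553.0],
        }
    )
    return EventStore(
        animals=animals,
        visits=visits,
        nosepokes=nosepokes,
        licks=licks,
        schedule=default_schedule(),
        assignments=empty_frames()["assignments"],
    )


@pytest.fixture
def tiny_store() -> EventStore:
    return make_tiny_store()


@pytest.fixture(scope="session")
def sim_store():
    """One default simulated cohort shared across the session."""
    store, truth = generate_cohort(default_config(seed=7))
    return store, truth
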