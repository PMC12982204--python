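import pytest

from scarfkit import GazeSegment, canonicalize
from scarfkit.fixtures import FixtureSpec, generate


def make_dataset(rows, **kwargs):
    """Dataset from (participant, stimulus, start, end, category, aois) tuples."""
    return canonicalize(
        [GazeSegment(p, s, a, b, cat, frozenset(aois)) for p, s, a, b, cat, aois in rows],
        **kwargs,
    )


@pytest.fixture
def worked_example():
    """The documented micro-example trial: fixations on A and B with a saccade.

    P1/S: fix A [0,100), sacc [100,120), fix B [120,300), fix A [300,350).
    Expected: A ttff=0 count=2 avg=75 dwell=150; B ttff=120 count=1 avg=180
    dwell=180.
    """
    return make_dataset(
        [
            ("P1", "S", 0, 100, "fixation", {"A"}),
            ("P1", "S", 100, 120, "saccade", ()),
            ("P1", "S", 120, 300, "fixation", {"B"}),
            ("P1", "S", 300, 350, "fixation", {"A"}),
        ]
    )


@pytest.fixture
def small_fixture():
    """Deterministic mid-size synthetic recording with groups + visibility."""
    return generate(FixtureSpec(n_participants=4, n_stimuli=3, seed=11))


@pytest.fixture
def plain_fixture():
    """Synthetic recording without groups/visibility (round-trip friendly)."""
    ds, truth = generate(
        FixtureSpec(n_participants=3, n_stimuli=3, seed=5, group_labels=(), visibility_density=0.0)
    )
    return ds, truth
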