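import numpy as np
import pytest

from operon_assembly import (
    BeadComplexSpec,
    InterfaceMatrix,
    distance_for_area,
    make_bead_complex,
)


@pytest.fixture
def bead_pair():
    """Two touching beads with a closed-form contact area."""
    spec = BeadComplexSpec(
        chains=(("A", "E1"), ("B", "E2")), bead_radius=3.0, contacts=(("A", "B", 6.0),)
    )
    return make_bead_complex(spec)


@pytest.fixture
def designed_four_chain():
    """Four beads with designed contact areas AB=1000 > BC=500 > CD=250."""
    r = 15.0
    contacts = tuple(
        (a, b, distance_for_area(area, r, 1.4))
        for (a, b), area in {("A", "B"): 1000.0, ("B", "C"): 500.0, ("C", "D"): 250.0}.items()
    )
    spec = BeadComplexSpec(
        chains=(("A", "E1"), ("B", "E2"), ("C", "E3"), ("D", "E4")),
        bead_radius=r,
        contacts=contacts,
    )
    model, truth = make_bead_complex(spec)
    return model, truth, {("A", "B"): 1000.0, ("B", "C"): 500.0, ("C", "D"): 250.0}


@pytest.fixture
def fig3a_matrix():
    """Homodimer-first toy: B dimerizes, then binds the two free R chains."""
    return InterfaceMatrix.from_pairs(
        ["B1", "B2", "R1", "R2"],
        {
            ("B1", "B2"): 1000.0,
            ("B1", "R1"): 500.0,
            ("B1", "R2"): 500.0,
            ("B2", "R1"): 500.0,
            ("B2", "R2"): 500.0,
        },
    )


def random_matrix(rng: np.random.Generator, n: int, distinct: bool = False) -> InterfaceMatrix:
    ids = [f"C{i}" for i in range(n)]
    if distinct:
        vals = rng.permutation(np.arange(1, n * (n - 1) // 2 + 1, dtype=float) * 10.0)
    else:
        vals = np.round(rng.uniform(0, 1000, n * (n - 1) // 2), 1)
    pairs = {}
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs[(ids[i], ids[j])] = float(vals[k])
            k += 1
    return InterfaceMatrix.from_pairs(ids, pairs)
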