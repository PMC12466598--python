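import numpy as np
import pytest

from wssgblup.pedigree import PedigreeTable, build_pedigree, compute_inbreeding


def random_pedigree(n: int, seed: int, p_founder: float = 0.3) -> PedigreeTable:
    """Random valid pedigree: each animal's parents drawn from earlier animals."""
    rng = np.random.default_rng(seed)
    animals = [f"a{i}" for i in range(n)]
    sires, dams = [], []
    for i in range(n):
        if i < 2 or rng.random() < p_founder:
            sires.append("")
            dams.append("")
        else:
            s, d = rng.choice(i, size=2, replace=False)
            sires.append(f"a{s}")
            dams.append(f"a{d}")
    return compute_inbreeding(build_pedigree(animals, sires, dams))


@pytest.fixture
def trio():
    """Two unrelated founders and their offspring."""
    return compute_inbreeding(build_pedigree(["s", "d", "x"], ["", "", "s"], ["", "", "d"]))


@pytest.fixture
def fullsib_mating():
    """Offspring of two full sibs whose parents are unrelated founders: F = 0.25."""
    return compute_inbreeding(
        build_pedigree(
            ["gs", "gd", "b1", "b2", "inbred"],
            ["", "", "gs", "gs", "b1"],
            ["", "", "gd", "gd", "b2"],
        )
    )
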