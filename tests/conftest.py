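import numpy as np
import pytest

import kinmat as km


@pytest.fixture
def toy_pedigree():
    """Founders 1,2; full sibs 3,4 = (1,2); 5 = (3,4) is inbred (F=0.25)."""
    recs = [
        km.PedigreeRecord("1"),
        km.PedigreeRecord("2"),
        km.PedigreeRecord("3", "1", "2"),
        km.PedigreeRecord("4", "1", "2"),
        km.PedigreeRecord("5", "3", "4"),
    ]
    ped, issues = km.sort_pedigree(recs)
    assert ped is not None
    return ped


@pytest.fixture
def sim_pedigree():
    cfg = km.SimConfig(seed=11, n_founders=12, n_generations=3)
    return km.simulate_pedigree(cfg)


@pytest.fixture
def sim_genotypes(sim_pedigree):
    cfg = km.SimConfig(seed=11, n_founders=12, n_generations=3, n_markers=300)
    return km.simulate_genotypes(sim_pedigree, cfg)


def random_pedigree_records(rng: np.random.Generator, n: int,
                            founder_fraction: float):
    """Raw records for a random acyclic pedigree (parents precede offspring),
    built directly so the pedigree oracle tests do not lean on the package's
    own simulator."""
    n_f = max(2, int(n * founder_fraction))
    recs = []
    sex = {}
    for i in range(n):
        label = str(i + 1)
        if i < n_f:
            recs.append(km.PedigreeRecord(label))
            sex[label] = "male" if i % 2 == 0 else "female"
            continue
        males = [l for l, s in sex.items() if s == "male"]
        females = [l for l, s in sex.items() if s == "female"]
        sire = str(rng.choice(males)) if males and rng.random() < 0.9 else None
        dam = str(rng.choice(females)) if females and rng.random() < 0.9 else None
        recs.append(km.PedigreeRecord(label, sire, dam))
        sex[label] = "male" if rng.random() < 0.5 else "female"
    return recs
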