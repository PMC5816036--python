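import numpy as np
import pandas as pd
import pytest

import camtraits as ct


@pytest.fixture(scope="session")
def design5():
    """Full factorial design, 5 replicates per cell (30 samples)."""
    return ct.factorial_design(5)


@pytest.fixture(scope="session")
def small_universe_map():
    """One 10-KO pathway inside a 500-KO universe."""
    kos = [f"K{i:05d}" for i in range(500)]
    return ct.PathwayMap({"p0": frozenset(kos[:10])}, frozenset(kos))


@pytest.fixture()
def two_group_table():
    """Deterministic 10-sample table where treatment counts double baseline."""
    rng = np.random.default_rng(0)
    base = rng.poisson(500, size=(5, 20))
    counts = np.vstack([base * 2, base])
    samples = [f"t{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
    design = ct.StudyDesign(
        samples=tuple(samples),
        compartment={s: ("rhizosphere" if s.startswith("t") else "bulk") for s in samples},
        cd_dose={s: (100 if s.startswith("t") else 0) for s in samples},
    )
    table = ct.KOCountTable(
        pd.DataFrame(counts, index=samples, columns=[f"K{j:05d}" for j in range(20)]),
        design,
    )
    comparison = ct.PairwiseComparison.from_design(design, ("rhizosphere", 100))
    return table, comparison
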