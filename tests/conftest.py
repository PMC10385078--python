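import numpy as np
import pandas as pd
import pytest

import amplimock as am


@pytest.fixture(scope="session")
def mock_species():
    return am.default_mock_species(seed=0)


@pytest.fixture(scope="session")
def small_env():
    """A reduced environmental dataset for unit tests (fast to regenerate)."""
    design = am.EnvDesign(core_size=20, zone_size=12, island_size=8,
                          reads_per_sample=20_000, n_ref_taxa=40, seed=11)
    counts, seqs, meta, truth = am.generate_env_dataset(design)
    return {"design": design, "counts": counts, "seqs": seqs, "meta": meta, "truth": truth}


@pytest.fixture(scope="session")
def ref_db():
    return am.generate_reference_db(20, 130, seed=5)


@pytest.fixture()
def toy_counts():
    df = pd.DataFrame(
        [[900, 50], [90, 800], [10, 150]],
        index=["asv1", "asv2", "asv3"], columns=["s1", "s2"],
    ).T
    return am.CountMatrix(df)


def write_lines(path, text):
    path.write_text(text)
    return str(path)
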