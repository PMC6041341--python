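import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ortholoss.family_matrix import GeneCountMatrix

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

SPECIES9 = ("Atha", "Inil", "Stub", "Slyc", "Cann", "Ccan", "Mgut", "Caus", "Ugib")
PANEL6 = ("Inil", "Stub", "Slyc", "Cann", "Ccan", "Mgut")


def make_matrix(rows: dict[str, list[int]], species=None) -> GeneCountMatrix:
    """Build a count matrix from {orthogroup: counts} in insertion order."""
    species = list(species) if species is not None else [
        f"sp{i}" for i in range(len(next(iter(rows.values()))))
    ]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    return GeneCountMatrix(frame)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_counts_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "Orthogroup\tspA\tspB\n"
        "OG1\t1\t2\n"
        "OG2\t0\t3\n"
        "OG3\t4\t0\n"
    )
    return path
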