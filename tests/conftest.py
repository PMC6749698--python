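import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20190917)


def random_peptide_rows(rng, max_proteins=10, max_peptides=6, n_replicates=3):
    """A random small peptide table as a list of row dicts."""
    n_proteins = int(rng.integers(1, max_proteins + 1))
    rows = []
    for p in range(n_proteins):
        n_pep = int(rng.integers(1, max_peptides + 1))
        for q in range(n_pep):
            modified = bool(rng.random() < 0.1)
            for r in range(n_replicates):
                if rng.random() < 0.15:
                    continue  # missing
                rows.append(
                    {
                        "protein_id": f"P{p}",
                        "peptide_seq": f"PEP{p}X{q}K",
                        "is_modified": modified,
                        "strain_id": "A",
                        "replicate_id": f"rep{r + 1}",
                        "intensity": float(rng.lognormal(3.0, 1.0)),
                    }
                )
    return rows
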