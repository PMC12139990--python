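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

from drugsig.model import (  # noqa: E402
    BindingSitePrediction,
    Compound,
    Fingerprint,
    IndicationMapping,
    Protein,
)


def random_fingerprint(rng: np.random.Generator, width: int = 32,
                       density: float = 0.3) -> Fingerprint:
    return Fingerprint(frozenset(int(i) for i in np.flatnonzero(rng.random(width) < density)),
                       width)


def random_library(rng: np.random.Generator, n_compounds=None, n_proteins=None,
                   width: int = 32):
    """A small random compound/protein library for oracle cross-checks.

    Includes occasional unscoreable compounds and prediction-free proteins
    so degenerate paths are exercised too.
    """
    n = n_compounds or int(rng.integers(8, 25))
    m = n_proteins or int(rng.integers(3, 11))
    compounds = []
    for i in range(n):
        fp = None if rng.random() < 0.05 else random_fingerprint(rng, width)
        compounds.append(Compound(id=f"C{i:03d}", name=f"c{i}", fingerprint=fp,
                                  approved=bool(rng.random() < 0.3),
                                  heavy_atoms=int(rng.integers(1, 40))))
    proteins = []
    for j in range(m):
        prot = Protein(id=f"P{j:03d}", name=f"p{j}")
        for s in range(int(rng.integers(0, 4))):
            prot.predictions.append(BindingSitePrediction(
                protein_id=prot.id, site_id=f"S{s}",
                ligand_fingerprint=random_fingerprint(rng, width),
                confidence=float(rng.uniform(0, 1))))
        proteins.append(prot)
    return compounds, proteins


def random_indication(rng: np.random.Generator, compounds, n_drugs=None,
                      ind_id: str = "IND") -> IndicationMapping:
    n_drugs = n_drugs or int(rng.integers(2, min(5, len(compounds)) + 1))
    picks = rng.choice(len(compounds), size=n_drugs, replace=False)
    return IndicationMapping(ind_id, "test indication",
                             frozenset(compounds[int(i)].id for i in picks))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
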