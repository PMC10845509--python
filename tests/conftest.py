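import numpy as np
import pytest

from dtiagg import (DTIDataset, InteractionTriplet, SyntheticSpec,
                    generate_dataset)
from dtiagg.featurization import CompoundRecord, ProteinRecord


@pytest.fixture(scope="session")
def tiny_dataset() -> DTIDataset:
    """A 3-compound x 3-protein dataset with 7 observed pairs."""
    compounds = [CompoundRecord("c0", "CCO"), CompoundRecord("c1", "CCN"),
                 CompoundRecord("c2", "C1CCCC1")]
    proteins = [ProteinRecord("p0", "MKVLA"), ProteinRecord("p1", "ACDEFGH"),
                ProteinRecord("p2", "WYWYWY")]
    pairs = [("c0", "p0", 1.0), ("c0", "p1", 2.0), ("c1", "p0", 3.0),
             ("c1", "p2", 4.0), ("c2", "p1", 5.0), ("c2", "p2", 6.0),
             ("c0", "p2", 7.0)]
    triplets = [InteractionTriplet(c, p, y) for c, p, y in pairs]
    return DTIDataset(compounds, proteins, triplets, name="tiny")


@pytest.fixture(scope="session")
def synthetic_rank1():
    """Noiseless rank-1 synthetic dataset (dense)."""
    spec = SyntheticSpec(n_compounds=20, n_proteins=10, rank=1,
                         noise_sd=0.0, density=1.0, seed=11)
    return generate_dataset(spec)
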