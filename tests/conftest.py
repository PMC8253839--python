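import numpy as np
import pytest

from scenesem.responses import FoldDesign
from scenesem.semspace import EmbeddingTable
from scenesem.synth import default_fold_design


@pytest.fixture(scope="session")
def folds81() -> FoldDesign:
    """The reference 9-fold design over 81 synthetic categories."""
    return default_fold_design()


@pytest.fixture(scope="session")
def embedding81(folds81) -> EmbeddingTable:
    """A fixed random 8-dimensional embedding over the 81 categories."""
    rng = np.random.default_rng(81)
    return EmbeddingTable(folds81.categories, rng.normal(size=(81, 8)))
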