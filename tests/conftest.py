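import numpy as np
import pytest

from peprank.encoding import EncodingScheme
from peprank.models import FeatureCache, ModelConfig, init_state
from peprank.preprocessing import consolidate_entries
from peprank.simulate import anchor_recovery_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """300-peptide clean synthetic allele with planted anchors."""
    entries_raw, truth, allele = anchor_recovery_dataset(300, seed=7)
    entries, _ = consolidate_entries(entries_raw)
    return entries, truth, allele


@pytest.fixture(scope="session")
def anchor2000():
    """Full-scale anchor study dataset (2000 peptides)."""
    entries_raw, truth, allele = anchor_recovery_dataset(2000, seed=7)
    entries, _ = consolidate_entries(entries_raw)
    return entries, truth, allele


@pytest.fixture(scope="session")
def feature_cache():
    return FeatureCache()


def make_state(arch="convm", k=1, scheme="blosum", loss_id="hv", seed=0, **kw):
    cfg = ModelConfig(
        architecture=arch,
        k=k,
        scheme=EncodingScheme.parse(scheme),
        loss_id=loss_id,
        **kw,
    )
    return init_state(cfg, np.random.default_rng(seed))


@pytest.fixture
def random_peptides():
    rng = np.random.default_rng(42)
    from peprank.preprocessing import AMINO_ACIDS

    def _make(n, lengths=(8, 9, 10, 11, 12, 13, 14, 15)):
        return [
            "".join(rng.choice(list(AMINO_ACIDS), size=rng.choice(lengths)))
            for _ in range(n)
        ]

    return _make
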