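import numpy as np
import pandas as pd
import pytest

from declinescan import GenotypeMatrix


def build_gm(gt, positions=None, scaffold="s1", samples=None, ref="A", alt="T",
             qual=60.0, mq=60.0, ad=None, scaffolds=None, ancestral=None):
    """Compact GenotypeMatrix builder for tests.

    ``gt`` is (n_sites, n_samples); ``ad`` an optional (ref, alt) pair of
    same-shape depth arrays.
    """
    gt = np.asarray(gt, np.int8)
    n_sites, n_samples = gt.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    if samples is None:
        samples = [f"i{k}" for k in range(n_samples)]
    sites = pd.DataFrame({
        "scaffold": scaffolds if scaffolds is not None else [scaffold] * n_sites,
        "pos": np.asarray(positions, int),
        "ref": ref, "alt": alt,
        "qual": np.broadcast_to(np.asarray(qual, float), (n_sites,)).copy(),
        "mq": np.broadcast_to(np.asarray(mq, float), (n_sites,)).copy(),
    })
    if ancestral is not None:
        sites["ancestral"] = ancestral
    ad_ref, ad_alt = (None, None) if ad is None else (np.asarray(ad[0]), np.asarray(ad[1]))
    return GenotypeMatrix(list(samples), sites, gt, ad_ref, ad_alt)


@pytest.fixture
def gm_builder():
    return build_gm
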