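import numpy as np
import pytest

from clonotrace.calling import call_genuine
from clonotrace.reads import FLANKS, count_merged
from clonotrace.simulate import random_barcodes, simulate_merged_reads


def run_mixture_pipeline(weights, n_reads, seed, error_rate=1e-3, n_clones=None):
    """Simulate merged amplicons -> extract -> cluster -> knee-point call.

    ``weights``: relative clone abundances (one per clone).  Returns
    (call result, list of true barcodes) so callers can check which true
    clones were called genuine.
    """
    rng = np.random.default_rng(seed)
    barcodes = random_barcodes(len(weights), 15, rng)
    fractions = dict(zip(barcodes, weights))
    seqs = simulate_merged_reads(
        fractions, n_reads, FLANKS["M1"], error_rate=error_rate, seed=seed
    )
    table, _ = count_merged(seqs.items(), FLANKS["M1"])
    return call_genuine(table), barcodes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
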