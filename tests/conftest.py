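import numpy as np
import pytest

from csrscope import synthetic_locus, simulate_sample
from csrscope.pipeline import run_sample


@pytest.fixture(scope="session")
def locus():
    return synthetic_locus()


@pytest.fixture(scope="session")
def primers(locus):
    return {"FW": locus.fw_primer,
            **{f"RV_{k}": v for k, v in locus.rv_primers.items()}}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def clean_sample(locus):
    """Zero-noise sample: 15 clones, 20 copies each (fixed)."""
    from csrscope.simulate import make_clone_table, sample_clones, simulate_reads
    rng = np.random.default_rng(11)
    table = make_clone_table(locus, 15, rng, min_separation=100)
    templates = sample_clones(table, 15, 11)
    records, truth = simulate_reads(templates, 20, "fixed", "clean",
                                    locus.genome, 11)
    return records, truth, templates


@pytest.fixture(scope="session")
def noisy_result(locus, primers):
    """Full pipeline result on a small noisy sample (shared across tests)."""
    records, truth, templates = simulate_sample(locus, 25, 600,
                                                "nanopore-like", seed=21)
    result = run_sample(records, None, locus.genome, locus.annotation,
                        truth=truth, primers=primers, seed=21)
    return result, templates
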