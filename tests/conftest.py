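import numpy as np
import pytest

from primeforest.motif_scoring import BackgroundModel
from primeforest.seqdata import GenomeStore, Pwm
from primeforest.synthetic_data import BenchmarkConfig, make_benchmark


@pytest.fixture(scope="session")
def uniform_bg() -> BackgroundModel:
    return BackgroundModel.uniform()


@pytest.fixture(scope="session")
def a_rich_pwm() -> Pwm:
    """Strongly A-preferring 5-column PWM (consensus AAAAA)."""
    probs = np.full((5, 4), 0.01)
    probs[:, 0] = 0.97
    return Pwm.from_probs("a_rich", probs)


@pytest.fixture(scope="session")
def small_genome() -> GenomeStore:
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5000))
    return GenomeStore({"chr1": seq, "chr2": seq[:2000]})


@pytest.fixture(scope="session")
def tiny_benchmark():
    """A small homotypic benchmark shared by the unit tests."""
    config = BenchmarkConfig(
        seed=5,
        genome_length=400_000,
        n_positives=30,
        n_gain_variants=8,
        n_loss_variants=8,
        n_neutral_variants=10,
        n_distractors_per_class=20,
        n_background_decoys=800,
        n_tracks=3,
    )
    return make_benchmark(config)
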