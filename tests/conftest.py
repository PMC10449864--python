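import numpy as np
import pytest

from ystrkit.simulate import SimConfig, make_pedigree, simulate_study


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def clean_study():
    """Noise-free simulated study: 12 loci, 4 males, 2 females, 20X."""
    cfg = SimConfig(
        seed=11, chrom_len=35_000, n_loci=12, n_males=4, n_females=2,
        coverage=20, read_len=250, min_spacing=260,
        p_stutter=0.0, p_flank_indel=0.0, base_error=0.0,
    )
    return cfg, *simulate_study(cfg)


@pytest.fixture(scope="session")
def noisy_study():
    """Default-noise study with a three-generation pedigree."""
    cfg = SimConfig(seed=23, chrom_len=35_000, n_loci=12, n_males=6, n_females=3, coverage=15)
    ped = make_pedigree(6, n_founders=2, generations=3, seed=23)
    return cfg, *simulate_study(cfg, ped)
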