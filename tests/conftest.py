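import numpy as np
import pytest

from vocalgwas.simulate import (
    CohortSpec,
    VoiceSpec,
    formant_targets,
    simulate_cohort,
    synth_vowel,
)


@pytest.fixture(scope="session")
def male_vowel_120():
    """1 s male [a]-like vowel at a constant 120 Hz, 44.1 kHz."""
    spec = VoiceSpec(f0=120.0, formants=formant_targets("a"), duration=1.0,
                     sample_rate=44100.0, seed=1)
    return synth_vowel(spec)


@pytest.fixture(scope="session")
def sibpair_cohort():
    """400-speaker sib-pair cohort with the study's planted effect."""
    spec = CohortSpec(n_speakers=400, n_variants=50, causal_effect_hz=2.1,
                      causal_af=0.48, pedigree="sibpairs", seed=3)
    return simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
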