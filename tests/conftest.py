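"""Shared fixtures: small, fast synthetic inputs with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from musclephys import (ECDProtocolParams, RunConfig, SectionParams,
                        TetanusParams, TwitchParams, generate_section,
                        reporting_composition, simulate_ecd_protocol,
                        simulate_tetanus, simulate_twitch)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def clean_twitch():
    return simulate_twitch(TwitchParams(noise_sd_Nm=0.0))


@pytest.fixture
def noisy_twitch():
    return simulate_twitch(TwitchParams(noise_sd_Nm=0.01, seed=7))


@pytest.fixture
def clean_tetanus():
    return simulate_tetanus(TetanusParams(noise_sd_Nm=0.0))


@pytest.fixture
def noisy_tetanus():
    return simulate_tetanus(TetanusParams(noise_sd_Nm=0.01, seed=7))


@pytest.fixture
def ecd_protocol():
    """Noise-free default protocol (r_inf 0.8, kappa 5) -> (traces, scales)."""
    return simulate_ecd_protocol(ECDProtocolParams(seed=11))


@pytest.fixture
def noisy_ecd_protocol():
    params = ECDProtocolParams(
        tetanus=TetanusParams(stim_duration_s=0.7, noise_sd_Nm=0.02), seed=11)
    return simulate_ecd_protocol(params)


@pytest.fixture(scope="session")
def small_section():
    """512x512 / 50-fibre section with truth (session-scoped: segmentation-heavy)."""
    params = SectionParams(shape=(512, 512), n_fibres=50,
                           composition=reporting_composition(40, 50, 5, 5),
                           seed=21)
    return generate_section(params)


@pytest.fixture
def qpcr_table():
    rows = []
    rng = np.random.default_rng(5)
    cq = {"HPRT1": 24.0, "RPL13A": 22.0, "SDHA": 25.0,
          "MYH7": 20.0, "MYH2": 19.0, "MYH1": 21.0, "MYH4": 30.0,
          "MYH3": 27.0, "MYH8": 28.0}
    for sample, genotype in (("D1", "WT"), ("D2", "DE50-MD")):
        for gene, base in cq.items():
            for rep in (1, 2, 3):
                rows.append(dict(sample_id=sample, genotype=genotype, gene=gene,
                                 Cq=base + rng.normal(0, 0.05), replicate=rep))
    return pd.DataFrame(rows)
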