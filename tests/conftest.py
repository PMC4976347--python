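import numpy as np
import pytest

from svimon import (
    EpisodeConfig,
    MonitorConfig,
    generate_episode,
    monitor_run,
)


@pytest.fixture(scope="session")
def episode42():
    """The default bulking episode used throughout the suite."""
    return generate_episode(EpisodeConfig(seed=42))


@pytest.fixture(scope="session")
def monitor42(episode42):
    """Monitoring replay of the default episode under default settings."""
    return monitor_run(episode42.series, MonitorConfig(seed=42))


@pytest.fixture(scope="session")
def quiescent_series():
    """A record that never approaches the pre-caution band (SVI ~ 100)."""
    cfg = EpisodeConfig(n_total=120, onset_index=119,
                        wander_amplitudes=(8.0, 4.0), seed=3)
    return generate_episode(cfg).series.slice(0, 110)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
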