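import numpy as np
import pytest

import plethykit as pk


@pytest.fixture(scope="session")
def adult_protocol():
    return pk.build_protocol("adult", "hypoxia")


@pytest.fixture(scope="session")
def quiet_profile():
    """No events, no variability: every cycle exactly the mean."""
    return pk.GenotypeProfile(label="quiet", cycle_cv=0.0, tv_cv=0.0,
                              apnea_rate_per_h=0.0, sigh_rate_per_h=0.0,
                              post_sigh_apnea_prob=0.0)


@pytest.fixture(scope="session")
def busy_profile():
    """Event-rich phenotype for recovery tests."""
    return pk.cko_profile()


@pytest.fixture(scope="session")
def short_sequence(busy_profile):
    """10 min of breathing with planted sighs and apneas (seed-fixed)."""
    return pk.simulate_breath_sequence(busy_profile, 600.0, seed=11)


def regular_table(n=20, cycle=0.3, tv=0.15, ti_frac=0.4):
    """Hand-built perfectly regular breath table."""
    cycles = np.full(n, cycle)
    onsets = np.concatenate([[0.0], np.cumsum(cycles)[:-1]])
    ti = ti_frac * cycles
    te = cycles - ti
    pif = np.pi * tv / (2 * ti)
    from plethykit.trace import make_breath_table
    return make_breath_table(onsets, ti, te, cycles, np.full(n, tv),
                             np.full(n, tv), pif, pif)
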