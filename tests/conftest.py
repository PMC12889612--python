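"""Shared fixtures: simulated sessions and their full analyses.

Sessions are simulated at 1 kHz ephys (test mode) so the whole suite runs in
minutes; every algorithm takes the sampling rate as a parameter.
"""

import numpy as np
import pytest

import swimstate as ss
from swimstate.pipeline import analyze_session


@pytest.fixture(scope="session")
def default_session():
    """One 20-trial session at generator defaults."""
    return ss.simulate_session(ss.ParadigmConfig(n_trials=20), seed=7,
                               fs_ephys=1000)


@pytest.fixture(scope="session")
def default_analysis(default_session):
    return analyze_session(default_session, seed=7)


@pytest.fixture(scope="session")
def fish_cohort():
    """Five simulated fish at defaults (the across-fish test bed)."""
    sessions = [ss.simulate_session(ss.ParadigmConfig(n_trials=20), seed=100 + k,
                                    fs_ephys=1000) for k in range(5)]
    analyses = [analyze_session(s, seed=100 + k, fish_id=k)
                for k, s in enumerate(sessions)]
    return sessions, analyses


@pytest.fixture(scope="session")
def calex_cohort():
    sessions, analyses = [], []
    for k in range(5):
        sp = ss.StateParams(mode="calex")
        pop = ss.PopulationConfig(mode="calex")
        s = ss.simulate_session(ss.ParadigmConfig(n_trials=20), sp, pop,
                                seed=200 + k, fs_ephys=1000)
        sessions.append(s)
        analyses.append(analyze_session(s, seed=200 + k, fish_id=k))
    return sessions, analyses


def bout_match_stats(detected, truth, tol=0.15):
    """(recall, precision) of detected bout onsets against ground truth."""
    d_on = np.array([b.onset for b in detected])
    t_on = np.array([b.onset for b in truth])
    if t_on.size == 0:
        return 1.0, 1.0
    if d_on.size == 0:
        return 0.0, 1.0
    recall = np.mean([np.min(np.abs(d_on - t)) <= tol for t in t_on])
    precision = np.mean([np.min(np.abs(t_on - d)) <= tol for d in d_on])
    return float(recall), float(precision)
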