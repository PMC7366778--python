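"""Shared fixtures: synthetic sessions and trained models, generated once.

Everything is produced programmatically at test time from fixed seeds; the
expensive 64-channel sessions and fitted models are session-scoped so each
is built exactly once per run.
"""

import numpy as np
import pytest

from p300bci.paradigm import TRAINING_TIMING, SpellerGrid
from p300bci.pipeline import fit_session
from p300bci.synthdata import SynthConfig, synthesize_session


def pick_targets(grid: SpellerGrid, n: int, seed: int) -> tuple:
    rng = np.random.default_rng(seed)
    return tuple(rng.choice(list(grid.characters), size=n))


@pytest.fixture(scope="session")
def grid() -> SpellerGrid:
    return SpellerGrid()


@pytest.fixture(scope="session")
def train_session(grid):
    """15-character training session at the default simulation conditions."""
    targets = pick_targets(grid, 15, seed=7)
    rec, sched, truth = synthesize_session(
        grid, targets, TRAINING_TIMING, SynthConfig(seed=11)
    )
    return rec, sched, truth


@pytest.fixture(scope="session")
def trained_lda(train_session):
    """xDAWN + LDA detector fitted on the training session, with CV report."""
    rec, _, _ = train_session
    return fit_session(rec, clf="lda", seed=0)


@pytest.fixture(scope="session")
def test_session(grid):
    """Held-out 10-character session at the same conditions, fresh seed."""
    targets = pick_targets(grid, 10, seed=8)
    rec, sched, truth = synthesize_session(
        grid, targets, TRAINING_TIMING, SynthConfig(seed=22)
    )
    return rec, sched, truth


@pytest.fixture(scope="session")
def small_session(grid):
    """Cheap 3-character, 8-channel session for plumbing tests."""
    targets = ("A", "K", "5")
    cfg = SynthConfig(n_channels=8, seed=33)
    rec, sched, truth = synthesize_session(grid, targets, TRAINING_TIMING, cfg)
    return rec, sched, truth
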