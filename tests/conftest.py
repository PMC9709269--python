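"""Shared fixtures.

The session-scoped smoke cohort (25 runs x 10,000 items at package defaults)
backs every cohort-level acceptance test; it is computed once per session.
"""

from __future__ import annotations

import pytest

from refbias import CorpusConfig, EngineConfig, run_cohort
from refbias.experiment import trials_frame
from refbias.model import build_lexicon, build_operators

# Fixed before any smoke-cohort outcome was observed; never tuned.
SMOKE_CORPUS_SEED = 5
SMOKE_MASTER_SEED = 20
SMOKE_N_RUNS = 25


@pytest.fixture(scope="session")
def operators():
    ops = build_operators()
    return {op.name: op for op in ops}


@pytest.fixture(scope="session")
def operator_list():
    return build_operators()


@pytest.fixture(scope="session")
def tiny_lexicon():
    return build_lexicon(verbs=["fascinated", "comforted"],
                         names=["leah", "kathy", "mara"])


@pytest.fixture(scope="session")
def smoke_cohort():
    corpus_cfg = CorpusConfig(seed=SMOKE_CORPUS_SEED)
    model_cfg = EngineConfig()  # package defaults
    return run_cohort(SMOKE_N_RUNS, corpus_cfg, model_cfg,
                      master_seed=SMOKE_MASTER_SEED)


@pytest.fixture(scope="session")
def smoke_trials(smoke_cohort):
    return trials_frame(smoke_cohort)
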