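from __future__ import annotations

import pytest

from fmscreen import pipeline as pl

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def paper_fixture():
    """The planted study-shaped dataset, built once per session."""
    return pl.make_paper_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def paper_report(paper_fixture):
    """Full pipeline report computed from the session fixture."""
    return pl.run_pipeline(pl.RunConfig(seed=FIXTURE_SEED), fixture=paper_fixture)
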