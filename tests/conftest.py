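"""Shared fixtures.

The two expensive artifacts — the planted-regime XAI table and the full
desk-scale pipeline run (training included) — are built once per session
and shared across module and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from lesionfocus.pipeline import PipelineConfig, run_pipeline
from lesionfocus.synthetic import make_regime_cases
from lesionfocus.xai import build_xai_table


@pytest.fixture(scope="session")
def regime_data():
    """300 planted-regime attribution cases (100 per regime) + XAI table."""
    cases, planted = make_regime_cases(100, image_size=(64, 64), seed=11)
    table = build_xai_table(cases)
    table = table.assign(planted=planted)
    return cases, table


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full desk-scale pipeline run: 2 eyes x 20 slices at 64x64,
    reduced 5-epoch training, explanation, XAI metrics and regimes."""
    out = tmp_path_factory.mktemp("pipeline")
    manifest = run_pipeline(PipelineConfig(seed=42), out_dir=out)
    return manifest, out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
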