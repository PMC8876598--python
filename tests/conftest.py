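"""Shared fixtures: synthetic libraries and one full pipeline run.

Library generation and the pipeline run are session-scoped because
annotation (ORFs x references Smith-Waterman) dominates runtime.
"""

from __future__ import annotations

import pathlib

import pytest

from venomkit import pipeline, synthetic

HP1_MATURE = "ADSGGDAGGDAGADDEGSCKWMFQSCEPPAKCCDGWTCYKGRCNLIL"
HP2_MATURE = "DDDKKECIGHMGWCAWTDGECCEGYRCKLWCRKIIDWL"


@pytest.fixture(scope="session")
def noisy_bundle() -> synthetic.LibraryBundle:
    """Default study conditions at reduced library size."""
    cfg = synthetic.GeneratorConfig(seed=11, n_transcripts=300)
    return synthetic.generate_library(cfg)


@pytest.fixture(scope="session")
def clean_bundle() -> synthetic.LibraryBundle:
    """Zero mutation and fragmentation rates: exact-recovery conditions."""
    cfg = synthetic.GeneratorConfig(
        seed=5, n_transcripts=220, point_mutation_rate=0.0,
        cys_loss_rate=0.0, stop_gain_rate=0.0, stop_readthrough_rate=0.0,
        fragmentation_prob=0.0)
    return synthetic.generate_library(cfg)


@pytest.fixture(scope="session")
def noisy_run(noisy_bundle, tmp_path_factory) -> tuple[dict, pathlib.Path]:
    out = tmp_path_factory.mktemp("noisy_run")
    cfg = pipeline.RunConfig(out_dir=str(out))
    summary = pipeline.run_pipeline(cfg, ests=noisy_bundle.records,
                                    refs=noisy_bundle.references,
                                    peaklists=noisy_bundle.peaklists)
    return summary, out


@pytest.fixture(scope="session")
def clean_run(clean_bundle, tmp_path_factory) -> tuple[dict, pathlib.Path]:
    out = tmp_path_factory.mktemp("clean_run")
    cfg = pipeline.RunConfig(out_dir=str(out))
    summary = pipeline.run_pipeline(cfg, ests=clean_bundle.records,
                                    refs=clean_bundle.references)
    return summary, out
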