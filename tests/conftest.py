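"""Shared fixtures: small synthetic samples that exercise every stage quickly."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from spatialimc import (
    ImmunotypeModel,
    PipelineConfig,
    scenario_preset,
    simulate_tissue,
)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact enriched-immunotype sample: 2 ROIs of 0.25 mm²."""
    return scenario_preset("enriched", seed=42, n_rois=2, roi_size_um=500)


@pytest.fixture(scope="session")
def small_sample(small_scenario):
    """(stacks, masks, ground_truth) for the small scenario."""
    return simulate_tissue(small_scenario)


@pytest.fixture(scope="session")
def small_results(small_scenario, small_sample):
    """Fitted pipeline results on the small sample."""
    stacks, masks, gt = small_sample
    model = ImmunotypeModel(
        stacks,
        masks,
        panel=small_scenario.panel,
        spillover=gt.spillover_matrix,
        config=PipelineConfig(seed=small_scenario.seed, sample_id="small"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
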