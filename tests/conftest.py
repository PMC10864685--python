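"""Shared fixtures: small synthetic scale patterns and feature sets."""

import numpy as np
import pytest

from beaverid.sift import SIFTConfig, extract_features
from beaverid.synthetic import PatternSpec, TransformParams, make_pattern, render_view


#: Small canvas with the same cell spacing (~25 px) as the full-size
#: benchmark after its resize to working resolution; keeps tests fast.
SMALL_CANVAS = (320, 240)
SMALL_CELLS = 120


def small_spec(seed: int, **overrides) -> PatternSpec:
    kw = dict(individual_seed=seed, canvas=SMALL_CANVAS, n_cells=SMALL_CELLS,
              boundary_width=2.5)
    kw.update(overrides)
    return PatternSpec(**kw)


@pytest.fixture(scope="session")
def pattern_small():
    """One deterministic small scale-pattern image (320 x 240)."""
    return make_pattern(small_spec(1))


@pytest.fixture(scope="session")
def pattern_small_other():
    """A different individual's pattern on the same canvas."""
    return make_pattern(small_spec(2))


@pytest.fixture(scope="session")
def features_small(pattern_small):
    """Features of the small pattern under the default configuration."""
    return extract_features(pattern_small, SIFTConfig(), image_id="p1")


def render(pattern, seed=0, **transform):
    return render_view(pattern, TransformParams(**transform), view_seed=seed)
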