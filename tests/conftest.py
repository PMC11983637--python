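import hypothesis
import pandas as pd
import pytest

import circogram as cg

hypothesis.settings.register_profile(
    "det", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("det")


@pytest.fixture(scope="session")
def genome():
    """Small seeded synthetic genome shared across tests."""
    return cg.generate_random_genome(n_chrom=3, mean_length=1_000_000, seed=11)


@pytest.fixture()
def track_with_data():
    """Track over two sectors with known per-sector (x, y) data."""
    df = pd.DataFrame({
        "category": ["a", "a", "a", "b", "b"],
        "x": [1.0, 2.0, 3.0, 0.5, 1.5],
        "y": [4.0, 5.0, 6.0, 0.1, 0.2],
    })
    return cg.make_track(df, ylim=(0.0, 10.0))


@pytest.fixture()
def simple_plot(track_with_data):
    """Two-sector generic plot with one data track."""
    plot = cg.make_plot("initialize", {
        "categories": ["a", "b"],
        "xlims": [(0.0, 4.0), (0.0, 2.0)],
    })
    return plot + track_with_data
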