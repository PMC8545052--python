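import datetime as dt

import pytest

from mythcast import SynthConfig, load_catalog, synthesize_corpus


@pytest.fixture(scope="session")
def catalog():
    return load_catalog("default")


@pytest.fixture(scope="session")
def small_corpus(catalog):
    """A small single-category synthetic corpus with ground truth."""
    config = SynthConfig(
        N=600, beta=0.5, gamma=0.25, T=60, i0=5, seed=42, category="Prevent"
    )
    records, emotions, truth = synthesize_corpus(config, catalog)
    return config, records, emotions, truth


@pytest.fixture(scope="session")
def labeled_small(small_corpus, catalog):
    from mythcast import label_tweets, window_filter

    _, records, _, _ = small_corpus
    start = dt.date(2020, 1, 1)
    end = start + dt.timedelta(days=59)
    return label_tweets(window_filter(records, start, end), catalog)
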