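import pytest

from pericompart.io_formats import GeneMapEntry
from pericompart.synthetic_data import SimConfig, simulate_genome_map, truth_labels


def make_map(segment_rates, chromosome="1H", spacing=10_000):
    """Deterministic gene map from (rate cM/gene, n genes) segments."""
    entries = []
    cm = 0.0
    i = 0
    for rate, n in segment_rates:
        for _ in range(n):
            entries.append(GeneMapEntry(f"{chromosome}g{i:05d}", chromosome,
                                        cm, (i + 1) * spacing))
            cm += rate
            i += 1
    return entries


@pytest.fixture(scope="session")
def three_segment_map():
    """1.0 / 0.01 / 1.0 cM-per-gene segments of 300 + 400 + 300 genes."""
    return make_map([(1.0, 300), (0.01, 400), (1.0, 300)])


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic genome (map, planted truth, centromeres, labels)."""
    config = SimConfig(seed=11)
    entries, truth, centromeres = simulate_genome_map(config)
    labels = truth_labels(entries, truth)
    return config, entries, truth, centromeres, labels
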