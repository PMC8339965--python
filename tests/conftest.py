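import pytest

from elscore.corpus_io import NormBandRow, NormTable
from elscore.norms import NormConfig, make_default_norm_table
from elscore.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_config():
    """Small corpus: 12 children x 8 items per subtest."""
    return GeneratorConfig(
        seed=7,
        n_children=12,
        items_per_subtest={"EV": 8, "WS": 8, "RS": 8, "FS": 8},
    )


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_corpus(small_config)


@pytest.fixture(scope="session")
def default_norm_table():
    """Synthetic norm table from a 5,000-per-band reference population."""
    return make_default_norm_table(1, NormConfig(n_per_band=5_000))


@pytest.fixture
def toy_norm_table():
    """Hand-built single-band table with easily checkable intervals.

    One age band [60, 120) per subtest; ELI is identity-ish around the
    centre (sum 30 -> 100).
    """

    def band(code, cuts):
        rows = []
        lo = 0
        for hi, scaled in cuts:
            rows.append(NormBandRow(60, 120, lo, hi, scaled))
            lo = hi + 1
        return rows

    tables = {
        "EV": band("EV", [(10, 1), (20, 10), (54, 19)]),
        "WS": band("WS", [(10, 1), (20, 10), (32, 19)]),
        "RS": band("RS", [(30, 1), (60, 10), (96, 19)]),
        "FS": band("FS", [(15, 1), (30, 10), (48, 19)]),
    }
    eli = []
    for s in range(3, 58):
        eli.append((s, s, min(155, max(45, 100 + 5 * (s - 30) // 2))))
    table = NormTable(subtest_tables=tables, eli_table=eli)
    table.validate()
    return table
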