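import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")

from jellytroph.datamodel import PreyCountTable  # noqa: E402
from jellytroph.mixing import SourceSpec, TEFSpec  # noqa: E402

# Published Table-1-style May column: per-taxon mean prey per medusa over the
# n = 20 May predators. Every mean times 20 is an integer, so an exact count
# table reproducing these means exists.
MAY_TAXON_MEANS = {
    "siphonophores": 0.0,
    "pteropods": 0.45,
    "ostracods": 0.10,
    "furcilia": 0.05,
    "fish_larvae": 0.0,
    "fish_eggs": 0.80,
    "copepods": 21.95,
    "chaetognaths": 1.35,
    "appendicularians": 0.20,
}
MAY_N_PREDATORS = 20
MAY_PRINTED_TOTAL = 25.0  # printed monthly mean total, +/- 1 prey per medusa


def may_prey_table() -> PreyCountTable:
    """A 20-predator May count table whose per-taxon means equal the printed
    Table-1-style May column (counts distributed round-robin)."""
    taxa = list(MAY_TAXON_MEANS)
    counts = np.zeros((MAY_N_PREDATORS, len(taxa)), dtype=np.int64)
    for j, taxon in enumerate(taxa):
        total = round(MAY_TAXON_MEANS[taxon] * MAY_N_PREDATORS)
        for i in range(total):
            counts[i % MAY_N_PREDATORS, j] += 1
    df = pd.DataFrame(counts, columns=taxa)
    df.insert(0, "month", "May")
    df.insert(0, "predator_id", [f"P{i}" for i in range(MAY_N_PREDATORS)])
    return PreyCountTable(data=df, taxa=tuple(taxa))


@pytest.fixture
def may_table() -> PreyCountTable:
    return may_prey_table()


def triangle_sources() -> list[SourceSpec]:
    from jellytroph.synth import WELL_SEPARATED_SOURCES

    return WELL_SEPARATED_SOURCES


@pytest.fixture
def paper_tef() -> TEFSpec:
    return TEFSpec(mean={"d13C": 2.0, "d15N": 3.2}, sd={"d13C": 0.3, "d15N": 0.1})


@pytest.fixture(scope="session")
def paper_like_bundle(tmp_path_factory):
    """One small paper-like synthetic bundle shared across tests."""
    from jellytroph.synth import gen_paper_like

    out = tmp_path_factory.mktemp("synth")
    tables, truth = gen_paper_like(seed=42, out_dir=out)
    return {"dir": out, "tables": tables, "truth": truth}
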