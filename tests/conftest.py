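import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")


@pytest.fixture(scope="session")
def linea():
    """Bundled C. linea table: (measurements, dataframe with printed cols)."""
    from karyocoi import io

    return io.load_fixture("cobitis_linea")


@pytest.fixture(scope="session")
def toy_alignment():
    """Four 20-mers with hand-countable differences, one species each."""
    from karyocoi import SpeciesAlignment

    taxa = ("t1", "t2", "t3", "t4")
    seqs = (
        "ACGTACGTACGTACGTACGT",
        "ACGTACGTACGTACGTACGC",
        "ACGAACGTACGTACTTACGT",
        "GCGTACGTACGTACGTACGT",
    )
    return SpeciesAlignment(
        taxa=taxa, sequences=seqs, species_map={t: t for t in taxa}
    )
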