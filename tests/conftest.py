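import pandas as pd
import pytest

from bifilter import GenotypeMatrix, SimConfig, simulate_population


@pytest.fixture(scope="session")
def default_sim():
    """Default study-scale simulation: 190 lines, 1000 mono + 400 poly loci,
    11 lines contaminated at 0.5, call error 1.6e-3, 2% missing."""
    return simulate_population(SimConfig(seed=7))


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free small population for exact-recovery checks."""
    config = SimConfig(
        seed=11,
        n_lines=80,
        n_monomorphic=120,
        n_simple=12,
        n_shemi=12,
        n_mhemi=12,
        n_pseudo=12,
        contamination=(),
        call_error_rate=0.0,
        missing_rate=0.0,
    )
    return simulate_population(config)


@pytest.fixture
def tiny_matrix():
    """3 loci x (2 parents + 4 lines), hand-checkable.

    locA: monomorphic AA; DH3 carries an NPG (AB), DH4 is missing.
    locB: polymorphic AA/BB; DH2 carries an NPG (AB).
    locC: polymorphic AA/NC.
    """
    df = pd.DataFrame(
        {
            "P1": ["AA", "AA", "AA"],
            "P2": ["AA", "BB", "NC"],
            "DH1": ["AA", "AA", "AA"],
            "DH2": ["AA", "AB", "NC"],
            "DH3": ["AB", "BB", "AA"],
            "DH4": ["-", "BB", "NC"],
        },
        index=pd.Index(["locA", "locB", "locC"], name="locus_id"),
    )
    return GenotypeMatrix(df, "P1", "P2")
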