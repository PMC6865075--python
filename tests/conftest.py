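import pytest

from phip_kinetics import ConcentrationSeries, Observation

#: Formation rate constants (min^-1) and kelvin temperatures for the
#: phenylalanine system, as reported by the reference analysis.
PHE_PAIRS = [(0.0024, 423.15), (0.0059, 453.15), (0.0710, 483.15)]


def make_series(amino_acid, temperature_C, rows):
    """Build a series from (time, replicate, concentration-or-None) rows."""
    obs = [
        Observation(t, rep, 0.0 if c is None else c, c is not None)
        for t, rep, c in rows
    ]
    return ConcentrationSeries(amino_acid, temperature_C, obs)


@pytest.fixture
def phe_pairs():
    return list(PHE_PAIRS)
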