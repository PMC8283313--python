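import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from necrosip.decompose import AbundanceTables, TAXONOMY_RANKS

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_tables(counts: dict, qpcr: dict, meta: dict, taxonomy: dict | None = None) -> AbundanceTables:
    """Assemble a small AbundanceTables from plain dicts.

    ``counts``: sample -> list of counts; ``meta``: sample -> (day, rep, frac, treat);
    ``taxonomy``: otu -> phylum (other ranks filled with placeholders).
    """
    samples = list(counts)
    n_otu = len(next(iter(counts.values())))
    otus = [f"OTU_{i + 1}" for i in range(n_otu)]
    cdf = pd.DataFrame({s: counts[s] for s in samples}, index=pd.Index(otus, name="otu_id"))
    mdf = pd.DataFrame(
        [dict(zip(("timepoint_day", "replicate", "fraction_class", "treatment"), meta[s]))
         for s in samples],
        index=pd.Index(samples, name="sample_id"),
    )
    q = pd.Series({s: float(qpcr[s]) for s in samples}, name="copies_per_g")
    if taxonomy is None:
        taxonomy = {}
    tax_rows = []
    for o in otus:
        ph = taxonomy.get(o, "Proteobacteria")
        tax_rows.append(dict(zip(TAXONOMY_RANKS, ("Bacteria", ph, "c", "o", "f", f"g_{o}", f"s_{o}"))))
    tdf = pd.DataFrame(tax_rows, index=cdf.index)
    return AbundanceTables(counts=cdf, sample_meta=mdf, qpcr=q, taxonomy=tdf)


@pytest.fixture
def light_meta():
    """Meta builder for light-fraction labeled samples."""
    def build(day, rep):
        return (day, rep, "light", "H2_18O")
    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
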