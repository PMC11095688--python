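import numpy as np
import pandas as pd
import pytest

from edna_assemblage import synthetic as syn
from edna_assemblage.tables import (
    AsvCountTable,
    SampleMetadataTable,
    TaxonomyTable,
)


@pytest.fixture(scope="session")
def separable_ds():
    cfg = syn.preset("separable-3")
    cfg.seed = 7
    return syn.generate(cfg)


@pytest.fixture(scope="session")
def null_ds():
    cfg = syn.preset("null")
    cfg.seed = 11
    return syn.generate(cfg)


@pytest.fixture()
def tiny_taxonomy():
    rows = {
        "a1": {"kingdom": "Animalia", "phylum": "Chordata", "subphylum": "Vertebrata",
               "class": "Actinopteri", "order": "Myctophiformes",
               "family": "Myctophidae", "genus": "Lampa", "species": "Lampa prima"},
        "a2": {"kingdom": "Animalia", "phylum": "Chordata", "subphylum": "Vertebrata",
               "class": "Actinopteri", "order": "Myctophiformes",
               "family": "Myctophidae", "genus": "Lampa", "species": "Lampa prima"},
        "a3": {"kingdom": "Animalia", "phylum": "Chordata", "subphylum": "Vertebrata",
               "class": "Mammalia", "order": "Primates",
               "family": "Hominidae", "genus": "Homo", "species": "Homo sapiens"},
        "a4": {"kingdom": "Animalia", "phylum": "Arthropoda",
               "class": "Copepoda", "order": "Calanoida",
               "family": "Calanidae", "genus": "Calanus", "species": "Calanus alter"},
        "a5": {"kingdom": "Animalia", "phylum": "Chordata"},
    }
    df = pd.DataFrame.from_dict(rows, orient="index").fillna("")
    return TaxonomyTable(lineages=df)


@pytest.fixture()
def tiny_metadata():
    t = pd.Timestamp("2021-11-01T10:00:00Z")
    rows = {
        "s1": dict(cruise="C1", latitude=33.0, longitude=-120.0, depth=70.0,
                   volume=990.0, timestamp=t, is_control=False,
                   below_detection=False, dna_concentration=1.5,
                   sunrise=pd.Timestamp("2021-11-01T06:00:00Z"),
                   sunset=pd.Timestamp("2021-11-01T18:00:00Z")),
        "s2": dict(cruise="C1", latitude=33.1, longitude=-120.2, depth=500.0,
                   volume=500.0, timestamp=t, is_control=False,
                   below_detection=False, dna_concentration=0.4,
                   sunrise=pd.Timestamp("2021-11-01T06:00:00Z"),
                   sunset=pd.Timestamp("2021-11-01T18:00:00Z")),
        "ctl": dict(cruise="C1", latitude=33.0, longitude=-120.0, depth=np.nan,
                    volume=np.nan, timestamp=t, is_control=True,
                    below_detection=True, dna_concentration=np.nan,
                    sunrise=pd.NaT, sunset=pd.NaT),
    }
    return SampleMetadataTable(data=pd.DataFrame.from_dict(rows, orient="index"))


@pytest.fixture()
def tiny_asv(tiny_metadata):
    counts = pd.DataFrame(
        {"s1": [1200, 5, 0, 30, 2], "s2": [0, 900, 250, 0, 1], "ctl": [0, 0, 0, 0, 4]},
        index=["a1", "a2", "a3", "a4", "a5"],
    )
    return AsvCountTable(marker="12S", counts=counts)
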