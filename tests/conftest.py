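import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

from mirheat import CountMatrix, MiRNARecord, SampleDesign
from mirheat.io import assign_groups


@pytest.fixture
def toy_records():
    """Six miRNAs: two named families (one with a shared-sequence pair), one unnamed."""
    recs = [
        MiRNARecord("ghr-miR156a", "UGACAGAAGAGAGUGAGCAC"),
        MiRNARecord("ghr-novel-miR156e-3p", "UGACAGAAGAGAGUGAGCAC"),
        MiRNARecord("ghr-miR172", "AGAAUCUUGAUGAUGCUGCAU"),
        MiRNARecord("ghr-novel-miR172b-5p", "GGAAUCUUGAUGAUGCUGCAG"),
        MiRNARecord("ghr-sRNA-001", "CCCCGGGGAAAAUUUUCCCC"),
        MiRNARecord("ghr-sRNA-002", "ACCCGGGGAAAAUUUUCCCA"),
    ]
    return assign_groups(recs)


@pytest.fixture
def toy_design():
    rows = []
    for i, stage in enumerate(["SCP", "MP", "MRP", "PM"], start=1):
        for genotype, g in (("tolerant", "H"), ("sensitive", "T")):
            for condition, c in (("HT", ""), ("NT", "C")):
                rows.append(
                    {
                        "library_id": f"{g}{c}{i}",
                        "genotype": genotype,
                        "condition": condition,
                        "stage": stage,
                        "replicate": 1,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def toy_counts(toy_records, toy_design):
    rng = np.random.default_rng(42)
    ids = [r.mirna_id for r in toy_records]
    libs = toy_design.library_ids
    counts = pd.DataFrame(
        rng.poisson(200, size=(len(ids), len(libs))), index=ids, columns=libs
    ).astype(np.int64)
    sizes = pd.Series(1_000_000, index=libs)
    return CountMatrix(counts, sizes)
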