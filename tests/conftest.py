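import numpy as np
import pandas as pd
import pytest

from trisomics import simulate_study, run_qc, NegativeBinomialDE


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic trisomy study (fixed default seed)."""
    return simulate_study()


@pytest.fixture(scope="session")
def clean_study():
    """Default study without contaminant/outlier samples (the analyzed 6v6)."""
    return simulate_study(n_contaminant_samples=0, n_outlier_samples=0, seed=101)


@pytest.fixture(scope="session")
def null_study():
    """No planted effects anywhere: everything downstream should be quiet."""
    return simulate_study(dosage_factor=1.0, n_planted_de=0, n_planted_dmrs=0,
                          n_cis_effects=0, n_contaminant_samples=0,
                          n_outlier_samples=0, seed=202)


@pytest.fixture(scope="session")
def qc_report(default_study):
    return run_qc(default_study.counts, default_study.samples,
                  default_study.gene_annotation)


@pytest.fixture(scope="session")
def de_results(clean_study):
    return NegativeBinomialDE.from_study(clean_study).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def planted_dmr_recovery(study, dmr_table):
    """(n_recovered, n_planted): planted DMRs overlapped by a significant call."""
    sig = dmr_table[dmr_table["fdr"] < 0.01]
    truth = study.truth["dmrs"]
    found = 0
    for _, t in truth.iterrows():
        ov = sig[(sig["chrom"] == t["chrom"]) & (sig["start"] <= t["end"])
                 & (sig["end"] >= t["start"])]
        if len(ov):
            found += 1
    return found, len(truth)
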