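import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mucopair as mp

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A reduced study: quick to generate, same structure as the full design."""
    return mp.StudyConfig(n_proteins=40, n_taxa=20, mean_depth=20_000,
                          seed=7)


@pytest.fixture
def small_proteome(small_config):
    matrix, truth = mp.gen_proteome_study(small_config)
    return matrix, truth


@pytest.fixture
def small_microbiome(small_config):
    table, truth = mp.gen_microbiome_study(small_config)
    return table, truth


def make_count_table(counts: np.ndarray, meta_rows: list[dict] | None = None,
                     sample_ids: list[str] | None = None,
                     taxon_ids: list[str] | None = None) -> mp.TaxonCountTable:
    """Build a TaxonCountTable from a raw array with minimal metadata."""
    n_taxa, n_samples = counts.shape
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(n_samples)]
    taxon_ids = taxon_ids or [f"T{i + 1}" for i in range(n_taxa)]
    if meta_rows is None:
        meta_rows = [{"subject_id": f"subj{j + 1}", "arm": "none",
                      "formulation": "none", "timepoint": "baseline",
                      "is_tech_replicate": False}
                     for j in range(n_samples)]
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    return mp.TaxonCountTable(
        pd.DataFrame(counts, index=taxon_ids, columns=sample_ids), meta)
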