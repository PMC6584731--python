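"""Shared fixtures: a small synthetic two-cancer study and handmade cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metasurv import (ClinicalTable, CohortCollection, ExpressionDataset,
                      SyntheticConfig, generate_collection)
from metasurv.cohort import CLINICAL_COLUMNS
from metasurv.curation import collapse_probes

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_dataset(values: np.ndarray, dataset_id: str = "ds0",
                 cancer_type: str = "synthetic-0",
                 gene_names: list[str] | None = None,
                 sample_ids: list[str] | None = None) -> ExpressionDataset:
    """Wrap a plain matrix (genes x samples) as an ExpressionDataset."""
    g, s = values.shape
    genes = gene_names or [f"G{i:03d}" for i in range(g)]
    samples = sample_ids or [f"{dataset_id}-S{i:03d}" for i in range(s)]
    vals = pd.DataFrame(values, index=pd.Index(genes, name="feature_id"),
                        columns=samples)
    feats = pd.DataFrame({"gene_symbol": genes,
                          "entrez_id": np.arange(g) + 1},
                         index=vals.index.rename("probe_id"))
    return ExpressionDataset(dataset_id, cancer_type, vals, feats)


def make_clinical(dataset_id: str, sample_ids: list[str],
                  time: np.ndarray, event: np.ndarray,
                  subtype: list[str] | None = None,
                  sample_type: list[str] | None = None) -> ClinicalTable:
    """Minimal valid clinical table around a survival endpoint."""
    n = len(sample_ids)
    df = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"),
                      columns=[c for c in CLINICAL_COLUMNS if c != "sample_id"],
                      dtype=object)
    df["dataset_id"] = dataset_id
    df["sample_type"] = sample_type or "tumor"
    df["days_to_death"] = np.asarray(time, dtype=float)
    df["vital_status"] = np.where(np.asarray(event) == 1, "deceased", "living")
    if subtype is not None:
        df["subtype"] = subtype
    return ClinicalTable(dataset_id, df)


def survival_dataset(seed: int, n: int = 80, n_genes: int = 40,
                     beta: np.ndarray | None = None,
                     dataset_id: str = "ds0",
                     cancer_type: str = "synthetic-0",
                     ) -> tuple[ExpressionDataset, ClinicalTable]:
    """One cohort with exponential survival driven by optional gene effects."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_genes, n))
    eta = np.zeros(n) if beta is None else beta @ z
    latent = rng.exponential(1000.0 / np.exp(eta))
    cens = rng.uniform(0, 3000.0, n)
    time = np.maximum(np.round(np.minimum(latent, cens)), 1.0)
    event = (latent <= cens).astype(int)
    expr = make_dataset(z, dataset_id, cancer_type)
    clin = make_clinical(dataset_id, expr.sample_ids, time, event)
    return expr, clin


@pytest.fixture(scope="session")
def small_study():
    """Two synthetic cancer types, six cohorts each, ten shared planted genes."""
    cfg = SyntheticConfig(n_cancer_types=2, datasets_per_type=6,
                          samples_per_dataset=(100, 110), n_genes=500,
                          n_shared_prognostic=10, n_type_specific=5,
                          multiprobe_fraction=0.1, seed=3)
    collection, truth = generate_collection(cfg)
    return cfg, collection, truth


@pytest.fixture(scope="session")
def small_collapsed(small_study):
    _, collection, _ = small_study
    return CohortCollection(
        [(collapse_probes(expr)[0], clin) for expr, clin in collection])
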