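"""Standardization filters applied to cohorts before any survival analysis.

Three steps, in their usual order:

1. :func:`collapse_probes` — microarray platforms measure a gene with
   several probesets; only the probe with the largest interquartile range
   across the cohort is kept per gene, unmapped probes are dropped.
2. :func:`remove_duplicates` — patients contributed to more than one study
   show up as near-identical columns across cohorts; pairs with Spearman
   correlation above a threshold (default 0.98) within a cancer type are
   collapsed to a single sample.
3. :func:`filter_collection` — non-tumor samples are removed, and whole
   cohorts are dropped when they have too few samples or too few observed
   survival events to support estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ClinicalTable, CohortCollection, ExpressionDataset, extract_endpoint

logger = logging.getLogger(__name__)

#: minimum shared non-missing genes for a sample pair to be scored
MIN_SHARED_GENES = 30


class EmptyResultError(ValueError):
    """A curation step would leave nothing to analyse."""


# ---------------------------------------------------------------------------
# Probe collapsing

def _gene_key(gene_symbol, entrez_id) -> str | None:
    if isinstance(gene_symbol, str) and gene_symbol:
        return gene_symbol
    if pd.notna(entrez_id):
        return f"ENTREZ:{int(entrez_id)}"
    return None


def collapse_probes(dataset: ExpressionDataset,
                    ) -> tuple[ExpressionDataset, dict[str, str]]:
    """Collapse multi-probe features to one row per gene by maximal IQR.

    Returns the collapsed dataset plus the provenance map gene -> chosen
    probe_id.  IQR ties break in favor of the probe listed first in the
    annotation table; probes with neither gene symbol nor Entrez id are
    dropped.  Idempotent: collapsing a collapsed dataset is the identity.
    """
    genes = [
        _gene_key(gs, ez)
        for gs, ez in zip(dataset.features["gene_symbol"],
                          dataset.features["entrez_id"])
    ]
    mappable = [g is not None for g in genes]
    if not any(mappable):
        raise EmptyResultError(
            f"{dataset.dataset_id}: no probe maps to a gene")

    mat = dataset.values.to_numpy(dtype=float)
    with np.errstate(all="ignore"):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            iqr = (np.nanpercentile(mat, 75, axis=1)
                   - np.nanpercentile(mat, 25, axis=1))
    iqr = np.where(np.isnan(iqr), -np.inf, iqr)

    chosen: dict[str, str] = {}
    best_iqr: dict[str, float] = {}
    for probe, gene, keep, v in zip(dataset.values.index, genes, mappable, iqr):
        if not keep:
            continue
        if gene not in chosen or v > best_iqr[gene]:
            chosen[gene] = probe
            best_iqr[gene] = v

    order = sorted(chosen)
    probes = [chosen[g] for g in order]
    values = dataset.values.loc[probes].copy()
    values.index = pd.Index(order, name="feature_id")
    features = dataset.features.loc[probes].copy()
    features.index = pd.Index(order, name="probe_id")
    collapsed = ExpressionDataset(dataset.dataset_id, dataset.cancer_type,
                                  values, features)
    return collapsed, chosen


# ---------------------------------------------------------------------------
# Duplicate-sample removal

@dataclass
class DuplicateReport:
    """Record of the duplicate scan: flagged pairs and removal decisions."""

    pairs: pd.DataFrame  # kept_id, removed_id, rho, cancer_type (global ids)

    @property
    def n_removed(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def _spearman_matrix(mat: np.ndarray) -> np.ndarray:
    """Spearman correlation between columns of a genes x samples matrix."""
    if not np.isnan(mat).any():
        ranks = stats.rankdata(mat, axis=0)
        return np.corrcoef(ranks.T)
    # pairwise-complete fallback, only used when measurements are missing
    p = mat.shape[1]
    rho = np.full((p, p), np.nan)
    for i in range(p):
        rho[i, i] = 1.0
        for j in range(i + 1, p):
            m = ~np.isnan(mat[:, i]) & ~np.isnan(mat[:, j])
            if m.sum() >= MIN_SHARED_GENES:
                rho[i, j] = rho[j, i] = stats.spearmanr(mat[m, i], mat[m, j]).statistic
    return rho


def remove_duplicates(collection: CohortCollection,
                      rho_threshold: float = 0.98,
                      within_dataset_only: bool = False,
                      ) -> tuple[CohortCollection, DuplicateReport]:
    """Drop near-duplicate transcriptomic profiles within each cancer type.

    Samples whose Spearman correlation over shared genes exceeds
    ``rho_threshold`` form an undirected graph; one member of each connected
    component is kept (preferring the largest cohort, then the
    lexicographically first dataset and sample id) and the rest removed.
    The report pairs every removed sample with the kept member of its
    component and the correlation between the two.
    """
    if not 0 < rho_threshold <= 1:
        raise ValueError("rho_threshold must lie in (0, 1]")

    drop: dict[str, set[str]] = {}
    rows = []
    for cancer_type, ds_ids in collection.grouping.items():
        sub = collection.subset(ds_ids)
        shared = None
        for expr, _ in sub:
            idx = set(expr.values.index)
            shared = idx if shared is None else shared & idx
        shared = sorted(shared or [])
        if len(shared) < MIN_SHARED_GENES:
            logger.warning("%s: fewer than %d shared genes, duplicate scan skipped",
                           cancer_type, MIN_SHARED_GENES)
            continue

        cols, owners, sizes = [], [], []
        for expr, _ in sub:
            block = expr.values.loc[shared]
            for sid in expr.sample_ids:
                cols.append(block[sid].to_numpy(dtype=float))
                owners.append((expr.dataset_id, sid))
                sizes.append(expr.n_samples)
        mat = np.column_stack(cols)
        rho = _spearman_matrix(mat)

        if within_dataset_only:
            same = np.array([[a[0] == b[0] for b in owners] for a in owners])
            rho = np.where(same, rho, np.nan)

        flagged = np.triu(np.nan_to_num(rho, nan=-2.0) > rho_threshold, k=1)
        if not flagged.any():
            continue

        # union-find over flagged pairs
        parent = list(range(len(owners)))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j in zip(*np.nonzero(flagged)):
            ri, rj = find(int(i)), find(int(j))
            if ri != rj:
                parent[ri] = rj

        comps: dict[int, list[int]] = {}
        for i in range(len(owners)):
            comps.setdefault(find(i), []).append(i)
        for members in comps.values():
            if len(members) < 2:
                continue
            keep = min(members, key=lambda i: (-sizes[i], owners[i]))
            for i in members:
                if i == keep:
                    continue
                ds, sid = owners[i]
                drop.setdefault(ds, set()).add(sid)
                rows.append({
                    "kept_id": f"{owners[keep][0]}:{owners[keep][1]}",
                    "removed_id": f"{ds}:{sid}",
                    "rho": float(rho[keep, i]),
                    "cancer_type": cancer_type,
                })

    pairs = pd.DataFrame(rows, columns=["kept_id", "removed_id", "rho", "cancer_type"])
    new_datasets = []
    for expr, clin in collection:
        bad = drop.get(expr.dataset_id, set())
        if bad:
            keep_ids = [s for s in expr.sample_ids if s not in bad]
            new_datasets.append((expr.subset_samples(keep_ids),
                                 clin.subset_samples(keep_ids)))
        else:
            new_datasets.append((expr, clin))
    return CohortCollection(new_datasets), DuplicateReport(pairs)


# ---------------------------------------------------------------------------
# Sample-type and dataset-size filtering

def filter_collection(collection: CohortCollection,
                      min_samples: int = 0,
                      min_events: int = 0,
                      tumor_only: bool = True,
                      endpoint: str = "overall_survival",
                      ) -> CohortCollection:
    """Drop non-tumor samples and under-powered cohorts.

    ``min_samples`` applies after the tumor filter; ``min_events`` counts
    observed events on the chosen endpoint.  Monotone: raising either
    threshold never retains more cohorts.
    """
    kept = []
    for expr, clin in collection:
        if tumor_only:
            tumor_ids = clin.df.index[clin.df["sample_type"] == "tumor"]
            expr = expr.subset_samples(tumor_ids)
            clin = clin.subset_samples(tumor_ids)
        if expr.n_samples < min_samples:
            logger.info("%s dropped: %d samples < %d", expr.dataset_id,
                        expr.n_samples, min_samples)
            continue
        ep = extract_endpoint(clin, endpoint)
        n_events = sum(e.event for e in ep.values())
        if n_events < min_events:
            logger.info("%s dropped: %d events < %d", expr.dataset_id,
                        n_events, min_events)
            continue
        kept.append((expr, clin))
    return CohortCollection(kept)
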