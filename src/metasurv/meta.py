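"""Random-effects pooling of per-dataset hazard estimates and genome-wide scans.

Each gene receives one D-index (log hazard ratio) per cohort; the per-cohort
estimates are pooled by inverse-variance weighting.  Under the random-effects
model the between-study variance tau^2 is estimated by the method of moments
of DerSimonian & Laird:

    Q    = sum w_i (y_i - y_fixed)^2,        w_i = 1 / se_i^2
    tau2 = max(0, (Q - (k - 1)) / (sum w - sum w^2 / sum w))

and the pooled estimate re-weights by 1 / (se_i^2 + tau2).  The pooled
p-value is a two-sided normal test of pooled_log_hr / pooled_se; q-values
are Benjamini-Hochberg over the scanned gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortCollection, endpoint_arrays, extract_endpoint
from .survstats import d_index_batch

Z975 = stats.norm.ppf(0.975)


@dataclass
class GeneEstimate:
    """One gene's log-hazard estimate in one cohort."""

    gene: str
    dataset_id: str
    log_hr: float
    se: float
    n: int
    n_events: int


@dataclass
class MetaEstimate:
    """Pooled log-hazard estimate for one gene across cohorts."""

    gene: str
    pooled_log_hr: float
    pooled_se: float
    p_value: float
    tau2: float
    cochran_q: float
    k: int
    q_value: float = field(default=np.nan)

    @property
    def hr(self) -> float:
        return float(np.exp(self.pooled_log_hr))

    @property
    def ci95(self) -> tuple[float, float]:
        half = Z975 * self.pooled_se
        return (self.pooled_log_hr - half, self.pooled_log_hr + half)


def combine_estimates(log_hrs: Sequence[float], ses: Sequence[float],
                      model: Literal["fixed", "random"] = "random",
                      ) -> tuple[float, float, float, float]:
    """Pool per-study estimates -> (pooled_log_hr, pooled_se, tau2, cochran_q).

    ``fixed``: inverse-variance weights.  ``random``: DerSimonian-Laird
    moment estimate of the between-study variance, then inverse total
    variance weights.  With one study the input is returned unchanged and
    tau2 = Q = 0.
    """
    y = np.asarray(log_hrs, dtype=float)
    s = np.asarray(ses, dtype=float)
    if y.size == 0:
        raise ValueError("cannot pool zero estimates")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown model {model!r}")

    w = 1.0 / s**2
    sw = w.sum()
    mu_fixed = float((w * y).sum() / sw)
    q = float((w * (y - mu_fixed) ** 2).sum())
    k = y.size

    if k == 1:
        return float(y[0]), float(s[0]), 0.0, 0.0

    if model == "fixed":
        return mu_fixed, float(1.0 / np.sqrt(sw)), 0.0, q

    denom = sw - (w**2).sum() / sw
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_re = 1.0 / (s**2 + tau2)
    pooled = float((w_re * y).sum() / w_re.sum())
    pooled_se = float(1.0 / np.sqrt(w_re.sum()))
    return pooled, pooled_se, tau2, q


def meta_estimate(gene: str, estimates: Sequence[GeneEstimate],
                  model: Literal["fixed", "random"] = "random") -> MetaEstimate:
    """Pool a gene's per-cohort estimates into a :class:`MetaEstimate`."""
    pooled, se, tau2, q = combine_estimates(
        [e.log_hr for e in estimates], [e.se for e in estimates], model=model)
    p = float(2.0 * stats.norm.sf(abs(pooled) / se))
    return MetaEstimate(gene=gene, pooled_log_hr=pooled, pooled_se=se,
                        p_value=p, tau2=tau2, cochran_q=q, k=len(estimates))


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def per_dataset_estimates(collection: CohortCollection,
                          endpoint: str = "overall_survival",
                          genes: Sequence[str] | None = None,
                          ) -> list[GeneEstimate]:
    """D-index of every gene in every cohort of a (gene-collapsed) collection.

    Cohorts where a gene's fit is degenerate (constant expression, too few
    events) simply contribute no estimate for that gene.  Missing values are
    tolerated gene-by-gene: a gene's fit in a cohort uses the samples where
    it was measured.
    """
    out: list[GeneEstimate] = []
    for expr, clin in collection:
        ep = extract_endpoint(clin, endpoint)
        ids, time, event = endpoint_arrays(ep, expr.sample_ids)
        if len(ids) == 0 or event.sum() < 2:
            continue
        mat = expr.values[ids]
        if genes is not None:
            mat = mat.loc[mat.index.intersection(genes)]
        x = mat.to_numpy(dtype=float).T  # samples x genes
        complete = ~np.isnan(x).any(axis=0)
        if complete.any():
            res = d_index_batch(x[:, complete], time, event)
            names = mat.index[complete]
            for j, g in enumerate(names):
                if res.converged[j]:
                    out.append(GeneEstimate(str(g), expr.dataset_id,
                                            float(res.coef[j]), float(res.se[j]),
                                            res.n, res.n_events))
        # genes with missing values: pairwise-complete, one at a time
        for j in np.flatnonzero(~complete):
            col = x[:, j]
            m = ~np.isnan(col)
            if m.sum() < 10 or event[m].sum() < 2 or np.ptp(col[m]) == 0:
                continue
            res = d_index_batch(col[m][:, None], time[m], event[m])
            if res.converged[0]:
                out.append(GeneEstimate(str(mat.index[j]), expr.dataset_id,
                                        float(res.coef[0]), float(res.se[0]),
                                        res.n, res.n_events))
    return out


def genomewide_meta(collection: CohortCollection,
                    endpoint: str = "overall_survival",
                    min_datasets: int = 6,
                    model: Literal["fixed", "random"] = "random",
                    genes: Sequence[str] | None = None,
                    ) -> list[MetaEstimate]:
    """Genome-wide per-gene meta-analysis over a curated collection.

    Genes with usable estimates in fewer than ``min_datasets`` cohorts are
    dropped; q-values are Benjamini-Hochberg over the returned set.
    """
    if min_datasets < 1:
        raise ValueError("min_datasets must be >= 1")
    per_gene: dict[str, list[GeneEstimate]] = {}
    for est in per_dataset_estimates(collection, endpoint, genes):
        per_gene.setdefault(est.gene, []).append(est)

    metas = [meta_estimate(g, ests, model=model)
             for g, ests in sorted(per_gene.items())
             if len(ests) >= min_datasets]
    if metas:
        q = adjust_fdr([m.p_value for m in metas])
        for m, qv in zip(metas, q):
            m.q_value = float(qv)
    return metas


def meta_table(metas: Sequence[MetaEstimate]) -> pd.DataFrame:
    """Tabulate meta-estimates (one row per gene) for export as TSV."""
    rows = []
    for m in metas:
        lo, hi = m.ci95
        rows.append({
            "gene": m.gene, "k": m.k, "pooled_log_hr": m.pooled_log_hr,
            "se": m.pooled_se, "hr": m.hr,
            "ci_lo": np.exp(lo), "ci_hi": np.exp(hi),
            "p": m.p_value, "q": m.q_value,
            "tau2": m.tau2, "cochran_q": m.cochran_q,
        })
    return pd.DataFrame(rows)
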