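"""Prognostic gene-signature discovery, scoring, and the random-signature null.

A signature is a gene list with a direction per gene: +1 when high expression
carries a hazard ratio above 1 (risk gene), -1 when below 1 (protective).
Discovery selects genes whose pooled hazard ratio passes an FDR threshold and
departs from 1 by a margin in *every* training cancer type, with concordant
direction.  Samples are scored by the signed average of within-cohort
standardized expression, so that a higher score always means worse expected
outcome.

Because many published signatures perform no better than random gene sets of
equal size, :func:`random_signature_null` tests a signature's pooled D-index
against the null distribution generated by signatures of randomly chosen
genes whose directions are assigned exactly as the real signature's were
(from the training-scan hazard signs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortCollection, ExpressionDataset, endpoint_arrays, extract_endpoint
from .meta import MetaEstimate, combine_estimates
from .survstats import DIndexResult, d_index
from scipy import stats


class CoverageError(ValueError):
    """No signature gene is measured in the dataset being scored."""


@dataclass
class GeneSignature:
    """A named gene list with +1/-1 directions.

    ``provenance`` optionally records, per gene, the per-cancer pooled
    hazard ratio and q-value that selected it.
    """

    name: str
    members: list[tuple[str, int]]
    entrez_ids: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.members]
        if len(genes) != len(set(genes)):
            raise ValueError("signature genes must be unique")
        if any(d not in (+1, -1) for _, d in self.members):
            raise ValueError("directions must be +1 or -1")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.members]

    @property
    def directions(self) -> dict[str, int]:
        return dict(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def flipped(self) -> "GeneSignature":
        return GeneSignature(self.name + "-flipped",
                             [(g, -d) for g, d in self.members],
                             dict(self.entrez_ids))

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "genes": [{"symbol": g, "entrez_id": self.entrez_ids.get(g),
                       "direction": d} for g, d in self.members],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GeneSignature":
        obj = json.loads(text)
        members = [(g["symbol"], int(g["direction"])) for g in obj["genes"]]
        entrez = {g["symbol"]: int(g["entrez_id"]) for g in obj["genes"]
                  if g.get("entrez_id") is not None}
        return cls(obj["name"], members, entrez)


@dataclass
class SelectionConfig:
    """Thresholds for cross-cancer signature discovery.

    A gene is selected when, in every training cancer type, its pooled
    hazard ratio is significant at ``fdr_max`` and lies outside
    [``hr_lower``, ``hr_upper``]; with ``require_concordance`` the side must
    agree across cancer types.
    """

    fdr_max: float = 0.05
    hr_upper: float = 1.125
    hr_lower: float = 0.875
    require_concordance: bool = True
    holdout_dataset_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must lie in (0, 1)")
        if not self.hr_lower < 1 < self.hr_upper:
            raise ValueError("need hr_lower < 1 < hr_upper")


def discover_signature(meta_by_cancer: Mapping[str, Sequence[MetaEstimate]],
                       config: SelectionConfig | None = None,
                       name: str = "discovered",
                       ) -> GeneSignature:
    """Select the genes prognostic in every training cancer type.

    Selection is invariant to gene and cancer-type ordering.  An empty
    selection yields an empty-membered signature with a warning rather
    than an error (the caller may relax thresholds).
    """
    config = config or SelectionConfig()
    if len(meta_by_cancer) < 2:
        raise ValueError("signature discovery needs >= 2 cancer types")
    tables = {ct: {m.gene: m for m in metas}
              for ct, metas in meta_by_cancer.items()}

    common = set.intersection(*(set(t) for t in tables.values()))
    members: list[tuple[str, int]] = []
    provenance: dict[str, dict[str, tuple[float, float]]] = {}
    for gene in sorted(common):
        sides = []
        ok = True
        for ct in sorted(tables):
            m = tables[ct][gene]
            if np.isnan(m.q_value) or m.q_value >= config.fdr_max:
                ok = False
                break
            if m.hr > config.hr_upper:
                sides.append(+1)
            elif m.hr < config.hr_lower:
                sides.append(-1)
            else:
                ok = False
                break
        if not ok:
            continue
        if config.require_concordance and len(set(sides)) > 1:
            continue
        mean_log_hr = float(np.mean([tables[ct][gene].pooled_log_hr
                                     for ct in tables]))
        members.append((gene, +1 if mean_log_hr > 0 else -1))
        provenance[gene] = {ct: (tables[ct][gene].hr, tables[ct][gene].q_value)
                            for ct in tables}

    if not members:
        warnings.warn("no gene passed the selection thresholds; "
                      "returning an empty signature", stacklevel=2)
        sig = GeneSignature.__new__(GeneSignature)
        sig.name, sig.members, sig.entrez_ids, sig.provenance = name, [], {}, {}
        return sig
    return GeneSignature(name, members, provenance=provenance)


# ---------------------------------------------------------------------------
# Scoring

def signed_average_score(dataset: ExpressionDataset,
                         signature: GeneSignature,
                         scaling: Literal["zscore", "rank"] = "zscore",
                         coverage_warn: float = 0.5,
                         ) -> pd.Series:
    """Signed-average risk score per sample for one cohort.

    Each measured signature gene is standardized within the cohort
    (z-score by default, or rank-scaled to [-1, 1]); the score is the
    direction-weighted sum divided by the number of measured signature
    genes.  Missing signature genes are dropped from the denominator; a
    coverage below ``coverage_warn`` triggers a warning and zero coverage
    raises :class:`CoverageError`.
    """
    if len(signature) == 0:
        raise CoverageError("cannot score an empty signature")
    present = [(g, d) for g, d in signature.members if g in dataset.values.index]
    usable: list[tuple[str, int]] = []
    cols = []
    for g, d in present:
        row = dataset.values.loc[g].to_numpy(dtype=float)
        if np.nanstd(row) == 0 or np.isnan(row).all():
            continue
        usable.append((g, d))
        cols.append(row)
    coverage = len(usable) / len(signature)
    if not usable:
        raise CoverageError(
            f"{dataset.dataset_id}: no signature gene measured with variance")
    if coverage < coverage_warn:
        warnings.warn(f"{dataset.dataset_id}: signature coverage "
                      f"{coverage:.0%} below {coverage_warn:.0%}", stacklevel=2)

    mat = np.vstack(cols)  # genes x samples
    if scaling == "zscore":
        mu = np.nanmean(mat, axis=1, keepdims=True)
        sd = np.nanstd(mat, axis=1, ddof=1, keepdims=True)
        std = (mat - mu) / sd
    elif scaling == "rank":
        n = mat.shape[1]
        r = stats.rankdata(mat, axis=1, nan_policy="omit")
        std = 2.0 * (r - 1) / (n - 1) - 1.0 if n > 1 else np.zeros_like(mat)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    dirs = np.array([d for _, d in usable], dtype=float)[:, None]
    contrib = np.where(np.isnan(std), 0.0, dirs * std)
    scores = contrib.sum(axis=0) / len(usable)
    out = pd.Series(scores, index=dataset.values.columns, name="score")
    out.attrs["coverage"] = coverage
    return out


def signature_meta_d(collection: CohortCollection,
                     signature: GeneSignature,
                     endpoint: str = "overall_survival",
                     scaling: Literal["zscore", "rank"] = "zscore",
                     ) -> tuple[float, float, list[DIndexResult]]:
    """Pooled random-effects D-index of a signature across a collection.

    Per cohort: signed-average scores, then the D-index of the score; the
    per-cohort log hazard ratios are pooled by DerSimonian-Laird.  Returns
    (pooled_log_hr, pooled_se, per-cohort results).  Cohorts where the fit
    is degenerate are skipped.
    """
    per: list[DIndexResult] = []
    for expr, clin in collection:
        ep = extract_endpoint(clin, endpoint)
        ids, time, event = endpoint_arrays(ep, expr.sample_ids)
        if len(ids) < 4 or event.sum() < 2:
            continue
        try:
            scores = signed_average_score(expr, signature, scaling=scaling)
        except CoverageError:
            continue
        s = scores.loc[ids].to_numpy(dtype=float)
        if np.ptp(s) == 0:
            continue
        per.append(d_index(s, time, event))
    if not per:
        raise ValueError("signature could not be evaluated in any cohort")
    pooled, se, _, _ = combine_estimates([r.log_hr for r in per],
                                         [r.se for r in per], model="random")
    return pooled, se, per


# ---------------------------------------------------------------------------
# Random-signature null

@dataclass
class NullTestResult:
    """Permutation comparison of a signature against random gene sets."""

    observed_log_hr: float
    null_distribution: np.ndarray
    p_value: float
    n_random: int
    seed: int

    def summary_frame(self) -> pd.DataFrame:
        qs = np.quantile(np.abs(self.null_distribution), [0.5, 0.9, 0.95, 0.99])
        return pd.DataFrame([{
            "observed_log_hr": self.observed_log_hr, "p": self.p_value,
            "n_random": self.n_random, "seed": self.seed,
            "null_abs_q50": qs[0], "null_abs_q90": qs[1],
            "null_abs_q95": qs[2], "null_abs_q99": qs[3],
        }])


def random_signature_null(collection: CohortCollection,
                          training_meta: Sequence[MetaEstimate],
                          signature: GeneSignature,
                          n_random: int = 1000,
                          seed: int = 0,
                          endpoint: str = "overall_survival",
                          random_directions: bool = False,
                          ) -> NullTestResult:
    """Test a signature against random same-size signatures.

    Random gene sets are drawn uniformly from genes measured in every
    cohort of ``collection`` that also carry a training meta-estimate;
    each random gene's direction is the sign of its training pooled log
    hazard ratio (or a coin flip with ``random_directions``), so the null
    signatures are built exactly as the observed one was, just on random
    genes.  Significance is the add-one permutation p-value on the
    magnitude of the pooled log hazard ratio:
    p = (1 + #{|D_null| >= |D_obs|}) / (n_random + 1).
    """
    size = len(signature)
    if size < 1 or n_random < 1:
        raise ValueError("need size >= 1 and n_random >= 1")
    train_sign = {m.gene: (1 if m.pooled_log_hr > 0 else -1)
                  for m in training_meta}
    shared: set[str] | None = None
    for expr, _ in collection:
        idx = set(expr.values.index)
        shared = idx if shared is None else shared & idx
    pool = sorted((shared or set()) & set(train_sign))
    if size > len(pool):
        raise ValueError(f"signature size {size} exceeds the "
                         f"{len(pool)}-gene eligible pool")

    observed, _, _ = signature_meta_d(collection, signature, endpoint)

    # precompute per-cohort standardized matrices and endpoints once; each
    # null draw is then a matrix slice + one D-index per cohort
    cohorts = []
    for expr, clin in collection:
        ep = extract_endpoint(clin, endpoint)
        ids, time, event = endpoint_arrays(ep, expr.sample_ids)
        if len(ids) < 4 or event.sum() < 2:
            continue
        mat = expr.values.loc[pool].to_numpy(dtype=float)
        mu = np.nanmean(mat, axis=1, keepdims=True)
        sd = np.nanstd(mat, axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = np.nan
        z = (mat - mu) / sd
        col = {s: j for j, s in enumerate(expr.values.columns)}
        keep = [col[s] for s in ids]
        cohorts.append((np.nan_to_num(z[:, keep]), time, event))
    sign_vec = np.array([train_sign[g] for g in pool], dtype=float)

    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    for b in range(n_random):
        idx = rng.choice(len(pool), size=size, replace=False)
        if random_directions:
            dirs = rng.choice([-1.0, 1.0], size=size)
        else:
            dirs = sign_vec[idx]
        logs, ses = [], []
        for z, time, event in cohorts:
            scores = dirs @ z[idx] / size
            if np.ptp(scores) == 0:
                continue
            r = d_index(scores, time, event)
            logs.append(r.log_hr)
            ses.append(r.se)
        null[b], _, _, _ = combine_estimates(logs, ses, model="random")
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_random + 1.0)
    return NullTestResult(observed_log_hr=observed, null_distribution=null,
                          p_value=float(p), n_random=n_random, seed=seed)


# ---------------------------------------------------------------------------
# Packaged signature and gene-list fixtures

def _read_data(name: str) -> str:
    return resources.files("metasurv.data").joinpath(name).read_text()


def load_multicancer_signature() -> GeneSignature:
    """The packaged 53-gene multi-cancer prognostic signature.

    Discovered from a breast + ovarian training meta-analysis (FDR < 5%,
    pooled HR > 1.125 or < 0.875 in both cancers) and validated in
    pancreatic cancer; directions follow the pooled hazard side (+1 when
    high expression is adverse).
    """
    return GeneSignature.from_json(_read_data("signature_multicancer_53.json"))


def load_ovarian_gene_list() -> list[str]:
    """Six well-studied prognostic genes evaluated in ovarian cancer."""
    return json.loads(_read_data("ovarian_prognostic_genes.json"))["genes"]


def load_breast_module_prototypes() -> list[str]:
    """Prototype genes of the seven breast-cancer gene modules."""
    return json.loads(_read_data("breast_module_prototypes.json"))["prototypes"]
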