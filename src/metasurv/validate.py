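"""Held-out evaluation of signatures: pooled and subtype-stratified D-index,
log-rank on median-split groups, and module-correlation meta-estimates.

A signature is evaluated exactly as it would be used clinically: per cohort,
samples are scored by the signed average, split at the cohort median, and
the cohort D-indices are pooled by random effects; the log-rank test runs on
the per-cohort groups concatenated across cohorts.  The same is repeated
within each molecular subtype.  Gene modules (a prototype gene plus its
correlated members) are scored by the identical signed-average machinery,
and signature-module agreement is a random-effects meta-estimate of the
per-cohort Spearman correlations on the Fisher-z scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortCollection, endpoint_arrays, extract_endpoint
from .meta import combine_estimates
from .signature import CoverageError, GeneSignature, signed_average_score
from .survstats import DIndexResult, d_index, logrank_test, median_split

#: |rho| is clipped here before the Fisher transform to avoid infinities
RHO_CLIP = 0.9999


@dataclass
class GeneModule:
    """A prototype gene plus correlated members, scored like a signature."""

    prototype: str
    members: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("module must be non-empty")
        if self.prototype not in {g for g, _ in self.members}:
            raise ValueError("prototype must be among the members")

    def as_signature(self) -> GeneSignature:
        return GeneSignature(f"module-{self.prototype}", list(self.members))


@dataclass
class EvaluationRecord:
    """One signature x stratum evaluation: pooled D-index and log-rank."""

    signature_name: str
    stratum: str
    d: DIndexResult
    logrank_chi2: float
    logrank_p: float
    n: int


@dataclass
class ModuleCorrelation:
    """Meta-estimate of the signature-module Spearman correlation."""

    prototype: str
    rho: float
    ci95: tuple[float, float]
    k: int
    per_dataset: list[tuple[str, float, int]]  # dataset_id, rho, n


def _stratum_records(collection: CohortCollection, signature: GeneSignature,
                     stratum: str, sample_filter, endpoint: str,
                     ) -> EvaluationRecord | None:
    """Pooled evaluation over one stratum; None when no cohort is usable."""
    logs, ses = [], []
    pooled_groups, pooled_time, pooled_event = [], [], []
    n_total = n_events = 0
    for expr, clin in collection:
        ep = extract_endpoint(clin, endpoint)
        ids, time, event = endpoint_arrays(ep, expr.sample_ids)
        keep = sample_filter(clin, ids)
        ids = [s for s, k in zip(ids, keep) if k]
        time, event = time[keep], event[keep]
        if len(ids) < 4 or event.sum() < 2:
            continue
        try:
            scores = signed_average_score(expr, signature)
        except CoverageError:
            continue
        s = scores.loc[ids].to_numpy(dtype=float)
        if np.ptp(s) == 0:
            continue
        res = d_index(s, time, event)
        logs.append(res.log_hr)
        ses.append(res.se)
        pooled_groups.append(median_split(s))
        pooled_time.append(time)
        pooled_event.append(event)
        n_total += len(ids)
        n_events += int(event.sum())
    if not logs:
        return None
    pooled, se, _, _ = combine_estimates(logs, ses, model="random")
    from scipy import stats as _st
    p = float(2.0 * _st.norm.sf(abs(pooled) / se))
    groups = np.concatenate(pooled_groups)
    time = np.concatenate(pooled_time)
    event = np.concatenate(pooled_event)
    if np.unique(groups).size == 2:
        chi2, lr_p = logrank_test(groups, time, event)
    else:
        chi2, lr_p = float("nan"), float("nan")
    d = DIndexResult(log_hr=pooled, se=se, p_value=p, n=n_total,
                     n_events=n_events)
    return EvaluationRecord(signature.name, stratum, d, chi2, lr_p, n_total)


def evaluate_signature(collection: CohortCollection,
                       signature: GeneSignature,
                       strata: Sequence[str] | None = None,
                       endpoint: str = "overall_survival",
                       ) -> list[EvaluationRecord]:
    """Evaluate a signature over all patients and within each subtype stratum.

    ``strata`` defaults to the subtype labels present in the clinical
    tables.  Strata with fewer than 2 events in every cohort are skipped
    with a warning.
    """
    if strata is None:
        labels: set[str] = set()
        for _, clin in collection:
            labels |= set(clin.df["subtype"].dropna().unique())
        strata = sorted(labels)

    records = []
    rec = _stratum_records(collection, signature, "all",
                          lambda clin, ids: np.ones(len(ids), dtype=bool),
                          endpoint)
    if rec is None:
        raise ValueError("signature scores not computable in any cohort")
    records.append(rec)
    for label in strata:
        rec = _stratum_records(
            collection, signature, label,
            lambda clin, ids, lab=label: np.asarray(
                clin.df.loc[ids, "subtype"].eq(lab).to_numpy()),
            endpoint)
        if rec is None:
            warnings.warn(f"stratum {label!r} skipped: too few events",
                          stacklevel=2)
            continue
        records.append(rec)
    return records


def evaluation_table(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Tabulate evaluation records (hazard-ratio scale) for TSV export."""
    rows = []
    for r in records:
        lo, hi = r.d.ci95()
        rows.append({
            "signature": r.signature_name, "stratum": r.stratum,
            "d_index": math.exp(r.d.log_hr),
            "ci_lo": math.exp(lo), "ci_hi": math.exp(hi),
            "d_p": r.d.p_value, "logrank_p": r.logrank_p, "n": r.n,
        })
    return pd.DataFrame(rows)


def correlate_with_modules(collection: CohortCollection,
                           signature: GeneSignature,
                           modules: Sequence[GeneModule],
                           ) -> list[ModuleCorrelation]:
    """Random-effects meta-estimate of signature-module score correlations.

    Per cohort the Spearman correlation between the two signed-average
    scores is Fisher-z transformed (se = 1/sqrt(n-3)), pooled by
    DerSimonian-Laird, and back-transformed; cohorts with n < 4 are
    skipped and |rho| is clipped at 0.9999 before the transform.
    """
    from scipy import stats as _st

    out = []
    for module in modules:
        per: list[tuple[str, float, int]] = []
        zs, ses = [], []
        for expr, _ in collection:
            if expr.n_samples < 4:
                continue
            try:
                s_sig = signed_average_score(expr, signature)
                s_mod = signed_average_score(expr, module.as_signature())
            except CoverageError:
                continue
            rho = float(_st.spearmanr(s_sig.to_numpy(), s_mod.to_numpy()).statistic)
            per.append((expr.dataset_id, rho, expr.n_samples))
            rho_c = float(np.clip(rho, -RHO_CLIP, RHO_CLIP))
            zs.append(np.arctanh(rho_c))
            ses.append(1.0 / math.sqrt(expr.n_samples - 3))
        if not per:
            continue
        pooled, se, _, _ = combine_estimates(zs, ses, model="random")
        lo, hi = pooled - 1.959963984540054 * se, pooled + 1.959963984540054 * se
        out.append(ModuleCorrelation(
            prototype=module.prototype, rho=float(np.tanh(pooled)),
            ci95=(float(np.tanh(lo)), float(np.tanh(hi))),
            k=len(per), per_dataset=per))
    return out
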