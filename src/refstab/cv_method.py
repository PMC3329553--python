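"""Coefficient-of-variation stability on normalized relative quantities.

Each candidate gene's relative quantities are divided by the per-sample
geometric mean of a reference set (by default the whole candidate panel,
the evaluated gene included), giving normalized relative quantities (NRQ).
A stable gene tracks the panel, so its NRQ is flat across samples; the
stability score is CV = sd(NRQ)/mean(NRQ), ranked ascending.

The CV is invariant both to per-sample scaling (a common factor cancels in
the geometric mean) and to per-gene scaling (CV is scale-free), so the
calibrator choice does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CVResult",
    "normalized_rq",
    "cv_stability",
    "nrq_standard_errors",
    "hellemans_qc",
]

#: quality guideline bounds on (M, CV) per panel homogeneity
HELLEMANS_LIMITS = {
    "heterogeneous": {"m": 1.0, "cv": 0.5},
    "homogeneous": {"m": 0.5, "cv": 0.25},
}


class CVMethodError(ValueError):
    pass


def _as_frame(rq) -> pd.DataFrame:
    return rq.rq if hasattr(rq, "rq") else rq


@dataclass
class CVResult:
    per_gene: pd.DataFrame   # gene, cv, mean_nrq, sd_nrq, rank
    ranking: list[str]
    nrq: pd.DataFrame

    def table(self) -> pd.DataFrame:
        return self.per_gene


def normalized_rq(rq, reference_set, log: list | None = None) -> pd.DataFrame:
    """NRQ_gs = rq_gs / geometric mean over the reference set at sample s.

    Samples where any reference gene is missing or zero are dropped with a
    log entry.
    """
    df = _as_frame(rq)
    reference_set = list(reference_set)
    if not reference_set:
        raise CVMethodError("reference set must be nonempty")
    missing = sorted(set(reference_set) - set(df.index))
    if missing:
        raise CVMethodError(f"reference genes absent from matrix: {missing}")
    ref = df.loc[reference_set]
    bad = [s for s in df.columns if ref[s].isna().any() or (ref[s] <= 0).any()]
    if bad:
        if log is not None:
            log.append(f"CV method: dropped samples with unusable reference values {bad}")
        df = df.drop(columns=bad)
        ref = ref.drop(columns=bad)
    geomean = np.exp(np.log(ref.to_numpy(float)).mean(axis=0))
    return df / geomean


def cv_stability(
    rq, candidate_set=None, leave_one_out: bool = False, log: list | None = None
) -> CVResult:
    """Rank candidates by the CV of their normalized relative quantities.

    The normalization set defaults to the full candidate panel including the
    evaluated gene; ``leave_one_out=True`` instead normalizes each gene by
    the geometric mean of the other candidates.
    """
    df = _as_frame(rq)
    candidates = list(candidate_set) if candidate_set is not None else list(df.index)
    if len(candidates) < (2 if not leave_one_out else 3):
        raise CVMethodError("CV method needs at least two candidates")
    sub = df.loc[candidates].dropna(axis=1)
    if sub.shape[1] < 2:
        raise CVMethodError("CV method needs >= 2 complete-case samples")

    if leave_one_out:
        rows = {}
        for gene in candidates:
            others = [g for g in candidates if g != gene]
            rows[gene] = normalized_rq(sub, others, log=log).loc[gene]
        nrq = pd.DataFrame(rows).T
    else:
        nrq = normalized_rq(sub, candidates, log=log).loc[candidates]

    stats = []
    for gene in candidates:
        vals = nrq.loc[gene].to_numpy(float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        stats.append({"gene": gene, "cv": sd / mean, "mean_nrq": mean, "sd_nrq": sd})
    per_gene = pd.DataFrame(stats).sort_values("cv", kind="stable").reset_index(drop=True)
    per_gene["rank"] = per_gene["cv"].rank(method="min").astype(int)
    return CVResult(per_gene=per_gene, ranking=list(per_gene["gene"]), nrq=nrq)


def nrq_standard_errors(
    nrq: pd.DataFrame, cq_sd: pd.DataFrame, amp_factor: pd.Series, n_tech: int = 3
) -> pd.DataFrame:
    """Delta-method per-sample NRQ standard errors from technical-replicate scatter.

    A Cq standard error of se_cq propagates through A**dCq to a relative
    error of ln(A)*se_cq, so se_NRQ ~= NRQ * ln(A) * cq_sd/sqrt(n_tech).
    These error bars are reported for inspection only; the CV ranking uses
    the across-sample scatter of NRQ itself.
    """
    ln_a = np.log(amp_factor.reindex(nrq.index).to_numpy(float))[:, None]
    se_cq = cq_sd.reindex(index=nrq.index, columns=nrq.columns).to_numpy(float)
    return pd.DataFrame(
        nrq.to_numpy(float) * ln_a * se_cq / np.sqrt(n_tech),
        index=nrq.index,
        columns=nrq.columns,
    )


def hellemans_qc(
    m: pd.Series | dict, cv: pd.Series | dict, panel: str = "heterogeneous"
) -> pd.DataFrame:
    """Flag genes violating the conventional (M, CV) quality guideline.

    Heterogeneous sample panels expect M <= 1 and CV <= 0.5; homogeneous
    panels tighten to M <= 0.5 and CV <= 0.25.
    """
    if panel not in HELLEMANS_LIMITS:
        raise ValueError(f"panel must be one of {sorted(HELLEMANS_LIMITS)}")
    limits = HELLEMANS_LIMITS[panel]
    m = pd.Series(m)
    cv = pd.Series(cv)
    genes = sorted(set(m.index) & set(cv.index))
    out = pd.DataFrame(
        {
            "gene": genes,
            "m": m.reindex(genes).values,
            "cv": cv.reindex(genes).values,
        }
    )
    out["m_ok"] = out["m"] <= limits["m"]
    out["cv_ok"] = out["cv"] <= limits["cv"]
    out["pass"] = out["m_ok"] & out["cv_ok"]
    return out
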