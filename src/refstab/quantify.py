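"""Efficiency-corrected relative quantification and RNA-integrity checks.

Aggregated Cq values are converted to relative quantities (RQ) per gene via
the ΔCq method: the sample with the lowest Cq (highest expression) is the
calibrator, ΔCq_s = Cq_min - Cq_s <= 0, and RQ_s = A**ΔCq_s where A is the
gene's amplification factor.  RQ is therefore in (0, 1] with the calibrator
at exactly 1.  Reactions at or above the Cq cutoff (default 40 cycles,
applied strictly) or undetermined are treated as missing, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RQMatrix",
    "IntegrityResult",
    "IntegrityThresholds",
    "to_relative_quantities",
    "integrity_ratio",
]

DEFAULT_CQ_CUTOFF = 40.0


class QuantifyError(ValueError):
    pass


@dataclass
class RQMatrix:
    """Gene x sample matrix of calibrator-scaled relative quantities.

    ``rq`` has genes as the row index and samples as columns; missing entries
    are NaN (never 0).  ``calibrator_cq`` records each gene's minimum Cq and
    ``efficiency`` the amplification factor(s) used.
    """

    rq: pd.DataFrame
    calibrator_cq: pd.Series
    efficiency: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.rq.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite <= 0).any():
            raise QuantifyError("relative quantities must be positive")
        if finite.size and (finite > 1 + 1e-9).any():
            raise QuantifyError("relative quantities must be <= 1 (calibrator-scaled)")

    @property
    def genes(self) -> list[str]:
        return list(self.rq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.rq.columns)

    def dropna_samples(self) -> pd.DataFrame:
        """Complete-case matrix: samples with any missing gene removed."""
        return self.rq.dropna(axis=1)

    def to_tsv(self, path) -> None:
        self.rq.to_csv(path, sep="\t", na_rep="NA", index_label="gene")

    def sidecar(self) -> dict:
        return {
            "calibrator_cq": {g: float(v) for g, v in self.calibrator_cq.items()},
            "efficiency": self.efficiency.to_dict(orient="records"),
        }


def _efficiency_lookup(eff, genes, sample_context=None) -> pd.DataFrame:
    """Normalize the accepted efficiency inputs to a (gene, context, amp_factor) frame.

    ``eff`` may be a dict gene->A, a float (shared A), a DataFrame with
    columns gene/context/amp_factor, or a list of EfficiencyEstimate.
    """
    if isinstance(eff, (int, float)):
        return pd.DataFrame(
            {"gene": genes, "context": "global", "amp_factor": float(eff)}
        )
    if isinstance(eff, dict):
        return pd.DataFrame(
            {"gene": list(eff), "context": "global",
             "amp_factor": [float(v) for v in eff.values()]}
        )
    if isinstance(eff, pd.DataFrame):
        df = eff.copy()
        if "context" not in df.columns:
            df["context"] = "global"
        return df[["gene", "context", "amp_factor"]]
    # assume iterable of EfficiencyEstimate
    return pd.DataFrame(
        [
            {"gene": e.gene_id, "context": e.context, "amp_factor": e.amp_factor}
            for e in eff
        ]
    )


def to_relative_quantities(
    agg: pd.DataFrame,
    eff,
    cq_cutoff: float = DEFAULT_CQ_CUTOFF,
    bio_rep="pooled",
    sample_context: pd.Series | None = None,
    log: list | None = None,
) -> RQMatrix:
    """Convert aggregated Cq values to an efficiency-corrected RQMatrix.

    ``agg`` is the output of :func:`refstab.qpcr_data.aggregate_technical`.
    ``bio_rep`` selects one biological replicate (int) or "pooled" to average
    Cq across biological replicates per (sample, gene).  ``sample_context``
    optionally maps sample id -> tissue/context label so per-tissue
    efficiencies are applied; otherwise each gene's "global" efficiency is
    used.  Entries with Cq >= cq_cutoff (strict filter) or undetermined are
    marked missing; genes with no valid sample are excluded with a log entry.
    """
    log = log if log is not None else []
    df = agg.copy()
    if bio_rep != "pooled":
        df = df[df["bio_rep"] == int(bio_rep)]
        if df.empty:
            raise QuantifyError(f"no data for biological replicate {bio_rep}")
    cq = df.groupby(["gene", "sample"], sort=True)["cq_mean"].mean().unstack("sample")
    cq = cq.mask(cq >= cq_cutoff)

    eff_df = _efficiency_lookup(eff, list(cq.index))
    missing_genes = set(cq.index) - set(eff_df["gene"])
    if missing_genes:
        raise QuantifyError(f"no efficiency for genes: {sorted(missing_genes)}")

    def amp_for(gene: str, sample: str) -> float:
        rows = eff_df[eff_df["gene"] == gene]
        if sample_context is not None:
            ctx = sample_context.get(sample)
            hit = rows[rows["context"] == ctx]
            if len(hit):
                return float(hit["amp_factor"].iloc[0])
        hit = rows[rows["context"] == "global"]
        if len(hit):
            return float(hit["amp_factor"].iloc[0])
        return float(rows["amp_factor"].mean())

    rq = pd.DataFrame(np.nan, index=cq.index, columns=cq.columns)
    calib = {}
    keep = []
    for gene in cq.index:
        row = cq.loc[gene]
        valid = row.dropna()
        if valid.empty:
            log.append(f"gene {gene}: no valid Cq below cutoff; excluded")
            continue
        keep.append(gene)
        cq_min = float(valid.min())
        calib[gene] = cq_min
        for sample, value in valid.items():
            a = amp_for(gene, sample)
            rq.loc[gene, sample] = a ** (cq_min - float(value))
    rq = rq.loc[keep]
    return RQMatrix(
        rq=rq,
        calibrator_cq=pd.Series(calib, name="calibrator_cq"),
        efficiency=eff_df[eff_df["gene"].isin(keep)].reset_index(drop=True),
    )


@dataclass
class IntegrityThresholds:
    """Verdict bounds for the 3':5' integrity ratio."""

    intact: float = 2.0
    degraded: float = 5.0


@dataclass
class IntegrityResult:
    sample_id: str
    ratio_3p5p: float
    verdict: str


def integrity_ratio(
    cq_3p: float,
    cq_5p: float,
    a_3p: float,
    a_5p: float,
    thresholds: IntegrityThresholds | None = None,
    sample_id: str = "",
) -> IntegrityResult:
    """3':5' mRNA integrity ratio from a two-amplicon assay.

    Amplicons at the 3' and 5' ends of one transcript report apparent
    quantities whose ratio gauges degradation (reverse transcription primes
    from the 3' end, so 5' signal drops first).  We form
    ratio = Ā**(Cq_5p - Cq_3p) with Ā the geometric mean of the two
    amplicons' amplification factors.  A ratio near 1 indicates intact mRNA;
    above the degraded threshold (default 5) indicates degradation.
    """
    thresholds = thresholds or IntegrityThresholds()
    if not (np.isfinite(cq_3p) and np.isfinite(cq_5p)):
        raise QuantifyError("integrity ratio needs numeric Cq at both ends")
    a_bar = float(np.sqrt(a_3p * a_5p))
    ratio = a_bar ** (cq_5p - cq_3p)
    if ratio <= thresholds.intact:
        verdict = "intact"
    elif ratio > thresholds.degraded:
        verdict = "degraded"
    else:
        verdict = "caution"
    return IntegrityResult(sample_id=sample_id, ratio_3p5p=float(ratio), verdict=verdict)
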