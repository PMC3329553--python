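"""geNorm expression-stability analysis.

For candidate reference genes j and k the pairwise variation V_jk is the
standard deviation (ddof=1) across samples of log2(rq_j / rq_k); a gene's
stability M_j is the mean of V_jk over all other candidates.  Genes are
ranked by stepwise exclusion of the highest-M gene until two remain (those
two cannot be ranked against each other and tie at the top).  The optimal
number of reference genes comes from the pairwise variation V_{n,n+1}
between normalization factors built from the top n and top n+1 genes; a
value at or below the conventional 0.15 guideline suggests the (n+1)-th
gene is not needed.

All statistics are invariant to per-gene rescaling of the relative
quantities, so the calibrator choice is irrelevant here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "GeNormResult",
    "pairwise_v",
    "m_values",
    "stepwise_ranking",
    "pairwise_variation_series",
    "optimal_n_from_series",
    "genorm_full",
]

DEFAULT_V_CUTOFF = 0.15


class GeNormError(ValueError):
    pass


def _as_frame(rq) -> pd.DataFrame:
    """Accept an RQMatrix or a plain gene x sample DataFrame."""
    return rq.rq if hasattr(rq, "rq") else rq


def _complete_cases(df: pd.DataFrame, log: list | None = None) -> pd.DataFrame:
    dropped = [s for s in df.columns if df[s].isna().any()]
    if dropped and log is not None:
        log.append(f"geNorm: dropped incomplete samples {dropped}")
    return df.drop(columns=dropped)


@dataclass
class GeNormResult:
    """Stepwise geNorm output.

    ranking: genes most -> least stable; the first two are tied (they are
    excluded last, together).  m_trajectory: one mapping of gene -> M per
    exclusion round, starting from the full candidate set.  final_pair_m is
    the mutual pairwise variation of the last two genes.  v_series maps
    n -> V_{n,n+1}; optimal_n is the smallest n with V <= the cutoff
    (None if the series never drops that low).
    """

    ranking: list[str]
    tied_top_pair: tuple[str, str]
    exclusion_order: list[str]
    m_trajectory: list[dict[str, float]]
    final_pair_m: float
    v_series: dict[int, float] = field(default_factory=dict)
    optimal_n: int | None = None

    def m_table(self) -> pd.DataFrame:
        rows = []
        for round_no, ms in enumerate(self.m_trajectory):
            for gene, m in ms.items():
                rows.append({"round": round_no, "gene": gene, "m": m})
        return pd.DataFrame(rows)

    def v_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"n": n, "v": v} for n, v in sorted(self.v_series.items())]
        )

    def summary(self) -> dict:
        return {
            "ranking": self.ranking,
            "tied_top_pair": list(self.tied_top_pair),
            "final_pair_m": self.final_pair_m,
            "v_series": {str(n): v for n, v in sorted(self.v_series.items())},
            "optimal_n": self.optimal_n,
        }


def pairwise_v(rq, gene_j: str, gene_k: str) -> float:
    """sd (ddof=1) over common samples of log2(rq_j / rq_k)."""
    df = _as_frame(rq)
    both = df.loc[[gene_j, gene_k]].dropna(axis=1)
    if both.shape[1] < 2:
        raise GeNormError(
            f"genes {gene_j}/{gene_k}: need >= 2 common samples, "
            f"have {both.shape[1]}"
        )
    ratios = np.log2(both.loc[gene_j].to_numpy() / both.loc[gene_k].to_numpy())
    return float(np.std(ratios, ddof=1))


def m_values(rq, genes=None) -> dict[str, float]:
    """M_j = mean over k != j of pairwise_v(j, k).

    With exactly two genes M equals their mutual V for both; that value
    cannot rank them (flagged by the caller).
    """
    df = _as_frame(rq)
    genes = list(genes) if genes is not None else list(df.index)
    if len(genes) < 2:
        raise GeNormError("M values need >= 2 genes")
    v = {}
    for j, k in combinations(genes, 2):
        v[(j, k)] = v[(k, j)] = pairwise_v(df, j, k)
    return {
        j: float(np.mean([v[(j, k)] for k in genes if k != j])) for j in genes
    }


def stepwise_ranking(rq, log: list | None = None) -> GeNormResult:
    """Rank genes by iterative exclusion of the least stable (highest M) gene.

    Samples with any missing gene are dropped (complete-case analysis); ties
    on M break lexicographically by gene id, which is logged.
    """
    df = _complete_cases(_as_frame(rq), log)
    if df.shape[0] < 3:
        raise GeNormError("stepwise ranking needs >= 3 genes")
    if df.shape[1] < 3:
        raise GeNormError(
            f"need >= 3 complete-case samples, have {df.shape[1]}"
        )
    remaining = list(df.index)
    exclusion: list[str] = []
    trajectory: list[dict[str, float]] = []
    while len(remaining) > 2:
        ms = m_values(df, remaining)
        trajectory.append(ms)
        worst_m = max(ms.values())
        candidates = sorted(g for g, m in ms.items() if m == worst_m)
        if len(candidates) > 1 and log is not None:
            log.append(
                f"geNorm: tie at M={worst_m:.6g} among {candidates}; "
                f"excluding {candidates[0]} (lexicographic)"
            )
        worst = candidates[0]
        exclusion.append(worst)
        remaining.remove(worst)
    final_pair = tuple(sorted(remaining))
    final_m = pairwise_v(df, *final_pair)
    trajectory.append({g: final_m for g in final_pair})
    ranking = list(final_pair) + list(reversed(exclusion))
    return GeNormResult(
        ranking=ranking,
        tied_top_pair=final_pair,
        exclusion_order=exclusion,
        m_trajectory=trajectory,
        final_pair_m=final_m,
    )


def optimal_n_from_series(v_series: dict[int, float], cutoff: float = DEFAULT_V_CUTOFF) -> int | None:
    """Smallest n with V_{n,n+1} <= cutoff, or None when the series never drops below."""
    return next((n for n, v in sorted(v_series.items()) if v <= cutoff), None)


def pairwise_variation_series(
    rq, ranking, cutoff: float = DEFAULT_V_CUTOFF
) -> tuple[dict[int, float], int | None]:
    """V_{n,n+1} between successive normalization factors, n = 2..K-1.

    NF_n(s) is the geometric mean over the top-n ranked genes of rq at
    sample s; V_{n,n+1} is the sd (ddof=1) over samples of
    log2(NF_n / NF_{n+1}).  Also returns the smallest n with V <= cutoff,
    or None if the series never reaches it ("none" in reports).  The cutoff
    is the conventional 0.15 guideline, not a hard rule.
    """
    df = _complete_cases(_as_frame(rq))
    ranking = [g for g in ranking if g in df.index]
    if len(ranking) < 3:
        raise GeNormError("V series needs a ranking of >= 3 genes")
    logs = np.log2(df.loc[ranking].to_numpy())
    v_series: dict[int, float] = {}
    for n in range(2, len(ranking)):
        nf_n = logs[:n].mean(axis=0)
        nf_n1 = logs[: n + 1].mean(axis=0)
        v_series[n] = float(np.std(nf_n - nf_n1, ddof=1))
    return v_series, optimal_n_from_series(v_series, cutoff)


def genorm_full(rq, cutoff: float = DEFAULT_V_CUTOFF, log: list | None = None) -> GeNormResult:
    """Run the full geNorm analysis: stepwise ranking plus the V series."""
    result = stepwise_ranking(rq, log=log)
    v_series, optimal = pairwise_variation_series(rq, result.ranking, cutoff)
    result.v_series = v_series
    result.optimal_n = optimal
    return result
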