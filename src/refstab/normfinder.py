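"""Model-based reference-gene stability (NormFinder-style).

Works on y = log2(relative quantity).  With candidate genes i = 1..k,
sample groups g = 1..G and samples j within group g, the model separates

* intragroup variation sigma_ig — the within-group scatter of gene i after
  removing gene and sample main effects, and
* intergroup variation d_ig — the systematic deviation of gene i's group-g
  mean from its overall level, after removing the group's common shift.

The stability score rho_i = mean over groups of (|d~_ig| + sqrt(sigma^2_ig/n_g))
combines a shrunken intergroup deviation d~ with the standard error of the
group mean; lower rho = more stable.  With a single group the score reduces
to the residual standard deviation sigma_i.

The estimator here is the package's own homoscedastic variant: per-sample
centering biases the naive residual variance down by (k-1)/k, so the
variance is inflated by k/(k-1); the shrinkage factor for d uses
gamma^2 / (gamma^2 + sigma^2_ig/n_g) with gamma^2 the variance of the raw
d's in excess of their mean sampling variance, floored at zero.  It is
validated by parameter-recovery simulation rather than by matching any
particular implementation's numerics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NormFinderResult", "normfinder_stability"]


class NormFinderError(ValueError):
    pass


@dataclass
class NormFinderResult:
    """Per-gene stability rho with the per-(gene, group) decomposition."""

    rho: pd.Series
    ranking: list[str]
    groups: list[str]
    sigma: pd.DataFrame       # gene x group intragroup sd
    d_raw: pd.DataFrame       # gene x group intergroup deviation (log2)
    d_shrunk: pd.DataFrame

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame({"gene": self.rho.index, "rho": self.rho.values})
        out["rank"] = out["rho"].rank(method="min").astype(int)
        for g in self.groups:
            out[f"sigma_{g}"] = self.sigma[g].reindex(out["gene"]).values
            out[f"d_{g}"] = self.d_shrunk[g].reindex(out["gene"]).values
        return out.sort_values("rho").reset_index(drop=True)

    def best_gene(self) -> str:
        return self.ranking[0]

    def best_pair(self) -> tuple[str, str]:
        """Best two-gene combination.

        Prefers the lowest-mean-rho pair whose shrunken intergroup deviations
        have opposite signs in every group (their biases partly cancel in a
        normalization factor); falls back to the overall lowest-rho pair.
        """
        genes = self.ranking[: min(5, len(self.ranking))]
        best = None
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = genes[i], genes[j]
                opposite = all(
                    self.d_shrunk.loc[a, g] * self.d_shrunk.loc[b, g] <= 0
                    for g in self.groups
                )
                score = (self.rho[a] + self.rho[b]) / 2
                key = (not opposite, score)
                if best is None or key < best[0]:
                    best = (key, (a, b))
        return best[1]


def normfinder_stability(
    rq,
    groups: pd.Series | None = None,
    use_groups: bool = True,
    variance_correction: bool = True,
    log: list | None = None,
) -> NormFinderResult:
    """Estimate NormFinder-style stability for every gene in ``rq``.

    ``rq`` is an RQMatrix or gene x sample DataFrame (complete cases only;
    samples with missing genes are dropped with a log entry).  ``groups``
    maps sample id -> group label; ``use_groups=False`` (or groups=None)
    pools everything into one group, where rho_i is simply the residual sd
    of gene i.  ``variance_correction`` toggles the k/(k-1) inflation.
    """
    df = rq.rq if hasattr(rq, "rq") else rq
    incomplete = [s for s in df.columns if df[s].isna().any()]
    if incomplete:
        if log is not None:
            log.append(f"NormFinder: dropped incomplete samples {incomplete}")
        df = df.drop(columns=incomplete)
    k = df.shape[0]
    if k < 3:
        raise NormFinderError("NormFinder needs >= 3 genes (sample centering degenerate)")

    if groups is None or not use_groups:
        grouping = pd.Series("all", index=df.columns)
    else:
        grouping = groups.reindex(df.columns)
        if grouping.isna().any():
            missing = list(grouping[grouping.isna()].index)
            raise NormFinderError(f"samples without group labels: {missing}")
    group_names = sorted(grouping.unique())
    sizes = grouping.value_counts()
    if use_groups and groups is not None:
        small = [g for g in group_names if sizes[g] < 2]
        if small:
            raise NormFinderError(f"groups with a single sample: {small}")

    y = np.log2(df.to_numpy(float))
    genes = list(df.index)
    inflation = k / (k - 1) if variance_correction else 1.0

    gene_group_mean = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    sigma2 = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    n_g = {}
    for g in group_names:
        cols = np.flatnonzero((grouping == g).to_numpy())
        sub = y[:, cols]
        n = sub.shape[1]
        n_g[g] = n
        gene_mean = sub.mean(axis=1, keepdims=True)      # ybar_ig
        sample_mean = sub.mean(axis=0, keepdims=True)    # ybar_gj
        grand = sub.mean()                               # ybar_g
        resid = sub - gene_mean - sample_mean + grand
        if n > 1:
            var = inflation * (resid**2).sum(axis=1) / (n - 1)
        else:
            var = np.zeros(k)
        gene_group_mean[g] = gene_mean.ravel()
        sigma2[g] = np.maximum(var, 0.0)

    # intergroup deviation: gene-by-group interaction of the group means
    ybar_ig = gene_group_mean.to_numpy(float)
    d_raw = ybar_ig - ybar_ig.mean(axis=1, keepdims=True)
    d_raw = d_raw - d_raw.mean(axis=0, keepdims=True)
    d_raw_df = pd.DataFrame(d_raw, index=genes, columns=group_names)

    sampling_var = sigma2.to_numpy(float) / np.array([n_g[g] for g in group_names])
    if len(group_names) > 1:
        gamma2 = float(np.var(d_raw, ddof=1)) - float(sampling_var.mean())
        if gamma2 < 0 and log is not None:
            log.append(f"NormFinder: gamma^2 estimate {gamma2:.4g} clamped to 0")
        gamma2 = max(0.0, gamma2)
        shrink = gamma2 / (gamma2 + sampling_var) if gamma2 > 0 else np.zeros_like(sampling_var)
        d_shrunk = d_raw * shrink
        rho = (np.abs(d_shrunk) + np.sqrt(sampling_var)).mean(axis=1)
    else:
        d_shrunk = np.zeros_like(d_raw)
        rho = np.sqrt(sigma2.to_numpy(float)).ravel()

    rho_s = pd.Series(rho, index=genes, name="rho")
    ranking = list(rho_s.sort_values(kind="stable").index)
    return NormFinderResult(
        rho=rho_s,
        ranking=ranking,
        groups=group_names,
        sigma=sigma2.apply(np.sqrt),
        d_raw=d_raw_df,
        d_shrunk=pd.DataFrame(d_shrunk, index=genes, columns=group_names),
    )
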