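"""Normalization factors, cross-method consensus, and target-gene validation.

A normalization factor (NF) is the per-sample geometric mean of a chosen
reference-gene set's relative quantities.  NF2(S) denotes the NF built from
the two most stable genes, NF2(U) from the two most unstable ones; comparing
a target gene's expression normalized by each exposes how much the reference
choice distorts the biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationFactor",
    "ValidationReport",
    "make_nf",
    "consensus",
    "validate_target",
]


class ValidationError(ValueError):
    pass


@dataclass
class NormalizationFactor:
    label: str
    gene_set: list[str]
    values: pd.Series  # per sample, > 0

    def __post_init__(self) -> None:
        if (self.values <= 0).any():
            raise ValidationError(f"{self.label}: NF values must be positive")


@dataclass
class VariantValidation:
    """Target-gene results under one normalization factor."""

    nf_label: str
    normalized: pd.Series                 # per-sample normalized expression
    condition_means: dict[str, float]
    fold_change: float                    # mean(condition B) / mean(condition A)
    gene_specific_variation_pct: float    # mean within-condition CV%


@dataclass
class ValidationReport:
    target_gene: str
    condition_pair: tuple[str, str]
    variants: dict[str, VariantValidation]

    def fold_change(self, label: str) -> float:
        return self.variants[label].fold_change

    def summary(self) -> dict:
        return {
            "target_gene": self.target_gene,
            "condition_pair": list(self.condition_pair),
            "variants": {
                label: {
                    "fold_change": v.fold_change,
                    "log2_fold_change": float(np.log2(v.fold_change)),
                    "condition_means": v.condition_means,
                    "gene_specific_variation_pct": v.gene_specific_variation_pct,
                }
                for label, v in self.variants.items()
            },
        }

    def normalized_table(self) -> pd.DataFrame:
        frames = []
        for label, v in self.variants.items():
            df = v.normalized.rename("normalized_expression").reset_index()
            df.columns = ["sample", "normalized_expression"]
            df.insert(0, "nf", label)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def make_nf(rq, gene_set, label: str = "NF", log: list | None = None) -> NormalizationFactor:
    """Per-sample geometric mean of the gene set's relative quantities.

    Samples missing any gene of the set are dropped with a log entry.
    """
    df = rq.rq if hasattr(rq, "rq") else rq
    gene_set = list(gene_set)
    if not gene_set:
        raise ValidationError("NF gene set must be nonempty")
    missing = sorted(set(gene_set) - set(df.index))
    if missing:
        raise ValidationError(f"{label}: genes absent from matrix: {missing}")
    sub = df.loc[gene_set]
    bad = [s for s in sub.columns if sub[s].isna().any()]
    if bad:
        if log is not None:
            log.append(f"{label}: dropped samples missing reference values {bad}")
        sub = sub.drop(columns=bad)
    values = pd.Series(
        np.exp(np.log(sub.to_numpy(float)).mean(axis=0)), index=sub.columns, name=label
    )
    return NormalizationFactor(label=label, gene_set=gene_set, values=values)


def consensus(top_sets: dict[str, set], log: list | None = None):
    """Cross-method consensus of top reference-gene sets.

    ``top_sets`` maps method name -> its top gene set.  Returns the sorted
    intersection and the full Venn partition (mapping each method-name
    combination, joined by '&', to the genes exclusive to exactly those
    methods).  An empty intersection is a warning, not an error.
    """
    if len(top_sets) < 2:
        raise ValidationError("consensus needs >= 2 methods")
    methods = sorted(top_sets)
    sets = {m: set(top_sets[m]) for m in methods}
    inter = set.intersection(*sets.values())
    if not inter and log is not None:
        log.append("consensus: empty intersection of method top sets")
    venn: dict[str, list[str]] = {}
    for r in range(1, len(methods) + 1):
        for combo in combinations(methods, r):
            inside = set.intersection(*(sets[m] for m in combo))
            outside = set.union(
                *(sets[m] for m in methods if m not in combo), set()
            )
            exclusive = inside - outside
            if exclusive:
                venn["&".join(combo)] = sorted(exclusive)
    return sorted(inter), venn


def validate_target(
    rq_target: pd.Series,
    nf_variants,
    conditions: pd.Series,
    condition_pair: tuple[str, str],
    target_gene: str = "target",
) -> ValidationReport:
    """Quantify a target gene under alternative normalization factors.

    For each NF variant: normalized expression = rq_target / NF per sample;
    the fold change is mean(condition B)/mean(condition A) over the declared
    ``condition_pair``; the average gene-specific variation is the mean over
    conditions of the within-condition CV of normalized expression, in
    percent.  Every condition must contribute >= 2 samples.
    """
    cond_a, cond_b = condition_pair
    variants: dict[str, VariantValidation] = {}
    for nf in nf_variants:
        common = rq_target.dropna().index.intersection(nf.values.index)
        norm = (rq_target.loc[common] / nf.values.loc[common]).astype(float)
        labels = conditions.reindex(common)
        means: dict[str, float] = {}
        cvs = []
        for cond in (cond_a, cond_b):
            vals = norm[labels == cond]
            if len(vals) < 2:
                raise ValidationError(
                    f"{nf.label}: condition {cond!r} has {len(vals)} samples (< 2)"
                )
            means[cond] = float(vals.mean())
            cvs.append(float(vals.std(ddof=1) / vals.mean()))
        variants[nf.label] = VariantValidation(
            nf_label=nf.label,
            normalized=norm,
            condition_means=means,
            fold_change=means[cond_b] / means[cond_a],
            gene_specific_variation_pct=100.0 * float(np.mean(cvs)),
        )
    return ValidationReport(
        target_gene=target_gene, condition_pair=(cond_a, cond_b), variants=variants
    )
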