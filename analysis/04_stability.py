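"""Rank candidate reference genes by three stability methods.

Runs geNorm (stepwise M ranking plus the V_{n,n+1} series), the
NormFinder-style variance decomposition over tissue groups, and the CV
method on the relative quantities from step 03, then forms the
cross-method consensus of the top-2 sets and the Hellemans-style M/CV
quality check.  Writes the per-method tables and consensus JSON under
results/stability/.
"""

import json
from pathlib import Path

import pandas as pd

import refstab as rs
from refstab.cv_method import hellemans_qc

DATA = Path("results")
OUT = Path("results/stability")
TARGET = "TARGET"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rq = pd.read_csv(DATA / "rq.tsv", sep="\t", index_col="gene")
    meta = rs.read_sample_meta(DATA / "data" / "meta.csv")
    candidates = rq.drop(index=TARGET)

    gn = rs.genorm_full(candidates)
    gn.m_table().to_csv(OUT / "genorm_m.tsv", sep="\t", index=False)
    gn.v_table().to_csv(OUT / "genorm_v.tsv", sep="\t", index=False)
    (OUT / "genorm.json").write_text(json.dumps(gn.summary(), indent=2))
    print(f"geNorm: best pair {'/'.join(gn.tied_top_pair)} "
          f"(M = {gn.final_pair_m:.3f}), V2/3 = {gn.v_series[2]:.3f}, "
          f"optimal n = {gn.optimal_n}")

    groups = meta.group_of().reindex(candidates.columns)
    nf = rs.normfinder_stability(candidates, groups=groups)
    nf.table().to_csv(OUT / "normfinder.tsv", sep="\t", index=False)
    print(f"NormFinder: best gene {nf.best_gene()} "
          f"(rho = {nf.rho.min():.3f}), best pair {'/'.join(nf.best_pair())}")

    cv = rs.cv_stability(candidates)
    cv.table().to_csv(OUT / "cv.tsv", sep="\t", index=False)
    best_cv = cv.per_gene.iloc[0]
    print(f"CV method: best gene {best_cv['gene']} (CV = {best_cv['cv']:.3f})")

    qc = hellemans_qc(
        gn.m_trajectory[0], cv.per_gene.set_index("gene")["cv"],
        panel="heterogeneous",
    )
    qc.to_csv(OUT / "hellemans_qc.tsv", sep="\t", index=False)
    print(f"quality guideline (heterogeneous panel M<=1, CV<=0.5): "
          f"{int(qc['pass'].sum())}/{len(qc)} genes pass")

    top = {
        "genorm": set(gn.ranking[:2]),
        "normfinder": set(nf.ranking[:2]),
        "cv": set(cv.ranking[:2]),
    }
    inter, venn = rs.consensus(top)
    (OUT / "consensus.json").write_text(json.dumps(
        {"top_sets": {m: sorted(s) for m, s in top.items()},
         "intersection": inter, "venn": venn}, indent=2))
    print(f"consensus of top-2 sets: {inter}")
    print(f"wrote per-method tables and consensus under {OUT}/")


if __name__ == "__main__":
    main()
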