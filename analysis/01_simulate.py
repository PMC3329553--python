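"""Simulate the multi-tissue reference-gene survey.

Generates the study-like dataset — 10 candidate reference genes plus one
seasonally/tissue-regulated target across 6 tissue groups, 2 biological x 3
technical replicates — and writes the replicate-level Cq table, the sample
metadata and the ground-truth record under results/data/.
"""

import json
from pathlib import Path

import refstab as rs

OUT = Path("results/data")
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = rs.study_like_config(seed=SEED)
    table, meta, truth = rs.simulate_cq(config)
    rs.write_cq_table(table, OUT / "cq.csv")
    meta.data.to_csv(OUT / "meta.csv", index=False)
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    cq = table.data["cq"]
    print(f"simulated {len(table)} reactions: {len(table.genes)} genes x "
          f"{len(table.samples)} samples x {config.n_bio_rep} bio x "
          f"{config.n_tech_rep} tech replicates")
    print(f"observed Cq range: {cq.min():.1f} - {cq.max():.1f}")
    print(f"wrote {OUT}/cq.csv, meta.csv, truth.json (seed {SEED})")


if __name__ == "__main__":
    main()
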