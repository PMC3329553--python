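"""Synthetic RT-qPCR data with known ground truth.

Real Cq data behind reference-gene studies are rarely published, so every
stage of the workflow is exercised on simulated data whose stability
structure is known by construction.  The generative model works on the
log2-quantity scale and is exactly invertible by the efficiency-corrected
ΔCq transform:

* true log2 quantity of gene g in biological sample j:
  ``x_gj = b_j + d_g,group(j) + eps_gj`` with sample (loading) effect
  ``b_j ~ N(0, sample_effect_sd^2)`` and biological noise
  ``eps_gj ~ N(0, sigma_g^2)``;
* observed Cq of technical replicate r:
  ``Cq_gjr = base_cq_g - x_gj * ln(2)/ln(A_g) + tau_gjr`` with
  ``tau ~ N(0, tech_noise_sd^2)`` on the cycle scale.

Gaussian noise lives on the log2 scale for biology and on the Cq scale for
technical replicates.  ``d_g,group`` are systematic group effects (log2
units) — zero for an ideally stable reference gene.  Each biological
replicate is an independent draw of b and eps (a separate RNA preparation).

The default "study-like" preset emulates a tree-tissue survey: 10 candidate
reference genes plus one target across 6 sample groups (leaf, three branch
periderm ages, dormant branch periderm, cork), 2 biological x 3 technical
replicates, amplification factors in [1.84, 1.99] and base Cq in [15, 31].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .qpcr_data import CqTable, SampleMeta, LONG_COLUMNS
from .efficiency import AmplificationCurve

__all__ = [
    "GeneSpec",
    "SimulationConfig",
    "simulate_cq",
    "simulate_curves",
    "study_like_config",
    "two_season_config",
    "normfinder_recovery_config",
    "designed_stability",
    "CYCLES_PER_LOG2",
]

#: cycles per doubling for a gene with amplification factor A: ln2/lnA
def CYCLES_PER_LOG2(amp_factor: float) -> float:
    return float(np.log(2.0) / np.log(amp_factor))


@dataclass
class GeneSpec:
    """Ground-truth parameters of one simulated gene."""

    name: str
    base_cq: float
    amp_factor: float
    noise_sd: float = 0.0                       # log2 units
    group_effects: dict[str, float] = field(default_factory=dict)  # log2 units

    def __post_init__(self) -> None:
        if not 1.0 < self.amp_factor <= 2.2:
            raise ValueError(f"{self.name}: amp_factor outside (1, 2.2]")
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd < 0")


@dataclass
class SimulationConfig:
    genes: list[GeneSpec]
    groups: dict[str, int]                      # group label -> number of samples
    n_bio_rep: int = 2
    n_tech_rep: int = 3
    tech_noise_sd: float = 0.0                  # cycles
    sample_effect_sd: float = 0.0               # log2 units
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.groups.values()):
            raise ValueError("group sizes must be >= 1")
        if self.n_bio_rep < 1 or self.n_tech_rep < 1:
            raise ValueError("replicate counts must be >= 1")

    def truth(self) -> dict:
        return {
            "genes": [asdict(g) for g in self.genes],
            "groups": dict(self.groups),
            "n_bio_rep": self.n_bio_rep,
            "n_tech_rep": self.n_tech_rep,
            "tech_noise_sd": self.tech_noise_sd,
            "sample_effect_sd": self.sample_effect_sd,
            "seed": self.seed,
        }


def simulate_cq(config: SimulationConfig):
    """Draw a CqTable + SampleMeta + truth record from the generative model.

    Deterministic under a fixed config (including seed).  Sample ids are
    ``<group>_<i>``; every (sample, bio_rep) pair gets independent sample
    and biological effects, technical replicates independent Cq noise.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    meta_rows = []
    for group, size in config.groups.items():
        for i in range(1, size + 1):
            sample = f"{group}_{i}"
            meta_rows.append({"sample": sample, "group": group, "collection": None})
            for bio in range(1, config.n_bio_rep + 1):
                b = rng.normal(0.0, config.sample_effect_sd) if config.sample_effect_sd else 0.0
                for gene in config.genes:
                    eps = rng.normal(0.0, gene.noise_sd) if gene.noise_sd else 0.0
                    x = b + gene.group_effects.get(group, 0.0) + eps
                    center = gene.base_cq - x * CYCLES_PER_LOG2(gene.amp_factor)
                    for tech in range(1, config.n_tech_rep + 1):
                        tau = rng.normal(0.0, config.tech_noise_sd) if config.tech_noise_sd else 0.0
                        rows.append(
                            (sample, gene.name, "1", bio, tech, center + tau)
                        )
    table = CqTable(pd.DataFrame(rows, columns=LONG_COLUMNS))
    meta = SampleMeta(pd.DataFrame(meta_rows))
    return table, meta, config.truth()


def simulate_curves(
    amp_factor: float,
    n_curves: int = 1,
    f_max: float = 10.0,
    baseline: float = 0.5,
    noise_sd: float = 0.0,
    cycles: int = 40,
    c_half: float = 25.0,
    seed: int = 0,
    gene_id: str = "sim",
    sample_id: str = "sim",
) -> list[AmplificationCurve]:
    """Simulate logistic amplification curves with steepness tied to efficiency.

    F(c) = baseline + f_max / (1 + exp(-(c - c_half)/s)) with s = 1/ln(A),
    so the early exponential phase grows by a factor A per cycle.  Gaussian
    noise of sd ``noise_sd * f_max`` is added per cycle.
    """
    if amp_factor <= 1.0:
        raise ValueError("amp_factor must exceed 1")
    rng = np.random.default_rng(seed)
    s = 1.0 / np.log(amp_factor)
    c = np.arange(1, cycles + 1, dtype=float)
    clean = baseline + f_max / (1.0 + np.exp(-(c - c_half) / s))
    curves = []
    for i in range(n_curves):
        noise = rng.normal(0.0, noise_sd * f_max, size=cycles) if noise_sd else 0.0
        curves.append(
            AmplificationCurve(
                well_id=f"W{i + 1}",
                gene_id=gene_id,
                sample_id=sample_id,
                fluorescence=clean + noise,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# presets

#: designed biological log2 noise, ascending: the first two genes dominate.
#: the extreme base-Cq genes are low-noise so the observed Cq range stays
#: near the designed [15, 31] span.
_STUDY_SIGMAS = [0.12, 0.15, 0.25, 0.30, 0.35, 0.45, 0.55, 0.70, 0.90, 1.10]
_STUDY_AMPS = [1.93, 1.95, 1.92, 1.98, 1.91, 1.95, 1.84, 1.94, 1.92, 1.99]
_STUDY_BASE_CQ = [15.5, 30.5, 18.5, 17.0, 24.0, 21.5, 26.0, 23.0, 22.0, 20.0]
STUDY_GROUPS = ["leaf", "periderm1", "periderm2", "periderm3", "dormant", "cork"]


def study_like_config(seed: int = 0, samples_per_group: int = 3) -> SimulationConfig:
    """Preset emulating a multi-tissue reference-gene survey.

    10 candidate genes (RG01..RG10, noise ascending so RG01/RG02 are the
    designed stable pair) plus a target gene with a real group effect, over
    6 tissue groups, 2 biological x 3 technical replicates.  Amplification
    factors span [1.84, 1.99] and base Cq [15, 31]; the least stable
    candidates also carry modest tissue effects, as real panels do.
    """
    genes = []
    for i, (sigma, amp, base) in enumerate(
        zip(_STUDY_SIGMAS, _STUDY_AMPS, _STUDY_BASE_CQ), start=1
    ):
        effects = {}
        if i >= 7:  # unstable tail: systematic tissue effects
            sign = 1.0 if i % 2 else -1.0
            effects = {"cork": sign * 0.8, "dormant": -sign * 0.6}
        genes.append(
            GeneSpec(
                name=f"RG{i:02d}", base_cq=base, amp_factor=amp,
                noise_sd=sigma, group_effects=effects,
            )
        )
    genes.append(
        GeneSpec(
            name="TARGET", base_cq=26.0, amp_factor=1.94, noise_sd=0.3,
            group_effects={"cork": 2.0, "periderm3": 1.0, "dormant": -1.0},
        )
    )
    return SimulationConfig(
        genes=genes,
        groups={g: samples_per_group for g in STUDY_GROUPS},
        n_bio_rep=2,
        n_tech_rep=3,
        tech_noise_sd=0.15,
        sample_effect_sd=0.25,
        seed=seed,
    )


def two_season_config(seed: int = 0, samples_per_group: int = 8) -> SimulationConfig:
    """Two-season validation design with a null target (true fold change 1).

    Two stable reference genes (sigma 0.1, no seasonal effect), two unstable
    seasonally co-regulated ones (sigma 0.8 with same-direction log2 shifts
    of 1.0 and 0.6 between seasons, so the bias survives their geometric
    mean), six mid-noise fillers, and a target gene with zero true seasonal
    effect.  Normalizing by the unstable pair therefore distorts the
    target's fold change while the stable pair recovers it.
    """
    genes = [
        GeneSpec("STB1", 20.0, 1.94, 0.10),
        GeneSpec("STB2", 19.0, 1.92, 0.10),
    ]
    for i, sigma in enumerate([0.30, 0.35, 0.40, 0.45, 0.50, 0.55], start=1):
        genes.append(GeneSpec(f"MID{i}", 21.0 + i, 1.93, sigma))
    genes += [
        GeneSpec("UNS1", 24.0, 1.90, 0.80, {"spring": 1.0, "summer": -1.0}),
        GeneSpec("UNS2", 25.0, 1.96, 0.80, {"spring": 0.6, "summer": -0.6}),
        GeneSpec("TARGET", 26.0, 1.94, 0.20),
    ]
    return SimulationConfig(
        genes=genes,
        groups={"spring": samples_per_group, "summer": samples_per_group},
        n_bio_rep=1,
        n_tech_rep=1,
        tech_noise_sd=0.0,
        sample_effect_sd=0.4,
        seed=seed,
    )


def normfinder_recovery_config(seed: int = 0, samples_per_group: int = 20) -> SimulationConfig:
    """Two-group recovery design with known intra/intergroup structure.

    10 genes with ascending within-group noise; genes 3..10 carry paired
    opposite-signed group effects (so effects sum to zero per group and the
    designed deviations survive the estimator's double centering).  The
    designed stability score is |d| + sigma/sqrt(n) per gene.
    """
    sigmas = [0.10, 0.12, 0.25, 0.30, 0.40, 0.50, 0.60, 0.75, 0.90, 1.10]
    deltas = [0.0, 0.0, 0.20, 0.20, 0.40, 0.40, 0.70, 0.70, 1.10, 1.10]
    genes = []
    for i, (sigma, delta) in enumerate(zip(sigmas, deltas), start=1):
        sign = 1.0 if i % 2 else -1.0   # pair up so effects cancel per group
        effects = {"g1": sign * delta, "g2": -sign * delta} if delta else {}
        genes.append(
            GeneSpec(
                name=f"G{i:02d}", base_cq=18.0 + i, amp_factor=1.93,
                noise_sd=sigma, group_effects=effects,
            )
        )
    return SimulationConfig(
        genes=genes,
        groups={"g1": samples_per_group, "g2": samples_per_group},
        n_bio_rep=1,
        n_tech_rep=1,
        tech_noise_sd=0.0,
        sample_effect_sd=0.5,
        seed=seed,
    )


def designed_stability(config: SimulationConfig) -> pd.Series:
    """Ground-truth stability score |d| + sigma/sqrt(n_g), averaged over groups.

    Mirrors the model-based score: smaller = more stable by design.
    """
    scores = {}
    for gene in config.genes:
        per_group = []
        for group, n in config.groups.items():
            d = gene.group_effects.get(group, 0.0)
            per_group.append(abs(d) + gene.noise_sd / np.sqrt(n))
        scores[gene.name] = float(np.mean(per_group))
    return pd.Series(scores, name="designed_stability")
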