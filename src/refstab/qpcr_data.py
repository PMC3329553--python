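"""Cq-level data handling for RT-qPCR experiments.

The quantification cycle (Cq) is the fractional PCR cycle at which a
reaction's fluorescence crosses a detection threshold; lower Cq means more
template.  This module holds the replicate-level Cq data model, delimited-text
readers/writers, technical-replicate aggregation, and inter-plate calibration
against a shared calibrator sample.

Cq values that the instrument could not call ("Undetermined") are kept as a
distinct missing marker (NaN internally), never coerced to a number.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CqTable",
    "SampleMeta",
    "LONG_COLUMNS",
    "UNDETERMINED_MARKERS",
    "read_cq_table",
    "write_cq_table",
    "read_sample_meta",
    "aggregate_technical",
    "interplate_calibrate",
]

#: canonical long-form column order
LONG_COLUMNS = ["sample", "gene", "plate", "bio_rep", "tech_rep", "cq"]

#: cell contents (case-insensitive, stripped) treated as an undetermined Cq
UNDETERMINED_MARKERS = {"undetermined", "undet", "na", "n/a", "nan", ""}

#: hard validity bound on any numeric Cq (cycles)
CQ_MAX = 45.0

#: default technical-replicate concordance threshold (cycles)
DEFAULT_SD_THRESHOLD = 0.5


class CqDataError(ValueError):
    """Raised for malformed or inconsistent Cq-level input."""


@dataclass
class CqTable:
    """Replicate-level Cq measurements in long form.

    ``data`` holds one row per reaction with columns
    ``sample, gene, plate, bio_rep, tech_rep, cq``; ``cq`` is a float where
    NaN encodes an undetermined reaction.  The replicate key
    (sample, gene, plate, bio_rep, tech_rep) is unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise CqDataError(f"CqTable missing columns: {missing}")
        df = df[LONG_COLUMNS].copy()
        df["bio_rep"] = df["bio_rep"].astype(int)
        df["tech_rep"] = df["tech_rep"].astype(int)
        df["cq"] = df["cq"].astype(float)
        key = ["sample", "gene", "plate", "bio_rep", "tech_rep"]
        dup = df.duplicated(subset=key)
        if dup.any():
            offender = df.loc[dup.idxmax(), key].tolist()
            raise CqDataError(f"duplicate replicate key: {tuple(offender)}")
        cq = df["cq"].to_numpy()
        bad = np.isfinite(cq) & ((cq <= 0) | (cq > CQ_MAX))
        if bad.any():
            raise CqDataError(
                f"Cq out of (0, {CQ_MAX}]: {sorted(cq[bad])[:5]}"
            )
        if (df["bio_rep"] < 1).any() or (df["tech_rep"] < 1).any():
            raise CqDataError("replicate indices must be >= 1")
        self.data = df.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SampleMeta:
    """Per-sample annotations: experimental group and optional collection label."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("sample", "group"):
            if col not in df.columns:
                raise CqDataError(f"metadata missing column {col!r}")
        if "collection" not in df.columns:
            df["collection"] = None
        if df["sample"].duplicated().any():
            dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise CqDataError(f"duplicate metadata for samples: {dups}")
        if df["group"].astype(str).str.strip().eq("").any():
            raise CqDataError("empty group label in metadata")
        self.data = df[["sample", "group", "collection"]].reset_index(drop=True)

    def group_of(self) -> pd.Series:
        """Series mapping sample id -> group label."""
        return self.data.set_index("sample")["group"]

    def require_samples(self, samples) -> None:
        missing = sorted(set(samples) - set(self.data["sample"]))
        if missing:
            raise CqDataError(f"samples without metadata: {missing}")


def _parse_cq_cell(value, row_no: int) -> float:
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().lower()
    if text in UNDETERMINED_MARKERS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise CqDataError(
            f"row {row_no}: unrecognized Cq value {value!r}"
        ) from None


def read_cq_table(path, dialect: str = "long", sep: str | None = None) -> CqTable:
    """Read a Cq table from delimited text.

    ``dialect='long'`` expects the header sample,gene,plate,bio_rep,tech_rep,cq
    (plate/bio_rep/tech_rep default to 1 when absent).  ``dialect='wide'``
    expects genes in the first column and one column per sample; wide input is
    melted to long form with plate and replicate indices of 1.  The cells
    "Undetermined"/"NA"/empty become the undetermined marker.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if dialect == "wide":
        gene_col = raw.columns[0]
        long = raw.melt(id_vars=[gene_col], var_name="sample", value_name="cq")
        long = long.rename(columns={gene_col: "gene"})
        long["plate"] = "1"
        long["bio_rep"] = 1
        long["tech_rep"] = 1
    elif dialect == "long":
        long = raw.rename(columns=str.lower)
        for col, default in (("plate", "1"), ("bio_rep", 1), ("tech_rep", 1)):
            if col not in long.columns:
                long[col] = default
        missing = [c for c in ("sample", "gene", "cq") if c not in long.columns]
        if missing:
            raise CqDataError(f"{path}: long input missing columns {missing}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    long["cq"] = [
        _parse_cq_cell(v, i + 2) for i, v in enumerate(long["cq"])
    ]
    return CqTable(long[LONG_COLUMNS])


def write_cq_table(table: CqTable, path, sep: str = ",") -> None:
    """Write a CqTable; undetermined Cq serializes as 'Undetermined'."""
    df = table.data.copy()
    df["cq"] = df["cq"].map(
        lambda v: "Undetermined" if not np.isfinite(v) else repr(float(v))
    )
    df.to_csv(path, sep=sep, index=False)


def read_sample_meta(path, sep: str | None = None) -> SampleMeta:
    """Read sample metadata CSV with header sample,group[,collection]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str).rename(columns=str.lower)
    return SampleMeta(df)


def aggregate_technical(
    table: CqTable, sd_threshold: float = DEFAULT_SD_THRESHOLD
) -> pd.DataFrame:
    """Collapse technical replicates to per-(sample, gene, bio_rep) means.

    Returns columns sample, gene, bio_rep, cq_mean, cq_sd, n_tech, flagged.
    The mean and sample standard deviation (ddof=1) cover numeric replicates
    only; undetermined replicates are excluded from the mean but counted in
    n_tech.  A group whose replicates are all undetermined aggregates to an
    undetermined (NaN) mean.  Single-replicate groups report sd 0 and are
    never flagged; otherwise flagged is true iff cq_sd > sd_threshold.
    """
    rows = []
    for (sample, gene, bio), grp in table.data.groupby(
        ["sample", "gene", "bio_rep"], sort=True
    ):
        cq = grp["cq"].to_numpy(float)
        numeric = cq[np.isfinite(cq)]
        n_tech = len(cq)
        if numeric.size == 0:
            mean, sd = np.nan, np.nan
        elif numeric.size == 1:
            mean, sd = float(numeric[0]), 0.0
        else:
            mean = float(numeric.mean())
            sd = float(numeric.std(ddof=1))
        flagged = bool(numeric.size > 1 and sd > sd_threshold)
        rows.append((sample, gene, bio, mean, sd, n_tech, flagged))
    return pd.DataFrame(
        rows,
        columns=["sample", "gene", "bio_rep", "cq_mean", "cq_sd", "n_tech", "flagged"],
    )


def write_aggregated(agg: pd.DataFrame, path) -> None:
    agg.to_csv(path, sep="\t", index=False)


def interplate_calibrate(table: CqTable, calibrator_sample: str) -> CqTable:
    """Align Cq values across plates using a calibrator sample.

    For each gene g and plate p every Cq of g on p is shifted by
    ``-(Cq_cal(g, p) - mean over plates of Cq_cal(g, .))`` where Cq_cal is the
    mean numeric Cq of the calibrator sample.  Centering on the across-plate
    mean (rather than any particular plate) makes the result invariant to
    plate ordering; calibrator records themselves shift by the same rule.
    """
    df = table.data.copy()
    cal = df[(df["sample"] == calibrator_sample) & np.isfinite(df["cq"])]
    if cal.empty:
        raise CqDataError(
            f"calibrator sample {calibrator_sample!r} has no numeric Cq"
        )
    cal_mean = cal.groupby(["gene", "plate"])["cq"].mean()

    missing = []
    for (gene, plate), grp in df.groupby(["gene", "plate"]):
        if (gene, plate) not in cal_mean.index:
            missing.append((gene, plate))
    if missing:
        raise CqDataError(
            f"calibrator {calibrator_sample!r} missing for (gene, plate): "
            f"{sorted(missing)}"
        )

    gene_center = cal_mean.groupby("gene").mean()
    shift = df.apply(
        lambda r: cal_mean[(r["gene"], r["plate"])] - gene_center[r["gene"]],
        axis=1,
    )
    df["cq"] = df["cq"] - shift
    return CqTable(df)
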