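"""Amplification-efficiency estimation.

PCR efficiency is expressed as the per-cycle amplification factor
A in (1, 2.2] (perfect doubling: A = 2) or as the fractional efficiency
e = A - 1.  Two estimators are provided:

* :func:`standard_curve_efficiency` — ordinary least squares of Cq on
  log10(template quantity) over a dilution series, with A = 10**(-1/slope)
  (the convention under which a slope of -3.3219 yields A = 2).
* :func:`curve_efficiency` — a per-reaction estimate from raw
  fluorescence-vs-cycle data: baseline subtraction, a four-parameter
  logistic fit, and a log-linear regression over the best exponential-phase
  window, in the spirit of exponential-window methods such as
  Real-time PCR Miner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EfficiencyEstimate",
    "AmplificationCurve",
    "CurveFitParams",
    "StandardCurveFit",
    "CurveEfficiencyResult",
    "standard_curve_efficiency",
    "curve_efficiency",
    "summarize_efficiency",
    "read_curves",
]

#: largest physically plausible amplification factor
A_MAX = 2.2


class EfficiencyError(ValueError):
    """Raised when an efficiency estimate cannot be formed."""


@dataclass
class EfficiencyEstimate:
    """Per-gene (optionally per-tissue) amplification factor with dispersion.

    ``amp_factor`` is A; ``frac_efficiency`` is e = A - 1 (the two scales the
    field both calls "E").
    """

    gene_id: str
    context: str
    amp_factor: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if not 1.0 < self.amp_factor <= A_MAX:
            raise EfficiencyError(
                f"amplification factor {self.amp_factor:.4f} outside (1, {A_MAX}]"
            )
        if self.se < 0:
            raise EfficiencyError("standard error must be >= 0")

    @property
    def frac_efficiency(self) -> float:
        return self.amp_factor - 1.0


@dataclass
class StandardCurveFit:
    """Dilution-series fit: the estimate plus regression diagnostics."""

    estimate: EfficiencyEstimate
    slope: float
    intercept: float
    r2: float


@dataclass
class AmplificationCurve:
    """Raw fluorescence trajectory of one reaction, indexed by cycle 1..C."""

    well_id: str
    gene_id: str
    sample_id: str
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fluorescence, dtype=float)
        if f.ndim != 1 or f.size < 15:
            raise EfficiencyError("curve needs >= 15 cycles")
        if not np.all(np.isfinite(f)):
            raise EfficiencyError("non-finite fluorescence")
        self.fluorescence = f

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(1, self.fluorescence.size + 1, dtype=float)


@dataclass
class CurveFitParams:
    """Tuning knobs for :func:`curve_efficiency`.

    baseline_cycles: inclusive early-cycle window whose mean is subtracted
        (None skips baseline subtraction, for data already baselined).
    min_window: minimum length of the exponential-phase regression window.
    min_fold: signal check — late-cycle mean must exceed this multiple of the
        early (baseline-window) mean.
    fit_logistic: when False the logistic step is skipped and the window scan
        runs over all cycles (useful for pure exponential data with no
        plateau); the plateau correction is then unavailable.
    plateau_correction: divide the window log-slope by (1 - mean fitted
        F/Fmax), undoing the flattening a logistic imposes on its early phase.
    """

    baseline_cycles: tuple[int, int] | None = (3, 8)
    min_window: int = 4
    min_fold: float = 3.0
    fit_logistic: bool = True
    plateau_correction: bool = True


@dataclass
class CurveEfficiencyResult:
    well_id: str
    gene_id: str
    sample_id: str
    amp_factor: float
    cq: float
    window: tuple[int, int]
    r2: float


def standard_curve_efficiency(
    points, gene_id: str = "", context: str = "global"
) -> StandardCurveFit:
    """Estimate the amplification factor from a dilution series.

    ``points`` is an iterable of (log10_quantity, cq) pairs or a DataFrame
    with columns log10_quantity and cq.  Cq is regressed on log10 quantity;
    the slope b must be negative with |b| >= 1, and A = 10**(-1/b).  The
    standard error of A follows from the slope SE by the delta method,
    dA/db = A * ln(10) / b**2.
    """
    if isinstance(points, pd.DataFrame):
        x = points["log10_quantity"].to_numpy(float)
        y = points["cq"].to_numpy(float)
    else:
        arr = np.asarray(list(points), dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 3:
        raise EfficiencyError("standard curve needs >= 3 distinct dilution points")
    fit = stats.linregress(x, y)
    b = fit.slope
    if b >= 0 or abs(b) < 1:
        raise EfficiencyError(
            f"implausible standard curve (slope {b:.4f}); expected slope <= -1"
        )
    amp = 10.0 ** (-1.0 / b)
    se_b = 0.0 if np.isnan(fit.stderr) else fit.stderr
    se_a = amp * math.log(10.0) / b**2 * se_b
    est = EfficiencyEstimate(
        gene_id=gene_id, context=context, amp_factor=amp, se=se_a, n=len(x)
    )
    return StandardCurveFit(
        estimate=est, slope=b, intercept=fit.intercept, r2=fit.rvalue**2
    )


def _logistic(c, fb, fmax, c_half, s):
    return fb + fmax / (1.0 + np.exp(-(c - c_half) / s))


def _fit_logistic(cycles: np.ndarray, f: np.ndarray):
    fmax0 = float(f.max() - f.min())
    c0 = float(cycles[np.argmax(np.diff(f))] if f.size > 1 else cycles[-1])
    p0 = (float(f.min()), fmax0, c0, 1.5)
    try:
        popt, _ = optimize.curve_fit(
            _logistic, cycles, f, p0=p0, maxfev=20000
        )
    except RuntimeError as exc:
        resid = float(np.linalg.norm(f - _logistic(cycles, *p0)))
        raise EfficiencyError(
            f"logistic fit failed to converge (residual norm {resid:.3g})"
        ) from exc
    resid = float(np.linalg.norm(f - _logistic(cycles, *popt)))
    return popt, resid


def _window_regression(cycles, logf):
    """Slope and R^2 of ln F vs cycle over one window."""
    fit = stats.linregress(cycles, logf)
    r2 = 0.0 if np.isnan(fit.rvalue) else fit.rvalue**2
    return fit.slope, r2


def curve_efficiency(
    curve: AmplificationCurve, params: CurveFitParams | None = None
) -> CurveEfficiencyResult:
    """Per-reaction amplification factor from raw fluorescence.

    Steps: (1) subtract the mean of the configured early-cycle baseline
    window; (2) fit a four-parameter logistic by nonlinear least squares;
    (3) scan contiguous windows of length >= ``min_window`` below the
    logistic midpoint and keep the window maximizing R^2 of ln F vs cycle
    (ties broken toward the widest, then earliest window); (4) A = exp of
    the window slope (plateau-corrected when enabled); Cq = the fractional
    cycle where the fitted logistic's second derivative peaks,
    c_half - s*ln(2 + sqrt(3)).
    """
    params = params or CurveFitParams()
    cycles = curve.cycles
    f_raw = curve.fluorescence

    if params.baseline_cycles is not None:
        lo, hi = params.baseline_cycles
        base_mask = (cycles >= lo) & (cycles <= hi)
    else:
        base_mask = np.zeros_like(cycles, dtype=bool)
    early = float(f_raw[base_mask].mean()) if base_mask.any() else float(f_raw[:5].mean())
    late = float(f_raw[-3:].mean())
    if early > 0 and late < params.min_fold * early:
        raise EfficiencyError("no exponential phase (signal check failed)")
    baseline = early if params.baseline_cycles is not None else 0.0
    f = f_raw - baseline

    c_half = np.inf
    fmax = np.nan
    fb = 0.0
    s = np.nan
    if params.fit_logistic:
        (fb, fmax, c_half, s), _resid = _fit_logistic(cycles, f)
        if fmax <= 0 or s <= 0:
            raise EfficiencyError("no exponential phase (degenerate logistic)")

    usable = np.isfinite(f) & (f > 0) & (cycles < c_half)
    idx = np.flatnonzero(usable)
    best = None  # (r2, width, -start, slope, window)
    for a in range(len(idx)):
        if idx[a + params.min_window - 1 : a + params.min_window].size == 0:
            break
        for b in range(a + params.min_window - 1, len(idx)):
            win = idx[a : b + 1]
            # windows must be contiguous in cycle number
            if win[-1] - win[0] != len(win) - 1:
                break
            slope, r2 = _window_regression(cycles[win], np.log(f[win]))
            if slope <= 0:
                continue
            key = (round(r2, 12), len(win), -win[0])
            if best is None or key > best[0]:
                best = (key, slope, (int(cycles[win[0]]), int(cycles[win[-1]])), r2, win)
    if best is None:
        raise EfficiencyError("no exponential phase (no positive-slope window)")
    _, slope, window, r2, win = best

    if params.fit_logistic and params.plateau_correction:
        frac = (_logistic(cycles[win], fb, fmax, c_half, s) - fb) / fmax
        factor = 1.0 - float(np.mean(frac))
        if factor > 0.05:
            slope = slope / factor
    amp = float(np.exp(slope))

    if params.fit_logistic:
        cq = float(c_half - s * math.log(2.0 + math.sqrt(3.0)))
    else:
        cq = float(np.nan)
    return CurveEfficiencyResult(
        well_id=curve.well_id,
        gene_id=curve.gene_id,
        sample_id=curve.sample_id,
        amp_factor=amp,
        cq=cq,
        window=window,
        r2=r2,
    )


def summarize_efficiency(
    per_reaction: pd.DataFrame, by=("gene",), context_col: str | None = None
) -> list[EfficiencyEstimate]:
    """Mean per-reaction amplification factor per group.

    ``per_reaction`` needs columns gene and amp_factor (plus any grouping
    columns named in ``by``).  se = sd/sqrt(n), 0 by convention for n = 1.
    Grouping by ("gene",) alone pools all tissues into context "global".
    """
    by = list(by)
    if "gene" not in by:
        raise ValueError("grouping must include 'gene'")
    out = []
    for keys, grp in per_reaction.groupby(by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        named = dict(zip(by, keys))
        a = grp["amp_factor"].to_numpy(float)
        mean = float(a.mean())
        se = float(a.std(ddof=1) / math.sqrt(a.size)) if a.size > 1 else 0.0
        context = str(named.get(context_col, "global")) if context_col else "global"
        out.append(
            EfficiencyEstimate(
                gene_id=str(named["gene"]), context=context,
                amp_factor=mean, se=se, n=int(a.size),
            )
        )
    return out


def efficiency_table(estimates) -> pd.DataFrame:
    """Tabulate EfficiencyEstimates (gene, context, amp_factor, frac_efficiency, se, n)."""
    return pd.DataFrame(
        [
            {
                "gene": e.gene_id,
                "context": e.context,
                "amp_factor": e.amp_factor,
                "frac_efficiency": e.frac_efficiency,
                "se": e.se,
                "n": e.n,
            }
            for e in estimates
        ]
    )


def read_curves(path, sep: str | None = None) -> list[AmplificationCurve]:
    """Read amplification curves from delimited text.

    Expected columns: well, gene, sample, cycle, fluorescence.
    """
    from pathlib import Path

    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep).rename(columns=str.lower)
    curves = []
    for (well, gene, sample), grp in df.groupby(["well", "gene", "sample"], sort=True):
        grp = grp.sort_values("cycle")
        curves.append(
            AmplificationCurve(
                well_id=str(well), gene_id=str(gene), sample_id=str(sample),
                fluorescence=grp["fluorescence"].to_numpy(float),
            )
        )
    return curves
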