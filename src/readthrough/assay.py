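"""Dual-luciferase quantification: readthrough efficiency, box summaries,
transactivation fold-changes and dose-shift estimation.

Readthrough efficiency of a stop-codon context is measured with a dual
reporter: the test construct carries the context (TGA stop) between
Renilla and firefly luciferases, and its sense-codon control replaces
the stop with TGG so every ribosome reads through.  Efficiency is

    100 * (firefly/Renilla of the TGA construct)
        / (firefly/Renilla of the matched TGG control)

in percent.  Box summaries follow the R type-7 quantile convention with
whiskers at 1.5 * IQR.  Dose-response curves are summarized by
4-parameter-logistic (4PL) fits; the shift between two curves is the
ratio of their EC50s, cross-checked by a fit-free horizontal
interpolation at half-maximal response.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


def relative_activity(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``ratio`` (firefly/renilla) column; reject nonpositive readings.

    Returns a copy with rejected rows dropped; rejections are logged
    with the offending column.
    """
    out = table.copy()
    bad = (out["firefly"] <= 0) | (out["renilla"] <= 0)
    if bad.any():
        logger.warning(
            "relative_activity: rejecting %d rows with nonpositive readings",
            int(bad.sum()),
        )
    out = out.loc[~bad].copy()
    out["ratio"] = out["firefly"] / out["renilla"]
    return out


@dataclass
class BoxStats:
    """Box-whisker summary (R type-7 quantiles, 1.5*IQR whiskers)."""

    median: float
    q25: float
    q75: float
    whisker_lo: float
    whisker_hi: float
    outliers: list[float] = field(default_factory=list)


def boxplot_stats(values) -> BoxStats:
    """Summarize values with the box-plot conventions of common R figures.

    Quantiles use the type-7 (linear interpolation) convention; whiskers
    extend to the most extreme values within 1.5 * IQR beyond the box
    limits; values outside are returned as outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("boxplot_stats requires at least one value")
    q25, med, q75 = np.percentile(v, [25, 50, 75])  # numpy 'linear' = type 7
    iqr = q75 - q25
    lo_lim, hi_lim = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_lim) & (v <= hi_lim)]
    return BoxStats(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=sorted(float(x) for x in v[(v < lo_lim) | (v > hi_lim)]),
    )


@dataclass
class EfficiencyResult:
    """Per-construct readthrough efficiencies (percent) with box summary."""

    construct_id: str
    efficiencies: list[float]
    box: BoxStats

    @property
    def median(self) -> float:
        return self.box.median


def readthrough_efficiency(
    test: pd.DataFrame,
    control: pd.DataFrame,
    paired: bool = False,
) -> EfficiencyResult:
    """Compute percent readthrough of TGA test wells against TGG controls.

    By default each test replicate is divided by the *mean* control
    firefly/Renilla ratio of its batch; ``paired=True`` divides by the
    same-numbered control replicate instead.  Batches are matched via
    the ``batch`` column when present.
    """
    if control.empty:
        raise ValueError("no control (TGG) replicates provided")
    test = relative_activity(test)
    control = relative_activity(control)
    if test.empty:
        raise ValueError("no usable test replicates")
    construct = str(test["construct"].iloc[0]) if "construct" in test else "test"

    if paired:
        merged = test.merge(
            control,
            on=[c for c in ("batch", "construct", "replicate") if c in test and c in control],
            suffixes=("", "_ctrl"),
        )
        if merged.empty:
            raise ValueError("paired mode: no matching control replicates")
        eff = 100.0 * merged["ratio"] / merged["ratio_ctrl"]
    else:
        if "batch" in test.columns and "batch" in control.columns:
            ctrl_mean = control.groupby("batch")["ratio"].mean()
            eff = 100.0 * test["ratio"] / test["batch"].map(ctrl_mean)
            eff = eff.dropna()
            if eff.empty:
                raise ValueError("no control batch matches the test batches")
        else:
            eff = 100.0 * test["ratio"] / control["ratio"].mean()
    values = [float(x) for x in eff]
    return EfficiencyResult(construct, values, boxplot_stats(values))


def transactivation_fold(
    stimulated: pd.DataFrame, vehicle: pd.DataFrame
) -> tuple[float, float]:
    """Fold-change of mean relative activity, stimulated over vehicle.

    Returns ``(fold, sem)`` where the standard error combines the
    relative dispersions of the two arms.
    """
    if vehicle.empty:
        raise ValueError("missing vehicle arm")
    if stimulated.empty:
        raise ValueError("missing stimulated arm")
    s = relative_activity(stimulated)["ratio"]
    v = relative_activity(vehicle)["ratio"]
    fold = float(s.mean() / v.mean())
    rel_var = 0.0
    if len(s) > 1:
        rel_var += s.var(ddof=1) / (len(s) * s.mean() ** 2)
    if len(v) > 1:
        rel_var += v.var(ddof=1) / (len(v) * v.mean() ** 2)
    return fold, fold * math.sqrt(rel_var)


# ---------------------------------------------------------------------------
# Dose-response


@dataclass
class DoseResponseFit:
    """A 4-parameter-logistic fit to one construct's dose-response."""

    construct_id: str
    doses: np.ndarray
    responses: np.ndarray
    floor: float
    span: float
    ec50: float
    hill: float
    residual: float  # RMS residual of the fit

    @property
    def top(self) -> float:
        return self.floor + self.span

    def predict(self, dose) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return self.floor + self.span / (1.0 + (self.ec50 / d) ** self.hill)


def _4pl(logd, floor, span, logec50, hill):
    return floor + span / (1.0 + 10 ** (hill * (logec50 - logd)))


def fit_dose_response(table: pd.DataFrame, construct: str | None = None) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 dose with multi-start initialization.

    Starting EC50s are taken from the dose quartiles; the best of the
    converged starts (lowest residual) is returned.
    """
    df = table
    if construct is not None:
        df = df[df["construct"] == construct]
    elif "construct" in df.columns and df["construct"].nunique() == 1:
        construct = str(df["construct"].iloc[0])
    else:
        construct = construct or "curve"
    if df.empty:
        raise ValueError(f"no rows for construct {construct!r}")
    doses = df["dose"].to_numpy(dtype=float)
    resp = df["response"].to_numpy(dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    logd = np.log10(doses)

    lo, hi = float(resp.min()), float(resp.max())
    starts = np.percentile(logd, [25, 50, 75])
    best = None
    for s in starts:
        p0 = [lo, max(hi - lo, 1e-9), s, 1.0]
        try:
            popt, _ = curve_fit(
                _4pl,
                logd,
                resp,
                p0=p0,
                maxfev=500 * len(p0),
                xtol=1e-8,
                ftol=1e-8,
                bounds=(
                    [-np.inf, 0.0, logd.min() - 6, 0.05],
                    [np.inf, np.inf, logd.max() + 6, 20.0],
                ),
            )
        except RuntimeError:
            continue
        rms = float(np.sqrt(np.mean((_4pl(logd, *popt) - resp) ** 2)))
        if best is None or rms < best[1]:
            best = (popt, rms)
    if best is None:
        raise ValueError(f"4PL fit failed to converge for {construct!r}")
    (floor, span, logec50, hill), rms = best
    return DoseResponseFit(
        construct_id=construct,
        doses=doses,
        responses=resp,
        floor=float(floor),
        span=float(span),
        ec50=float(10 ** logec50),
        hill=float(hill),
        residual=rms,
    )


def _halfmax_dose(fit: DoseResponseFit) -> float | None:
    """Fit-free dose at half-maximal observed response, by interpolation."""
    df = pd.DataFrame({"dose": fit.doses, "response": fit.responses})
    curve = df.groupby("dose")["response"].mean().sort_index()
    target = (curve.min() + curve.max()) / 2.0
    d = np.log10(curve.index.to_numpy())
    r = curve.to_numpy()
    for i in range(len(r) - 1):
        if (r[i] - target) * (r[i + 1] - target) <= 0 and r[i] != r[i + 1]:
            frac = (target - r[i]) / (r[i + 1] - r[i])
            return float(10 ** (d[i] + frac * (d[i + 1] - d[i])))
    return None


def dose_shift(
    fit_a: DoseResponseFit, fit_b: DoseResponseFit
) -> dict[str, float | None]:
    """Horizontal shift between two dose-response curves.

    Returns the 4PL estimate ``ec50_b / ec50_a`` and, when the observed
    response ranges overlap enough to interpolate, a fit-free estimate
    as the ratio of the doses at each curve's half-maximal response.
    """
    shift = fit_b.ec50 / fit_a.ec50
    ha, hb = _halfmax_dose(fit_a), _halfmax_dose(fit_b)
    fit_free = hb / ha if (ha is not None and hb is not None) else None
    if fit_free is None:
        logger.warning("dose_shift: fit-free estimate unavailable")
    return {"shift": float(shift), "shift_fit_free": fit_free}
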