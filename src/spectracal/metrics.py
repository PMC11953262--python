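"""Figures of merit and method-comparison statistics.

Relative errors follow the standard chemometric convention
``RRMSE% = 100 * RMSE / mean(reference)``, applied uniformly to the
calibration (RRMSEC), cross-validation (RRMSECV) and prediction (RRMSEP)
errors. The bias-corrected RRMSEP divides the (n-1)-denominator standard
error of prediction, after removing the mean bias, by the same reference
mean. Detection and quantitation limits follow the ICH Q2(R1)
residual-standard-deviation convention (LOD = 3.3 σ/S, LOQ = 10 σ/S) on
the predicted-vs-actual validation regression, which forces
LOQ/LOD = 10/3.3.

Method comparison mirrors pharmaceutical-analysis practice: a
pooled-variance two-sample t test on the mean recoveries and a two-tailed
variance-ratio F test (larger variance in the numerator).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DomainError

__all__ = [
    "rrmse",
    "bias_corrected_rrmsep",
    "regression_fit",
    "lod_loq",
    "recovery_pct",
    "rsd_pct",
    "pooled_t_test",
    "variance_f_test",
    "standard_addition_recovery",
    "ValidationReport",
    "ComparisonResult",
    "compare_methods",
    "build_validation_report",
]


def _pair(pred, ref):
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.size != ref.size or pred.size == 0:
        raise DomainError(f"pred ({pred.size}) and ref ({ref.size}) must have equal length >= 1")
    return pred, ref


def rrmse(pred, ref) -> float:
    """100 * sqrt(mean squared error) / mean(ref)."""
    pred, ref = _pair(pred, ref)
    m = np.mean(ref)
    if m == 0:
        raise DomainError("mean reference is zero; relative error undefined")
    return float(100.0 * np.sqrt(np.mean((pred - ref) ** 2)) / m)


def bias_corrected_rrmsep(pred, ref) -> float:
    """Relative standard error of prediction after removing the mean bias."""
    pred, ref = _pair(pred, ref)
    if pred.size < 2:
        raise DomainError("bias-corrected RRMSEP needs n >= 2")
    m = np.mean(ref)
    if m == 0:
        raise DomainError("mean reference is zero; relative error undefined")
    err = pred - ref
    sep = np.sqrt(np.sum((err - err.mean()) ** 2) / (pred.size - 1))
    return float(100.0 * sep / m)


def regression_fit(pred, ref) -> tuple[float, float, float]:
    """OLS of predicted on actual: (slope, intercept, R^2)."""
    pred, ref = _pair(pred, ref)
    if pred.size < 3:
        raise DomainError("regression needs n >= 3")
    if np.ptp(ref) == 0:
        raise DomainError("reference values are constant; regression degenerate")
    res = stats.linregress(ref, pred)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def lod_loq(pred, ref) -> tuple[float, float]:
    """ICH 3.3σ/S and 10σ/S limits from the predicted-vs-actual regression."""
    pred, ref = _pair(pred, ref)
    slope, intercept, _ = regression_fit(pred, ref)
    resid = pred - (slope * ref + intercept)
    sigma = float(np.std(resid, ddof=1))
    lod = 3.3 * sigma / slope
    return float(lod), float(10.0 * sigma / slope)


def recovery_pct(pred: float, nominal: float) -> float:
    if nominal <= 0:
        raise DomainError("nominal concentration must be > 0")
    return 100.0 * pred / nominal


def rsd_pct(values) -> float:
    """Relative standard deviation, 100 * SD(n-1) / mean."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise DomainError("RSD needs n >= 2")
    m = v.mean()
    if m == 0:
        raise DomainError("mean is zero; RSD undefined")
    return float(100.0 * v.std(ddof=1) / m)


def standard_addition_recovery(base_pred: float, spiked_pred: float, added: float) -> float:
    if added <= 0:
        raise DomainError("added concentration must be > 0")
    return 100.0 * (spiked_pred - base_pred) / added


def pooled_t_test(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (|t|, df, two-tailed p). Zero pooled variance with equal
    means gives t = 0, p = 1; with unequal means it is an error.
    """
    if n_a < 2 or n_b < 2:
        raise DomainError("both groups need n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise DomainError("standard deviations must be >= 0")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if sp2 == 0:
        if mean_a == mean_b:
            return 0.0, df, 1.0
        raise DomainError("zero pooled variance with unequal means: t is infinite")
    t = abs(mean_a - mean_b) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * stats.t.sf(t, df)
    return float(t), int(df), float(min(p, 1.0))


def variance_f_test(var_a, n_a, var_b, n_b) -> tuple[float, int, int, float]:
    """Two-tailed variance-ratio F test; larger variance in the numerator."""
    if var_a <= 0 or var_b <= 0:
        raise DomainError("variances must be > 0")
    if n_a < 2 or n_b < 2:
        raise DomainError("both groups need n >= 2")
    if var_a >= var_b:
        f, df1, df2 = var_a / var_b, n_a - 1, n_b - 1
    else:
        f, df1, df2 = var_b / var_a, n_b - 1, n_a - 1
    p = 2.0 * stats.f.sf(f, df1, df2)
    return float(f), int(df1), int(df2), float(min(p, 1.0))


@dataclass
class ComparisonResult:
    """Summary statistics and t/F comparison of two methods."""

    mean_a: float
    sd_a: float
    var_a: float
    n_a: int
    mean_b: float
    sd_b: float
    var_b: float
    n_b: int
    t_stat: float
    t_df: int
    t_p: float
    f_stat: float
    f_df1: int
    f_df2: int
    f_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def compare_methods(values_a, values_b) -> ComparisonResult:
    """Full two-method comparison from raw per-determination values."""
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise DomainError("both methods need n >= 2 determinations")
    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    t, t_df, t_p = pooled_t_test(a.mean(), sd_a, a.size, b.mean(), sd_b, b.size)
    f, df1, df2, f_p = variance_f_test(sd_a**2, a.size, sd_b**2, b.size)
    return ComparisonResult(
        mean_a=float(a.mean()), sd_a=float(sd_a), var_a=float(sd_a**2), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(sd_b), var_b=float(sd_b**2), n_b=int(b.size),
        t_stat=t, t_df=t_df, t_p=t_p, f_stat=f, f_df1=df1, f_df2=df2, f_p=f_p,
    )


@dataclass
class ValidationReport:
    """All figures of merit for one analyte, plus optional comparison."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    lod_ugml: float
    loq_ugml: float
    rrmsec_pct: float
    rrmsep_pct: float
    bc_rrmsep_pct: float
    recovery_pct_per_sample: list[float]
    intraday_rsd_pct: float | None = None
    interday_rsd_pct: float | None = None
    comparison: ComparisonResult | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_markdown(self) -> str:
        rows = [
            ("slope", f"{self.slope:.4f}"),
            ("intercept", f"{self.intercept:.4f}"),
            ("R^2", f"{self.r_squared:.4f}"),
            ("LOD (ug/mL)", f"{self.lod_ugml:.4f}"),
            ("LOQ (ug/mL)", f"{self.loq_ugml:.4f}"),
            ("RRMSEC %", f"{self.rrmsec_pct:.4f}"),
            ("RRMSEP %", f"{self.rrmsep_pct:.4f}"),
            ("bias-corrected RRMSEP %", f"{self.bc_rrmsep_pct:.4f}"),
            ("mean recovery %", f"{np.mean(self.recovery_pct_per_sample):.2f}"),
        ]
        if self.intraday_rsd_pct is not None:
            rows.append(("intra-day RSD %", f"{self.intraday_rsd_pct:.3f}"))
        if self.interday_rsd_pct is not None:
            rows.append(("inter-day RSD %", f"{self.interday_rsd_pct:.3f}"))
        out = [f"### {self.analyte}", "", "| figure of merit | value |", "| --- | --- |"]
        out += [f"| {k} | {v} |" for k, v in rows]
        if self.comparison is not None:
            c = self.comparison
            out += [
                "",
                "| comparison | proposed | reference |",
                "| --- | --- | --- |",
                f"| mean | {c.mean_a:.2f} | {c.mean_b:.2f} |",
                f"| SD | {c.sd_a:.3f} | {c.sd_b:.3f} |",
                f"| variance | {c.var_a:.3f} | {c.var_b:.3f} |",
                f"| t (df {c.t_df}) | {c.t_stat:.3f} | p = {c.t_p:.3f} |",
                f"| F ({c.f_df1},{c.f_df2}) | {c.f_stat:.3f} | p = {c.f_p:.3f} |",
            ]
        return "\n".join(out) + "\n"


def build_validation_report(analyte: str, pred_cal, ref_cal, pred_val, ref_val,
                            intraday_values=None, interday_values=None,
                            comparison: ComparisonResult | None = None) -> ValidationReport:
    """Assemble a per-analyte report from calibration/validation predictions."""
    slope, intercept, r2 = regression_fit(pred_val, ref_val)
    lod, loq = lod_loq(pred_val, ref_val)
    pred_val_arr, ref_val_arr = _pair(pred_val, ref_val)
    recoveries = [recovery_pct(p, r) for p, r in zip(pred_val_arr, ref_val_arr) if r > 0]
    return ValidationReport(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        lod_ugml=lod,
        loq_ugml=loq,
        rrmsec_pct=rrmse(pred_cal, ref_cal),
        rrmsep_pct=rrmse(pred_val, ref_val),
        bc_rrmsep_pct=bias_corrected_rrmsep(pred_val, ref_val),
        recovery_pct_per_sample=[float(r) for r in recoveries],
        intraday_rsd_pct=None if intraday_values is None else rsd_pct(intraday_values),
        interday_rsd_pct=None if interday_values is None else rsd_pct(interday_values),
        comparison=comparison,
    )
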