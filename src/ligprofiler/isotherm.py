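"""1:1 isotherm fitting of direct and competition titrations.

Direct titrations add fibril binding sites (titrant, in site-equivalent
nM) to a fixed concentration of reporter ligand; the observed signal is

    signal = baseline + amplitude * theta(titrant; K_d)

where ``theta`` is the exact ligand-depletion-aware bound fraction of the
reporter, i.e. the physical root of the mass-balance quadratic divided by
the reporter total.  For titrant >> reporter the quadratic reduces to the
familiar free-ligand hyperbola.

Competition titrations add a dark competitor (L1) to a pre-formed
fibril/reporter mixture; the reporter fluorescence falls from ``f_start``
to a limiting ``f_end`` as L1 saturates the shared site class BS1:

    signal = f_end + (f_start - f_end) * (1 - theta(l1; K_d,app))

with ``theta`` the 1:1 bound fraction of L1 (free ~ total for the
competitor, since the shared sites are dilute relative to the apparent
K_d).  The fraction of reporter sites accessible to the competitor is

    %BS1 = 100 * (f_start - f_end) / (f_start - f_background).

Replicates are fitted independently and pooled with Student-t 95%
confidence intervals.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TitrationCurve",
    "DirectFitResult",
    "CompetitionFitResult",
    "PooledParam",
    "PooledFit",
    "SchemaError",
    "DegenerateAssayError",
    "fit_direct",
    "fit_competition",
    "fit_curve",
    "aggregate_replicates",
    "t_confidence_interval",
    "curves_to_frame",
    "frame_to_curves",
    "read_titrations_csv",
    "write_titrations_csv",
]

CSV_COLUMNS = [
    "assay_id",
    "fibril",
    "assay_kind",
    "reporter",
    "competitor",
    "fibril_conc_nM",
    "reporter_conc_nM",
    "titrant_nM",
    "signal",
    "replicate",
    "background_signal",
]

ASSAY_KINDS = ("direct_intensity", "direct_anisotropy", "competition")

#: ratio of displacement to residual scatter below which a competition
#: titration is called "no displacement"
NO_DISPLACEMENT_SD_FACTOR = 3.0


class SchemaError(ValueError):
    """Malformed titration input (bad columns, non-monotone titrant, ...)."""


class DegenerateAssayError(ValueError):
    """The reporter never bound: f_start does not exceed the blank."""


@dataclass(frozen=True)
class TitrationCurve:
    """One assay replicate: titrant series plus observed signal."""

    assay_kind: str
    reporter: str
    titrant_conc: np.ndarray
    signal: np.ndarray
    fixed_concs: Mapping[str, float] = field(default_factory=dict)
    competitor: str | None = None
    replicate_id: str = "r1"
    assay_id: str = ""
    fibril: str = ""
    background: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.titrant_conc, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "titrant_conc", t)
        object.__setattr__(self, "signal", y)
        if self.assay_kind not in ASSAY_KINDS:
            raise SchemaError(f"unknown assay_kind {self.assay_kind!r}")
        if t.shape != y.shape or t.ndim != 1:
            raise SchemaError("titrant and signal series must be equal-length 1-D")
        if len(t) < 5:
            raise SchemaError(f"need at least 5 titration points, got {len(t)}")
        if np.any(t < 0):
            raise SchemaError("titrant concentrations must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise SchemaError(
                f"titrant series must be strictly increasing (replicate {self.replicate_id!r})"
            )
        if self.assay_kind == "competition" and not self.competitor:
            raise SchemaError("competition curves must name a competitor")

    @property
    def reporter_conc(self) -> float:
        return float(self.fixed_concs.get("reporter", 0.0))


@dataclass(frozen=True)
class DirectFitResult:
    kd: float
    amplitude: float
    baseline: float
    kd_ci95: tuple[float, float]
    amplitude_ci95: tuple[float, float]
    rmse: float
    converged: bool
    low_confidence: bool = False
    n_points: int = 0


@dataclass(frozen=True)
class CompetitionFitResult:
    kd_l1: float
    f_start: float
    f_end: float
    f_background: float
    percent_bs1: float
    kd_ci95: tuple[float, float]
    percent_bs1_ci95: tuple[float, float]
    displacement: float
    displacement_ci95: tuple[float, float]
    no_displacement: bool
    rmse: float
    converged: bool
    low_confidence: bool = False
    n_points: int = 0


def _bound_quadratic(l_total, s_total, kd):
    """Vectorized stable root of b^2 - (L+S+Kd) b + L S = 0 (physical branch)."""
    l = np.asarray(l_total, dtype=float)
    s = np.asarray(s_total, dtype=float)
    p = l + s + kd
    disc = np.maximum(p * p - 4.0 * l * s, 0.0)
    denom = p + np.sqrt(disc)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(denom > 0, 2.0 * l * s / np.where(denom > 0, denom, 1.0), 0.0)
    return b


def _theta_direct(titrant, reporter_total, kd):
    """Depletion-aware bound fraction of the reporter vs added sites."""
    if reporter_total <= 0:
        raise SchemaError("direct fit requires a positive fixed reporter concentration")
    return _bound_quadratic(titrant, reporter_total, kd) / reporter_total


def _theta_hyperbolic(l1, kd):
    """1:1 bound fraction of the titrated competitor (free ~ total)."""
    return l1 / (l1 + kd)


def _profiled_fit(t, y, basis_fn, log_kd_starts):
    """1-D optimization over log10(Kd) with the linear coefficients profiled out.

    ``basis_fn(kd)`` returns the (n, 2) design matrix; the two linear
    coefficients are solved by least squares at every Kd.  Returns the
    best (kd, coefs, rss) over the deterministic starts; ties go to the
    lowest residual.
    """

    def coefs_rss(log_kd):
        a = basis_fn(10.0 ** log_kd)
        coef, *_ = np.linalg.lstsq(a, y, rcond=None)
        r = y - a @ coef
        return coef, float(r @ r)

    lo = min(log_kd_starts) - 4.0
    hi = max(log_kd_starts) + 4.0
    best = None
    n_ok = 0
    for lk in log_kd_starts:
        res = optimize.least_squares(
            lambda p: y - basis_fn(10.0 ** p[0]) @ coefs_rss(p[0])[0],
            x0=[lk],
            bounds=([lo], [hi]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        if not np.all(np.isfinite(res.x)):
            continue
        n_ok += 1
        coef, rss = coefs_rss(res.x[0])
        if best is None or rss < best[2] - 1e-12 * max(best[2], 1e-300):
            best = (10.0 ** res.x[0], coef, rss)
    if best is None:
        return None
    return best + (n_ok > 0,)


def _covariance(t, y, model_fn, params, rss):
    """Linearized covariance of (log10 kd, c1, c2) at the optimum."""
    n = len(y)
    p = np.asarray(params, dtype=float)
    k = len(p)
    if n <= k:
        return None, max(n - k, 0)
    jac = np.empty((n, k))
    for j in range(k):
        h = 1e-6 * max(abs(p[j]), 1e-3)
        up, dn = p.copy(), p.copy()
        up[j] += h
        dn[j] -= h
        jac[:, j] = (model_fn(up) - model_fn(dn)) / (2 * h)
    s2 = rss / (n - k)
    try:
        cov = s2 * np.linalg.pinv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return None, n - k
    return cov, n - k


def _ci(value, se, df):
    if se is None or not np.isfinite(se) or df < 1:
        return (-math.inf, math.inf)
    q = stats.t.ppf(0.975, df)
    return (value - q * se, value + q * se)


def _pow10(x):
    return 10.0 ** min(x, 300.0) if math.isfinite(x) else (0.0 if x < 0 else math.inf)


def _log_kd_starts(t):
    tp = t[t > 0]
    if len(tp) == 0:
        raise SchemaError("titrant series has no positive points")
    return list(np.log10(np.geomspace(tp.min(), tp.max(), 3)))


def fit_direct(curve: TitrationCurve) -> DirectFitResult:
    """Least-squares fit of a direct titration to the 1:1 quadratic isotherm.

    Three deterministic multi-starts on a log-K_d grid spanning the
    titrant range; amplitude and baseline are profiled out linearly.
    Non-convergence is reported via ``converged=False``, never raised.
    """
    if curve.assay_kind not in ("direct_intensity", "direct_anisotropy"):
        raise SchemaError(f"fit_direct cannot handle assay_kind {curve.assay_kind!r}")
    t, y = curve.titrant_conc, curve.signal
    l_tot = curve.reporter_conc

    def basis(kd):
        th = _theta_direct(t, l_tot, kd)
        return np.column_stack([np.ones_like(th), th])

    fit = _profiled_fit(t, y, basis, _log_kd_starts(t))
    if fit is None:
        nan = float("nan")
        return DirectFitResult(nan, nan, nan, (nan, nan), (nan, nan), nan,
                               converged=False, n_points=len(t))
    kd, (baseline, amplitude), rss, ok = fit

    def model(p):
        th = _theta_direct(t, l_tot, 10.0 ** p[0])
        return p[1] + p[2] * th

    cov, df = _covariance(t, y, model, [math.log10(kd), baseline, amplitude], rss)
    if cov is not None:
        se_logkd, se_amp = math.sqrt(max(cov[0, 0], 0)), math.sqrt(max(cov[2, 2], 0))
        kd_ci = tuple(_pow10(b) for b in _ci(math.log10(kd), se_logkd, df))
        amp_ci = _ci(amplitude, se_amp, df)
    else:
        kd_ci, amp_ci = (-math.inf, math.inf), (-math.inf, math.inf)
    rmse = math.sqrt(rss / len(y))
    return DirectFitResult(
        kd=kd,
        amplitude=amplitude,
        baseline=baseline,
        kd_ci95=kd_ci,
        amplitude_ci95=amp_ci,
        rmse=rmse,
        converged=bool(ok) and math.isfinite(kd) and kd > 0,
        low_confidence=bool(t.max() < kd / 2),
        n_points=len(t),
    )


def fit_competition(
    curve: TitrationCurve, f_background: float | None = None
) -> CompetitionFitResult:
    """Fit a competitor displacement titration and derive the limiting %BS1.

    ``f_background`` defaults to the curve's measured no-fibril blank; a
    baseline from a paired direct fit of the reporter may be supplied
    instead.  The no-displacement call follows the rule that the fitted
    amplitude must both exclude zero at 95% and exceed three residual
    standard deviations.
    """
    if curve.assay_kind != "competition":
        raise SchemaError(f"fit_competition cannot handle assay_kind {curve.assay_kind!r}")
    t, y = curve.titrant_conc, curve.signal
    if f_background is None:
        f_background = curve.background if curve.background is not None else 0.0
    f_bg = float(f_background)

    def basis(kd):
        th = _theta_hyperbolic(t, kd)
        return np.column_stack([1.0 - th, th])  # coefficients (f_start, f_end)

    fit = _profiled_fit(t, y, basis, _log_kd_starts(t))
    nan = float("nan")
    if fit is None:
        return CompetitionFitResult(
            nan, nan, nan, f_bg, nan, (nan, nan), (nan, nan), nan, (nan, nan),
            no_displacement=False, rmse=nan, converged=False, n_points=len(t))
    kd, (f_start, f_end), rss, ok = fit
    rmse = math.sqrt(rss / len(y))

    # extra-sum-of-squares comparison against the constant (no-displacement)
    # model: the profile-likelihood version of "the displacement CI includes 0"
    n = len(y)
    rss_const = float(np.sum((y - np.mean(y)) ** 2))
    if rss <= 0:
        f_stat = math.inf if rss_const > 0 else 0.0
    else:
        f_stat = ((rss_const - rss) / 2.0) / (rss / (n - 3))
    displacement_supported = f_stat > stats.f.ppf(0.95, 2, n - 3)

    if not displacement_supported:
        f_start = f_end = float(np.mean(y))
        rmse = math.sqrt(rss_const / n)
        if f_start <= f_bg:
            raise DegenerateAssayError(
                f"flat titration at the background level ({f_start:.3g} <= {f_bg:.3g}): "
                "the reporter never bound"
            )
        return CompetitionFitResult(
            kd_l1=nan, f_start=f_start, f_end=f_end, f_background=f_bg,
            percent_bs1=0.0, kd_ci95=(nan, nan), percent_bs1_ci95=(0.0, 0.0),
            displacement=0.0, displacement_ci95=(0.0, 0.0), no_displacement=True,
            rmse=rmse, converged=bool(ok), n_points=n,
        )

    if f_start <= f_bg:
        raise DegenerateAssayError(
            f"f_start ({f_start:.3g}) does not exceed the background ({f_bg:.3g}): "
            "the reporter never bound"
        )

    def model(p):
        th = _theta_hyperbolic(t, 10.0 ** p[0])
        return p[1] * (1.0 - th) + p[2] * th

    cov, df = _covariance(t, y, model, [math.log10(kd), f_start, f_end], rss)
    displacement = f_start - f_end
    if cov is not None:
        se_logkd = math.sqrt(max(cov[0, 0], 0))
        var_disp = max(cov[1, 1] + cov[2, 2] - 2 * cov[1, 2], 0.0)
        se_disp = math.sqrt(var_disp)
        kd_ci = tuple(_pow10(b) for b in _ci(math.log10(kd), se_logkd, df))
        disp_ci = _ci(displacement, se_disp, df)
        # delta method for %BS1 = 100 (fs - fe) / (fs - fbg)
        denom = f_start - f_bg
        g = np.array([100.0 * (f_end - f_bg) / denom**2, -100.0 / denom])
        var_bs1 = float(g @ cov[1:, 1:] @ g)
        se_bs1 = math.sqrt(max(var_bs1, 0.0))
    else:
        kd_ci, disp_ci = (-math.inf, math.inf), (-math.inf, math.inf)
        se_bs1 = None

    no_disp = (disp_ci[0] <= 0.0 <= disp_ci[1]) or (
        abs(displacement) < NO_DISPLACEMENT_SD_FACTOR * rmse
    )
    if no_disp:
        percent_bs1 = 0.0
        bs1_ci = (0.0, 0.0)
        kd_out, kd_ci = nan, (nan, nan)
    else:
        percent_bs1 = float(np.clip(100.0 * displacement / (f_start - f_bg), 0.0, 100.0))
        bs1_ci = _ci(percent_bs1, se_bs1, df if cov is not None else 0)
        kd_out = kd
    return CompetitionFitResult(
        kd_l1=kd_out,
        f_start=f_start,
        f_end=f_end,
        f_background=f_bg,
        percent_bs1=percent_bs1,
        kd_ci95=kd_ci,
        percent_bs1_ci95=bs1_ci,
        displacement=displacement,
        displacement_ci95=disp_ci,
        no_displacement=bool(no_disp),
        rmse=rmse,
        converged=bool(ok) and math.isfinite(f_start),
        low_confidence=bool(not no_disp and t.max() < kd / 2),
        n_points=len(t),
    )


def fit_curve(curve: TitrationCurve, f_background: float | None = None):
    """Dispatch to :func:`fit_direct` or :func:`fit_competition`."""
    if curve.assay_kind == "competition":
        return fit_competition(curve, f_background=f_background)
    return fit_direct(curve)


# ---------------------------------------------------------------------------
# replicate aggregation


@dataclass(frozen=True)
class PooledParam:
    mean: float
    ci95: tuple[float, float]
    sd: float
    n: int
    values: tuple[float, ...]


@dataclass(frozen=True)
class PooledFit:
    """t-based pooling of per-replicate fit results for one assay/fibril."""

    assay_kind: str
    params: Mapping[str, PooledParam]
    resid_sd: float
    n: int

    def __getitem__(self, name: str) -> PooledParam:
        return self.params[name]


def t_confidence_interval(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Mean and t-based 95% CI: mean +/- t(0.975, n-1) * sd / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 replicates to form a confidence interval")
    m = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return m, (m - half, m + half)


_DIRECT_PARAMS = ("kd", "amplitude", "baseline")
_COMPETITION_PARAMS = ("kd_l1", "f_start", "f_end", "displacement", "percent_bs1")


def aggregate_replicates(fits: Sequence) -> PooledFit:
    """Pool per-replicate parameter estimates with Student-t 95% CIs."""
    if len(fits) < 2:
        raise ValueError("need at least 2 replicate fits to aggregate")
    if isinstance(fits[0], DirectFitResult):
        names, kind = _DIRECT_PARAMS, "direct"
    elif isinstance(fits[0], CompetitionFitResult):
        names, kind = _COMPETITION_PARAMS, "competition"
    else:
        raise TypeError(f"cannot aggregate {type(fits[0]).__name__}")
    if not all(isinstance(f, type(fits[0])) for f in fits):
        raise TypeError("all replicate fits must come from the same assay kind")
    params = {}
    for name in names:
        vals = np.array([getattr(f, name) for f in fits], dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) >= 2:
            m, ci = t_confidence_interval(finite)
            params[name] = PooledParam(m, ci, float(np.std(finite, ddof=1)),
                                       len(finite), tuple(vals))
        else:
            nan = float("nan")
            params[name] = PooledParam(nan, (nan, nan), nan, len(finite), tuple(vals))
    resid_sd = float(np.sqrt(np.mean([f.rmse**2 for f in fits])))
    return PooledFit(assay_kind=kind, params=params, resid_sd=resid_sd, n=len(fits))


# ---------------------------------------------------------------------------
# CSV external interface


def curves_to_frame(curves: Sequence[TitrationCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for t, y in zip(c.titrant_conc, c.signal):
            rows.append(
                {
                    "assay_id": c.assay_id,
                    "fibril": c.fibril,
                    "assay_kind": c.assay_kind,
                    "reporter": c.reporter,
                    "competitor": c.competitor or "",
                    "fibril_conc_nM": c.fixed_concs.get("fibril", float("nan")),
                    "reporter_conc_nM": c.fixed_concs.get("reporter", float("nan")),
                    "titrant_nM": t,
                    "signal": y,
                    "replicate": c.replicate_id,
                    "background_signal": c.background if c.background is not None else "",
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_curves(df: pd.DataFrame) -> list[TitrationCurve]:
    required = [c for c in CSV_COLUMNS if c != "background_signal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError("empty titration table")
    df = df.copy()
    for col in ("assay_id", "fibril", "replicate", "assay_kind", "reporter", "competitor"):
        df[col] = df[col].fillna("").astype(str)
    curves = []
    keys = ["assay_id", "fibril", "replicate"]
    for (assay_id, fibril, replicate), g in df.groupby(keys, sort=False):
        g = g.reset_index()
        first = g.iloc[0]
        bg = None
        if "background_signal" in g.columns:
            raw = first["background_signal"]
            if raw not in ("", None) and not (isinstance(raw, float) and math.isnan(raw)):
                bg = float(raw)
        try:
            curves.append(
                TitrationCurve(
                    assay_kind=str(first["assay_kind"]),
                    reporter=str(first["reporter"]),
                    competitor=str(first["competitor"]) or None,
                    fixed_concs={
                        "fibril": float(first["fibril_conc_nM"]),
                        "reporter": float(first["reporter_conc_nM"]),
                    },
                    titrant_conc=g["titrant_nM"].to_numpy(float),
                    signal=g["signal"].to_numpy(float),
                    replicate_id=str(replicate),
                    assay_id=str(assay_id),
                    fibril=str(fibril),
                    background=bg,
                )
            )
        except SchemaError as err:
            row = int(g["index"].iloc[0]) + 2  # 1-based plus header line
            raise SchemaError(
                f"assay {assay_id!r} fibril {fibril!r} replicate {replicate!r} "
                f"(starting near CSV line {row}): {err}"
            ) from err
    return curves


def read_titrations_csv(path) -> list[TitrationCurve]:
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as err:
        raise SchemaError(f"{path}: empty or unreadable CSV") from err
    return frame_to_curves(df)


def write_titrations_csv(curves: Sequence[TitrationCurve], path, header_lines=()) -> None:
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    curves_to_frame(curves).to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
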