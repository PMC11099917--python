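"""Binding calls, paired significance tests, and per-fibril ligand profiles.

A pooled fit becomes a binary binding call when the 95% CI of its
amplitude (direct assays) or displacement (competition assays) excludes
zero, the effect has the physical sign, and its magnitude is at least
three pooled residual standard deviations.  Ordinal features (K_d ranks,
%BS1 classes) are only asserted when backed by a significant two-sided
paired t-test or a confidence interval clear of the class boundary;
otherwise the feature is left unset and classification degrades to an
ambiguity set rather than a guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .assays import PROTOCOL_ASSAYS
from .isotherm import PooledFit

__all__ = [
    "ALPHA_DEFAULT",
    "BS1_CLASS_THRESHOLD",
    "BindingCall",
    "PairedTestResult",
    "LigandProfile",
    "IncompleteProfileError",
    "call_binding",
    "paired_t_test",
    "holm_correction",
    "build_profile",
    "build_panel_profiles",
]

ALPHA_DEFAULT = 0.05
#: %BS1 above which displacement counts as "almost complete" (high class)
BS1_CLASS_THRESHOLD = 70.0
#: numerical floor for p-values of degenerate (zero-variance) paired tests
P_FLOOR = 1e-12
CALL_SD_FACTOR = 3.0


class IncompleteProfileError(ValueError):
    """A required assay is missing from a fibril's pooled results."""


@dataclass(frozen=True)
class BindingCall:
    assay: str
    fibril: str
    bound: bool
    estimate: float
    ci95: tuple[float, float]
    resid_sd: float
    rule: str


@dataclass(frozen=True)
class PairedTestResult:
    fibril_a: str
    fibril_b: str
    parameter: str
    t_stat: float
    p_value: float
    n_pairs: int
    significant: bool
    alpha: float = ALPHA_DEFAULT
    degenerate: bool = False


@dataclass(frozen=True)
class LigandProfile:
    """Feature vector of one fibril: binary calls plus ordinal annotations."""

    fibril: str
    binary: Mapping[str, bool] = field(default_factory=dict)
    ordinal: Mapping[str, str] = field(default_factory=dict)
    bs1: Mapping[str, float] = field(default_factory=dict)

    def features(self) -> dict[str, object]:
        """Flat feature map consumed by the decision tree."""
        out: dict[str, object] = {}
        for assay, bound in self.binary.items():
            out[_binary_feature(assay)] = bool(bound)
        out.update(self.ordinal)
        return out


def _binary_feature(assay_id: str) -> str:
    # "AAR-direct" -> aar_bind ; "ThT/S5H" -> s5h_bind (the probed ligand)
    probe = assay_id.split("/")[-1].split("-")[0]
    return f"{probe.lower()}_bind"


def call_binding(
    pooled: PooledFit, assay_kind: str, assay: str = "", fibril: str = ""
) -> BindingCall:
    """Binary bind / no-bind call from a pooled fit.

    ``bound`` requires the amplitude (direct) or displacement
    (competition) to have a 95% CI excluding zero, the physical sign
    (signal gain on binding, signal loss on displacement), and magnitude
    of at least three pooled residual SDs.  Monotone in the true effect:
    growing a real amplitude at fixed noise can only flip no->yes.
    """
    name = "displacement" if assay_kind == "competition" else "amplitude"
    est = pooled[name]
    if not (math.isfinite(est.ci95[0]) and math.isfinite(est.ci95[1])):
        raise ValueError(f"{assay}/{fibril}: pooled {name} has no confidence interval")
    ci_excludes_zero = est.ci95[0] > 0.0 or est.ci95[1] < 0.0
    big_enough = abs(est.mean) >= CALL_SD_FACTOR * pooled.resid_sd
    right_sign = est.mean > 0.0
    bound = bool(ci_excludes_zero and big_enough and right_sign)
    return BindingCall(
        assay=assay,
        fibril=fibril,
        bound=bound,
        estimate=est.mean,
        ci95=est.ci95,
        resid_sd=pooled.resid_sd,
        rule=f"CI excludes 0: {ci_excludes_zero}; |{name}| >= "
             f"{CALL_SD_FACTOR}*resid_sd: {big_enough}; positive: {right_sign}",
    )


def paired_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = ALPHA_DEFAULT,
    fibril_a: str = "a",
    fibril_b: str = "b",
    parameter: str = "kd",
) -> PairedTestResult:
    """Two-sided paired t-test, paired by replicate index.

    t = mean(d) / (sd(d)/sqrt(n)), df = n - 1.  Zero-variance differences
    with nonzero mean are degenerate: p is floored at 1e-12 and flagged,
    never NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be equal-length 1-D")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    degenerate = sd_d == 0.0
    if degenerate:
        if mean_d == 0.0:
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, mean_d)
            p = P_FLOOR
    else:
        t = mean_d / (sd_d / math.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), n - 1))
        p = max(p, P_FLOOR)
    return PairedTestResult(
        fibril_a=fibril_a,
        fibril_b=fibril_b,
        parameter=parameter,
        t_stat=t,
        p_value=p,
        n_pairs=n,
        significant=bool(p < alpha),
        alpha=alpha,
        degenerate=degenerate,
    )


def holm_correction(tests: Sequence[PairedTestResult]) -> list[PairedTestResult]:
    """Optional Holm step-down correction over a family of paired tests.

    Off by default everywhere: the decision protocol uses raw two-sided
    paired-t p-values.
    """
    order = sorted(range(len(tests)), key=lambda i: tests[i].p_value)
    m = len(tests)
    out = list(tests)
    crossed = False
    for rank, i in enumerate(order):
        adj_alpha = tests[i].alpha / (m - rank)
        if crossed or tests[i].p_value >= adj_alpha:
            crossed = True
            out[i] = PairedTestResult(
                **{**tests[i].__dict__, "significant": False}
            )
    return out


def _sig_lower(
    kd_a: Sequence[float], kd_b: Sequence[float], alpha: float, fa: str, fb: str, param: str
) -> tuple[bool, PairedTestResult]:
    res = paired_t_test(kd_a, kd_b, alpha=alpha, fibril_a=fa, fibril_b=fb, parameter=param)
    return bool(res.significant and np.mean(kd_a) < np.mean(kd_b)), res


def build_profile(
    fibril: str,
    pooled: Mapping[str, PooledFit],
    ordinal: Mapping[str, str] | None = None,
    alpha: float = ALPHA_DEFAULT,
    required: Sequence[str] = tuple(PROTOCOL_ASSAYS),
) -> LigandProfile:
    """Assemble one fibril's profile from its pooled per-assay fits.

    Ordinal (panel-relative) features must be supplied by the caller or
    by :func:`build_panel_profiles`; a missing protocol assay raises
    :class:`IncompleteProfileError` naming the assay.
    """
    for assay in required:
        if assay not in pooled:
            raise IncompleteProfileError(f"fibril {fibril!r}: missing assay {assay!r}")
    binary = {}
    bs1 = {}
    for assay, fit in pooled.items():
        call = call_binding(fit, fit.assay_kind, assay=assay, fibril=fibril)
        binary[assay] = call.bound
        if fit.assay_kind == "competition" and call.bound:
            bs1[assay] = fit["percent_bs1"].mean
    ordinal = dict(ordinal or {})
    if "ThT/OXI" in pooled and binary.get("ThT/OXI"):
        cls = _bs1_class(pooled["ThT/OXI"]["percent_bs1"])
        if cls is not None:
            ordinal.setdefault("oxi_bs1_class", cls)
    return LigandProfile(fibril=fibril, binary=binary, ordinal=ordinal, bs1=bs1)


def _bs1_class(param) -> str | None:
    """'low' / 'high' only when the pooled CI is clear of the threshold."""
    lo, hi = param.ci95
    if hi < BS1_CLASS_THRESHOLD:
        return "low"
    if lo > BS1_CLASS_THRESHOLD:
        return "high"
    return None


def build_panel_profiles(
    pooled_by_fibril: Mapping[str, Mapping[str, PooledFit]],
    alpha: float = ALPHA_DEFAULT,
) -> dict[str, LigandProfile]:
    """Profiles for a whole panel, including panel-relative ordinal ranks.

    Fibrils are first grouped by their binary vector over the protocol
    assays.  Within a group that binds S5H, a member earns
    ``s5h_kd_rank='lowest'`` only when its S5H K_d is significantly lower
    (paired by replicate) than every other member's; the remaining
    members are then ranked ``aar_kd_rank='lower'/'higher'`` by the same
    rule on the AAR direct K_d.  Unsupported orderings stay unset.
    """
    profiles = {
        fib: build_profile(fib, pooled, alpha=alpha)
        for fib, pooled in pooled_by_fibril.items()
    }
    groups: dict[tuple, list[str]] = {}
    for fib, prof in profiles.items():
        key = tuple(prof.binary.get(a, False) for a in PROTOCOL_ASSAYS[:3])
        groups.setdefault(key, []).append(fib)

    def kd_values(fib: str, assay: str, param: str) -> np.ndarray:
        return np.asarray(pooled_by_fibril[fib][assay][param].values, dtype=float)

    for key, members in groups.items():
        if len(members) < 2:
            continue
        ordinals: dict[str, dict[str, str]] = {m: {} for m in members}
        binds_s5h = all(profiles[m].binary.get("ThT/S5H") for m in members)
        rest = list(members)
        if binds_s5h:
            lowest = None
            for m in members:
                others = [o for o in members if o != m]
                if all(
                    _sig_lower(kd_values(m, "ThT/S5H", "kd_l1"),
                               kd_values(o, "ThT/S5H", "kd_l1"),
                               alpha, m, o, "kd")[0]
                    for o in others
                ):
                    lowest = m
                    break
            if lowest is not None:
                ordinals[lowest]["s5h_kd_rank"] = "lowest"
                for m in members:
                    if m != lowest:
                        ordinals[m]["s5h_kd_rank"] = "other"
                rest = [m for m in members if m != lowest]
        binds_aar = all(profiles[m].binary.get("AAR-direct") for m in rest)
        if len(rest) >= 2 and binds_aar:
            for m in rest:
                others = [o for o in rest if o != m]
                lower_all = all(
                    _sig_lower(kd_values(m, "AAR-direct", "kd"),
                               kd_values(o, "AAR-direct", "kd"),
                               alpha, m, o, "kd")[0]
                    for o in others
                )
                higher_all = all(
                    _sig_lower(kd_values(o, "AAR-direct", "kd"),
                               kd_values(m, "AAR-direct", "kd"),
                               alpha, o, m, "kd")[0]
                    for o in others
                )
                if lower_all:
                    ordinals[m]["aar_kd_rank"] = "lower"
                elif higher_all:
                    ordinals[m]["aar_kd_rank"] = "higher"
        for m in members:
            if ordinals[m]:
                prof = profiles[m]
                profiles[m] = LigandProfile(
                    fibril=prof.fibril,
                    binary=prof.binary,
                    ordinal={**prof.ordinal, **ordinals[m]},
                    bs1=prof.bs1,
                )
    return profiles
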