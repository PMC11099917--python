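"""End-to-end orchestration: simulate -> fit -> profile -> classify."""

from __future__ import annotations

from typing import Mapping, Sequence

from .classifier import DecisionTree, classify_with_path, reference_tree
from .isotherm import PooledFit, TitrationCurve, aggregate_replicates, fit_curve
from .profiles import ALPHA_DEFAULT, LigandProfile, build_panel_profiles

__all__ = ["fit_replicates", "pool_curves", "profile_curves", "classify_profiles", "run_reference_pipeline"]


def fit_replicates(curves: Sequence[TitrationCurve]):
    """Fit every curve independently, grouped by (fibril, assay)."""
    grouped: dict[tuple[str, str], list] = {}
    for c in curves:
        grouped.setdefault((c.fibril, c.assay_id), []).append(fit_curve(c))
    return grouped


def pool_curves(curves: Sequence[TitrationCurve]) -> dict[str, dict[str, PooledFit]]:
    """Per-fibril, per-assay pooled fits from raw titration curves."""
    pooled: dict[str, dict[str, PooledFit]] = {}
    for (fibril, assay), fits in fit_replicates(curves).items():
        pooled.setdefault(fibril, {})[assay] = aggregate_replicates(fits)
    return pooled


def profile_curves(
    curves: Sequence[TitrationCurve], alpha: float = ALPHA_DEFAULT
) -> dict[str, LigandProfile]:
    return build_panel_profiles(pool_curves(curves), alpha=alpha)


def classify_profiles(
    profiles: Mapping[str, LigandProfile], tree: DecisionTree | None = None
) -> dict[str, dict]:
    tree = tree or reference_tree()
    report = {}
    for fibril, prof in profiles.items():
        result, path = classify_with_path(prof, tree)
        report[fibril] = {
            "label": result if isinstance(result, str) else None,
            "ambiguity_set": sorted(result) if not isinstance(result, str) else None,
            "path": path,
        }
    return report


def run_reference_pipeline(seed: int, sigma_rel: float = 0.02, replicates: int = 3,
                           alpha: float = ALPHA_DEFAULT) -> dict[str, dict]:
    """Simulate the reference panel and classify every fibril from its own data."""
    from .synthetic import NoiseModel, make_reference_panel, simulate_panel

    panel = make_reference_panel(seed)
    noise = NoiseModel(sigma_rel=sigma_rel, replicates=replicates, seed=seed)
    curves = simulate_panel(panel, noise)
    profiles = profile_curves(curves, alpha=alpha)
    return classify_profiles(profiles)
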