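"""End-to-end cohort analysis.

Orchestrates the full measurement chain over a two-group cohort of eyes:
QC exclusion, sweep averaging and filtering, per-trace feature extraction,
per-eye Hill fits of the a- and b-wave intensity-response relations, OP
areas at the two designated intensities, within-trace amplitude ratios, and
the normality-gated group statistics with Bonferroni correction per
comparison family.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .features import compute_ratios, extract_features
from .filters import process_trace
from .hill import fit_hill, summarize_op
from .stats import StatResult, linear_fit, two_sample_compare
from .synth import Cohort

__all__ = ["AnalysisPlan", "ResultsBundle", "qc_exclude", "extract_cohort_features", "fit_cohort_hill", "run_pipeline"]

# QC flags that discard one eye vs every eye of the animal.
EYE_LEVEL_FLAGS = {"bad_contact"}
ANIMAL_LEVEL_FLAGS = {"anesthesia_failure", "deceased"}


@dataclass(frozen=True)
class AnalysisPlan:
    """Comparison structure: which quantities, and the Bonferroni m per family."""

    m_hill_params: int = 3       # Vmax, k, n compared per wave family
    m_op_intensities: int = 2    # the two designated OP intensities
    m_ratios: int = 3            # b/a, OP/a, OP/b medians
    op_intensity_indices: tuple = (8, 13)
    include_ratios: bool = True

    def __post_init__(self) -> None:
        if min(self.m_hill_params, self.m_op_intensities, self.m_ratios) < 1:
            raise ValueError("Bonferroni m must be >= 1")


@dataclass
class ResultsBundle:
    """All tables produced by one pipeline run."""

    features: pd.DataFrame            # one row per eye x intensity
    fits_a: pd.DataFrame              # per-eye a-wave Hill fits
    fits_b: pd.DataFrame              # per-eye b-wave Hill fits
    param_stats: dict                 # (wave, param) -> StatResult
    op_areas: pd.DataFrame            # per-eye OP areas at the designated steps
    op_stats: dict                    # intensity index -> StatResult
    ratios: pd.DataFrame              # per-trace ratio table
    ratio_stats: dict                 # ratio name -> StatResult
    linear_fits: dict                 # (relation, group) -> LinearFitResult
    exclusions: list                  # qc exclusion log
    provenance: dict

    def content_hash(self) -> str:
        """Deterministic digest of every numeric table, for reproducibility checks."""
        h = hashlib.sha256()
        for df in (self.features, self.fits_a, self.fits_b, self.op_areas, self.ratios):
            h.update(df.round(9).to_csv(index=False).encode())
        for key in sorted(self.param_stats, key=str):
            h.update(json.dumps(asdict(self.param_stats[key]), sort_keys=True, default=str).encode())
        return h.hexdigest()


def qc_exclude(cohort: Cohort) -> tuple:
    """Apply the exclusion rules to QC flags.

    Eye-level flags (inadequate electrode contact) discard only the
    affected eye; animal-level flags (anesthesia failure, death) discard
    every eye of that animal.  Returns ``(filtered_cohort, exclusion_log)``.
    """
    dead_animals = {e.animal_id for e in cohort.eyes if ANIMAL_LEVEL_FLAGS & set(e.qc_flags)}
    kept, log = [], []
    for eye in cohort.eyes:
        if eye.animal_id in dead_animals:
            log.append({"eye_id": eye.eye_id, "animal_id": eye.animal_id, "reason": "animal-level flag", "flags": list(eye.qc_flags)})
        elif EYE_LEVEL_FLAGS & set(eye.qc_flags):
            log.append({"eye_id": eye.eye_id, "animal_id": eye.animal_id, "reason": "eye-level flag", "flags": list(eye.qc_flags)})
        else:
            kept.append(eye)
    return Cohort(spec=cohort.spec, eyes=kept), log


def extract_cohort_features(cohort: Cohort) -> pd.DataFrame:
    """Process every eye x intensity sweep set and extract features."""
    rows = []
    for eye in cohort.eyes:
        for idx, sweeps in enumerate(eye.sweep_sets, start=1):
            bundle = process_trace(sweeps)
            feats = extract_features(bundle)
            ratios = compute_ratios(feats)
            rows.append({
                "eye_id": eye.eye_id, "animal_id": eye.animal_id, "group": eye.group,
                "intensity_index": idx, "intensity_log": feats.intensity_log,
                "a_amp_uV": feats.a_amp_uV, "a_latency_ms": feats.a_latency_ms,
                "b_amp_uV": feats.b_amp_uV, "b_latency_ms": feats.b_latency_ms,
                "op_area_uVms": feats.op_area_uVms,
                "b_over_a": ratios.b_over_a, "op_over_a": ratios.op_over_a, "op_over_b": ratios.op_over_b,
                "qc_flag": ";".join(feats.qc_flags + ratios.qc_flags),
            })
    return pd.DataFrame(rows)


def fit_cohort_hill(features: pd.DataFrame, wave: str) -> pd.DataFrame:
    """Per-eye Hill fit of one wave's amplitude-vs-intensity series."""
    col = {"a": "a_amp_uV", "b": "b_amp_uV"}[wave]
    rows = []
    for (eye_id, group), sub in features.groupby(["eye_id", "group"], sort=True):
        fit = fit_hill(sub["intensity_log"].to_numpy(), sub[col].to_numpy())
        rows.append({
            "eye_id": eye_id, "group": group, "Vmax_uV": fit.Vmax_uV, "k_log": fit.k_log,
            "n_slope": fit.n_slope, "rss": fit.rss, "converged": fit.converged,
        })
    return pd.DataFrame(rows)


def _group_values(df: pd.DataFrame, col: str, groups: list) -> tuple:
    out = []
    for g in groups:
        vals = df.loc[df["group"] == g, col].to_numpy(dtype=float)
        out.append(vals[np.isfinite(vals)])
    return tuple(out)


def run_pipeline(cohort: Cohort, plan: AnalysisPlan | None = None) -> ResultsBundle:
    """Run the full analysis on a (possibly QC-flagged) cohort.

    Deterministic: the same cohort and plan always produce bundles with the
    same :meth:`ResultsBundle.content_hash`.
    """
    plan = plan or AnalysisPlan()
    cohort, exclusions = qc_exclude(cohort)
    if not cohort.eyes:
        raise ValueError("no eyes left after QC exclusion")
    groups = cohort.group_names
    if len(groups) != 2:
        raise ValueError(f"pipeline expects exactly 2 groups, found {groups}")

    features = extract_cohort_features(cohort)
    fits_a = fit_cohort_hill(features, "a")
    fits_b = fit_cohort_hill(features, "b")

    param_stats: dict = {}
    for wave, fits in (("a", fits_a), ("b", fits_b)):
        conv = fits[fits["converged"]]
        for param in ("Vmax_uV", "k_log", "n_slope"):
            g1, g2 = _group_values(conv, param, groups)
            param_stats[(wave, param)] = two_sample_compare(g1, g2, plan.m_hill_params)

    # OP areas at the designated intensities (no curve fitting).
    op_rows = []
    for (eye_id, group), sub in features.groupby(["eye_id", "group"], sort=True):
        sub = sub.sort_values("intensity_index")
        summary = summarize_op(sub["op_area_uVms"].to_numpy(), *plan.op_intensity_indices)
        op_rows.append({
            "eye_id": eye_id, "group": group,
            f"area_idx{plan.op_intensity_indices[0]}_uVms": summary.area_at_idx8_uVms,
            f"area_idx{plan.op_intensity_indices[1]}_uVms": summary.area_at_idx13_uVms,
        })
    op_areas = pd.DataFrame(op_rows)
    op_stats = {}
    for idx in plan.op_intensity_indices:
        g1, g2 = _group_values(op_areas, f"area_idx{idx}_uVms", groups)
        op_stats[idx] = two_sample_compare(g1, g2, plan.m_op_intensities)

    # Within-trace ratios, pooled across eyes per group.
    ratio_cols = ("b_over_a", "op_over_a", "op_over_b")
    ratios = features[["eye_id", "group", "intensity_index", *ratio_cols, "qc_flag"]].copy()
    ratio_stats: dict = {}
    linear_fits: dict = {}
    if plan.include_ratios:
        for col in ratio_cols:
            g1, g2 = _group_values(ratios.dropna(subset=[col]), col, groups)
            ratio_stats[col] = two_sample_compare(g1, g2, plan.m_ratios)
        for yx, name in ((("b_amp_uV", "a_amp_uV"), "b_vs_a"),
                         (("op_area_uVms", "a_amp_uV"), "op_vs_a"),
                         (("op_area_uVms", "b_amp_uV"), "op_vs_b")):
            ycol, xcol = yx
            for g in groups:
                sub = features[(features["group"] == g) & (features[xcol] > 0)]
                linear_fits[(name, g)] = linear_fit(sub[xcol].to_numpy(), sub[ycol].to_numpy())

    provenance = {
        "software_version": __version__,
        "seed": cohort.spec.seed,
        "groups": {g: int((features["group"] == g).nunique() and len(cohort.group_eyes(g))) for g in groups},
        "sweeps_per_intensity": cohort.spec.sweeps_per_intensity,
        "n_intensities": cohort.spec.stimulus.n_steps,
        "plan": asdict(plan),
        "n_excluded": len(exclusions),
    }
    return ResultsBundle(
        features=features, fits_a=fits_a, fits_b=fits_b, param_stats=param_stats,
        op_areas=op_areas, op_stats=op_stats, ratios=ratios, ratio_stats=ratio_stats,
        linear_fits=linear_fits, exclusions=exclusions, provenance=provenance,
    )
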