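"""Orchestration of the bidirectional exposure x outcome MR grid.

For every cell of the grid: select instruments, clump, filter weak
instruments, harmonize against the outcome, run all three estimators,
assemble the sensitivity report, and issue the robust-inference call:

1. no detectable directional pleiotropy (Egger intercept p > 0.05);
2. a consistent direction of the causal estimate across all methods
   (IVW remains the primary estimate on disagreement);
3. no leave-one-out outlier.

Multiplicity is controlled per direction by Bonferroni over the number of
exposures tested in that direction.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .estimators import MREstimate, SensitivityReport
from .harmonize import harmonize_set
from .instruments import LDMatrix, build_instrument_set
from .records import StudyMeta
from .sumstats_io import Dialect, deduplicate, read_sumstats

__all__ = [
    "MRConfig",
    "StudySpec",
    "CausalCall",
    "bonferroni_threshold",
    "format_threshold",
    "robust_call",
    "run_direction",
    "make_reports",
    "calls_to_tables",
    "load_manifest",
]


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def format_threshold(threshold: float) -> str:
    """Render a threshold to 2 significant figures the way reports print it
    (decimal at or above 1e-3, otherwise compact scientific)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exponent = math.floor(math.log10(threshold))
    rounded = round(threshold, -exponent + 1)
    if rounded >= 1e-3:
        return f"{rounded:.{max(0, -exponent + 1)}f}"
    mantissa = rounded / 10.0**exponent
    if mantissa >= 10:  # rounding carried over a decade
        mantissa /= 10
        exponent += 1
    return f"{mantissa:.1f}e{exponent}"


@dataclass
class MRConfig:
    """All knobs of the analysis, in one place (YAML-loadable)."""

    alpha: float = 0.05
    p_primary: float = 5e-8
    p_fallback: float = 5e-6
    min_count: int = 3
    window_kb: float = 10_000
    r2_max: float = 0.001
    f_min: float = 10.0
    ambiguity_window: float = 0.08
    effects_model: str = "multiplicative_random"
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "MRConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


@dataclass
class StudySpec:
    """One study in a manifest: where its file is and what it measures."""

    study_id: str
    path: str
    trait_type: str = "continuous"
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    dialect: Optional[Dialect] = None
    ld_path: Optional[str] = None

    def meta(self) -> StudyMeta:
        return StudyMeta(
            study_id=self.study_id,
            trait_type=self.trait_type,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )


def load_manifest(path: str | Path) -> list[StudySpec]:
    """Read a YAML manifest listing study files."""
    data = yaml.safe_load(Path(path).read_text())
    specs = []
    for entry in data["studies"]:
        dialect_path = entry.pop("dialect", None)
        spec = StudySpec(**entry)
        if dialect_path:
            spec.dialect = Dialect.from_file(dialect_path)
        specs.append(spec)
    return specs


@dataclass
class CausalCall:
    """The per-cell verdict: estimates, sensitivity, tier and robustness."""

    exposure_id: str
    outcome_id: str
    direction: str  # forward | reverse
    primary_estimate: Optional[MREstimate]
    all_estimates: list[MREstimate] = field(default_factory=list)
    sensitivity: Optional[SensitivityReport] = None
    significance_tier: str = "null"  # bonferroni | suggestive | null
    robust: bool = False
    criteria_breakdown: dict = field(default_factory=dict)
    attrition: dict = field(default_factory=dict)
    n_instruments: int = 0
    threshold_used: Optional[float] = None
    reason: Optional[str] = None  # populated for null cells


def robust_call(
    all_estimates: Sequence[MREstimate],
    sensitivity: SensitivityReport,
    threshold: float,
    exposure_id: str = "",
    outcome_id: str = "",
    direction: str = "forward",
    alpha: float = 0.05,
) -> CausalCall:
    """Apply the three-criterion robustness rule and assign a significance tier.

    Criterion 2 compares the sign of the causal estimate across every
    available method; IVW stays the primary estimate even when methods
    disagree. Criteria that cannot be evaluated (too few instruments for
    Egger or leave-one-out) are recorded as ``None`` and fail the
    conjunction, so robustness is never claimed on missing evidence.
    """
    by_method = {e.method: e for e in all_estimates}
    primary = by_method.get("ivw") or (all_estimates[0] if all_estimates else None)

    no_pleiotropy: Optional[bool] = None
    if sensitivity is not None and sensitivity.egger_intercept_pval is not None:
        no_pleiotropy = sensitivity.egger_intercept_pval > alpha

    direction_consistent: Optional[bool] = None
    signs = {np.sign(e.beta) for e in all_estimates}
    if len(all_estimates) >= 2:
        direction_consistent = len(signs) == 1
    elif len(all_estimates) == 1:
        direction_consistent = True

    no_loo_outlier: Optional[bool] = None
    if sensitivity is not None and len(sensitivity.loo_table) > 0:
        no_loo_outlier = not sensitivity.loo_outlier_flag

    criteria = {
        "no_pleiotropy": no_pleiotropy,
        "direction_consistent": direction_consistent,
        "no_loo_outlier": no_loo_outlier,
    }
    robust = all(v is True for v in criteria.values())

    tier = "null"
    if primary is not None:
        if primary.pval < threshold:
            tier = "bonferroni"
        elif primary.pval < alpha:
            tier = "suggestive"

    return CausalCall(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        direction=direction,
        primary_estimate=primary,
        all_estimates=list(all_estimates),
        sensitivity=sensitivity,
        significance_tier=tier,
        robust=robust,
        criteria_breakdown=criteria,
    )


def _analyze_cell(
    exposure: StudySpec,
    outcome: StudySpec,
    iset,
    outcome_cache: dict,
    config: MRConfig,
    threshold: float,
    direction: str,
) -> CausalCall:
    call_stub = CausalCall(
        exposure_id=exposure.study_id,
        outcome_id=outcome.study_id,
        direction=direction,
        primary_estimate=None,
        threshold_used=iset.threshold_used,
    )
    if len(iset) == 0:
        call_stub.reason = "no instruments"
        return call_stub

    if outcome.study_id not in outcome_cache:
        recs, _ = read_sumstats(outcome.path, outcome.dialect)
        recs, _ = deduplicate(recs)
        outcome_cache[outcome.study_id] = recs
    out_records = outcome_cache[outcome.study_id]

    pairs, attrition = harmonize_set(iset, out_records, config.ambiguity_window)
    call_stub.attrition = attrition
    analyzed = [p for p in pairs if not p.dropped]
    call_stub.n_instruments = len(analyzed)
    if not analyzed:
        call_stub.reason = "no harmonized pairs"
        return call_stub

    binary = outcome.trait_type == "binary"
    estimates: list[MREstimate] = [est.ivw(analyzed, config.effects_model)]
    sensitivity = None
    if len(analyzed) >= 3:
        estimates.append(
            est.weighted_median(analyzed, n_boot=config.n_boot, seed=config.seed)
        )
        egger, *_ = est.mr_egger(analyzed)
        estimates.append(egger)
        sensitivity = est.sensitivity_report(analyzed, estimates[0], config.effects_model)
    elif len(analyzed) >= 2:
        sensitivity = est.sensitivity_report(analyzed, estimates[0], config.effects_model)
    if binary:
        estimates = [e.with_odds_ratio() for e in estimates]

    call = robust_call(
        estimates,
        sensitivity,
        threshold,
        exposure_id=exposure.study_id,
        outcome_id=outcome.study_id,
        direction=direction,
        alpha=config.alpha,
    )
    call.attrition = attrition
    call.n_instruments = len(analyzed)
    call.threshold_used = iset.threshold_used
    return call


def run_direction(
    exposures: Sequence[StudySpec],
    outcomes: Sequence[StudySpec],
    config: Optional[MRConfig] = None,
    direction: str = "forward",
    ld_matrices: Optional[dict] = None,
) -> list[CausalCall]:
    """Analyze the full exposures x outcomes cross in one direction.

    The Bonferroni denominator is the number of exposures tested in this
    direction. Cells that end with no usable instruments yield a null call
    with a reason; a study whose file cannot be read voids only its own
    cells.
    """
    config = config or MRConfig()
    threshold = bonferroni_threshold(config.alpha, max(len(exposures), 1))
    ld_matrices = dict(ld_matrices or {})
    calls: list[CausalCall] = []
    outcome_cache: dict = {}
    for exposure in exposures:
        ld = ld_matrices.get(exposure.study_id)
        if ld is None and exposure.ld_path:
            try:
                ld = LDMatrix.from_file(exposure.ld_path)
                ld_matrices[exposure.study_id] = ld
            except OSError as exc:
                warnings.warn(f"cannot read LD matrix for {exposure.study_id}: {exc}")
        try:
            exp_records, _ = read_sumstats(exposure.path, exposure.dialect)
            exp_records, _ = deduplicate(exp_records)
            iset = build_instrument_set(
                exposure.study_id,
                exp_records,
                ld=ld,
                p_primary=config.p_primary,
                p_fallback=config.p_fallback,
                min_count=config.min_count,
                window_kb=config.window_kb,
                r2_max=config.r2_max,
                f_min=config.f_min,
            )
        except (OSError, ValueError) as exc:
            for outcome in outcomes:
                calls.append(
                    CausalCall(
                        exposure_id=exposure.study_id,
                        outcome_id=outcome.study_id,
                        direction=direction,
                        primary_estimate=None,
                        reason=f"error: {exc}",
                    )
                )
            continue
        for outcome in outcomes:
            try:
                calls.append(
                    _analyze_cell(
                        exposure, outcome, iset, outcome_cache, config, threshold, direction
                    )
                )
            except (OSError, ValueError) as exc:
                calls.append(
                    CausalCall(
                        exposure_id=exposure.study_id,
                        outcome_id=outcome.study_id,
                        direction=direction,
                        primary_estimate=None,
                        reason=f"error: {exc}",
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# report tables


def _estimate_rows(call: CausalCall):
    for e in call.all_estimates:
        or_, or_lo, or_hi = e.or_scale if e.or_scale else (None, None, None)
        yield (
            call.exposure_id,
            call.outcome_id,
            call.direction,
            e.method,
            e.n_snp,
            e.beta,
            e.se,
            e.ci_low,
            e.ci_high,
            e.pval,
            or_,
            or_lo,
            or_hi,
        )


def calls_to_tables(calls: Sequence[CausalCall]) -> dict[str, pd.DataFrame]:
    """Flatten calls into the estimates/sensitivity/calls/attrition tables."""
    est_rows = [row for c in calls for row in _estimate_rows(c)]
    estimates = pd.DataFrame(
        est_rows,
        columns=[
            "exposure",
            "outcome",
            "direction",
            "method",
            "n_snp",
            "beta",
            "se",
            "ci_low",
            "ci_high",
            "pval",
            "or",
            "or_low",
            "or_high",
        ],
    )
    sens_rows = []
    for c in calls:
        s = c.sensitivity
        if s is None:
            continue
        sens_rows.append(
            (
                c.exposure_id,
                c.outcome_id,
                c.direction,
                s.q,
                s.q_df,
                s.q_pval,
                s.egger_intercept,
                s.egger_intercept_pval,
                s.loo_outlier_flag,
            )
        )
    sensitivity = pd.DataFrame(
        sens_rows,
        columns=[
            "exposure",
            "outcome",
            "direction",
            "q",
            "q_df",
            "q_pval",
            "egger_intercept",
            "egger_intercept_pval",
            "loo_outlier_flag",
        ],
    )
    call_rows = []
    for c in calls:
        p = c.primary_estimate
        call_rows.append(
            (
                c.exposure_id,
                c.outcome_id,
                c.direction,
                c.n_instruments,
                None if p is None else p.beta,
                None if p is None else p.pval,
                c.significance_tier,
                c.robust,
                c.criteria_breakdown.get("no_pleiotropy"),
                c.criteria_breakdown.get("direction_consistent"),
                c.criteria_breakdown.get("no_loo_outlier"),
                c.reason,
            )
        )
    calls_df = pd.DataFrame(
        call_rows,
        columns=[
            "exposure",
            "outcome",
            "direction",
            "n_snp",
            "beta_ivw",
            "pval_ivw",
            "tier",
            "robust",
            "no_pleiotropy",
            "direction_consistent",
            "no_loo_outlier",
            "reason",
        ],
    )
    attr_rows = []
    for c in calls:
        a = c.attrition or {}
        attr_rows.append(
            (
                c.exposure_id,
                c.outcome_id,
                c.direction,
                a.get("missing_in_outcome", 0),
                a.get("dropped_incompatible", 0),
                a.get("dropped_ambiguous_palindrome", 0),
                a.get("analyzed", 0),
            )
        )
    attrition = pd.DataFrame(
        attr_rows,
        columns=[
            "exposure",
            "outcome",
            "direction",
            "missing_in_outcome",
            "dropped_incompatible",
            "dropped_ambiguous_palindrome",
            "analyzed",
        ],
    )
    return {
        "estimates": estimates,
        "sensitivity": sensitivity,
        "calls": calls_df,
        "attrition": attrition,
    }


def make_reports(calls: Sequence[CausalCall]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the heatmap matrix (signed -log10 p per method) and the
    forest-plot table from a list of calls."""
    heat_rows = []
    forest_rows = []
    for c in calls:
        for e in c.all_estimates:
            heat_rows.append(
                (
                    c.exposure_id,
                    c.outcome_id,
                    c.direction,
                    e.method,
                    float(np.sign(e.beta) * -np.log10(max(e.pval, 1e-300))),
                )
            )
            or_, or_lo, or_hi = e.or_scale if e.or_scale else (None, None, None)
            forest_rows.append(
                (
                    c.exposure_id,
                    c.outcome_id,
                    c.direction,
                    e.method,
                    or_ if or_ is not None else e.beta,
                    or_lo if or_lo is not None else e.ci_low,
                    or_hi if or_hi is not None else e.ci_high,
                    e.pval,
                    c.significance_tier,
                    c.robust,
                )
            )
    heatmap = pd.DataFrame(
        heat_rows,
        columns=["exposure", "outcome", "direction", "method", "signed_neglog10_p"],
    )
    if not heatmap.empty:
        heatmap = heatmap.pivot_table(
            index="exposure",
            columns=["outcome", "method"],
            values="signed_neglog10_p",
            sort=True,
        )
    forest = pd.DataFrame(
        forest_rows,
        columns=[
            "exposure",
            "outcome",
            "direction",
            "method",
            "estimate",
            "ci_low",
            "ci_high",
            "pval",
            "tier",
            "robust",
        ],
    )
    return heatmap, forest


def write_tables(calls: Sequence[CausalCall], out_dir: str | Path) -> dict[str, Path]:
    """Write estimates/sensitivity/calls/attrition/heatmap TSVs plus a
    JSON-lines log of per-cell stage decisions to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = calls_to_tables(calls)
    heatmap, forest = make_reports(calls)
    tables["heatmap"] = heatmap.reset_index() if not heatmap.empty else heatmap
    tables["forest"] = forest
    paths = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    log_path = out_dir / "decisions.jsonl"
    with log_path.open("w") as fh:
        for c in calls:
            fh.write(
                json.dumps(
                    {
                        "exposure": c.exposure_id,
                        "outcome": c.outcome_id,
                        "direction": c.direction,
                        "threshold_used": c.threshold_used,
                        "n_instruments": c.n_instruments,
                        "attrition": c.attrition,
                        "tier": c.significance_tier,
                        "robust": c.robust,
                        "criteria": c.criteria_breakdown,
                        "reason": c.reason,
                    }
                )
                + "\n"
            )
    paths["decisions"] = log_path
    return paths
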