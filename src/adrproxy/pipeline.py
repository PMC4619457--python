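"""End-to-end validation pipeline and report writers.

``run_pipeline`` chains the stages for each configured gap setting —
pattern classification, medical-record adjudication, tabulation, accuracy
metrics with the matched-duration sensitivity/specificity design — and
writes the report bundle: ``counts.csv`` (the contingency table),
``metrics.csv``, ``durations.csv`` (treatment-duration summaries per
category), ``reclassification.csv`` (category transitions between the two
gap settings) and ``run_log.yaml``.

A counts-only entry point (:func:`metrics_from_counts`) accepts a prefilled
contingency table, which is how the published validation tables are
reproduced without patient-level data.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjudication import (
    DEFAULT_AFTER_DAYS,
    DEFAULT_BEFORE_DAYS,
    AscertainmentLevel,
    PatientClass,
    adjudicate_cohort,
)
from .episodes import (
    DEFAULT_LOOKBACK_DAYS,
    DEFAULT_STUDY_END,
    DEFAULT_STUDY_START,
    PatternCategory,
    classify_cohort,
    identify_starters,
)
from .errors import ConfigError
from .io import read_inputs
from .metrics import (
    CONTINUATION_MINUS_DEATH,
    CONTINUATION_TOTAL,
    SWITCHERS_TOTAL,
    TOTAL_DISCONTINUATION,
    ValidationCounts,
    match_controls,
    npv,
    ppv,
    sensitivity_specificity,
    tabulate,
)

__all__ = ["RunConfig", "run_pipeline", "metrics_from_counts", "durations_table"]

_PPV_GROUPS = [
    PatternCategory.SWITCH_ARB,
    PatternCategory.SWITCH_OTHER,
    PatternCategory.STOP,
    SWITCHERS_TOTAL,
    TOTAL_DISCONTINUATION,
]
_NPV_GROUPS = [
    PatternCategory.CONT_END_OF_STUDY,
    PatternCategory.CONT_OUT_OF_STUDY,
    PatternCategory.CONT_DEATH,
    CONTINUATION_MINUS_DEATH,
    CONTINUATION_TOTAL,
]
_MATCH_GROUPS = [
    PatternCategory.SWITCH_ARB,
    PatternCategory.SWITCH_OTHER,
    PatternCategory.STOP,
    SWITCHERS_TOTAL,
]


@dataclass
class RunConfig:
    """Settings for a full validation run; defaults mirror the reference
    design (90/180-day gaps, -180/+90-day review window, 95 % Wilson CIs)."""

    dispensing_path: str | Path = "dispensing.csv"
    followup_path: str | Path = "followup.csv"
    events_path: str | Path | None = "gp_events.csv"
    out_dir: str | Path = "out"
    study_start: _dt.date = DEFAULT_STUDY_START
    study_end: _dt.date = DEFAULT_STUDY_END
    lookback_days: int = DEFAULT_LOOKBACK_DAYS
    gap_days: list[int] = field(default_factory=lambda: [90, 180])
    #: None ties the switch window to the gap setting
    switch_window_days: int | None = None
    before_days: int = DEFAULT_BEFORE_DAYS
    after_days: int = DEFAULT_AFTER_DAYS
    ci_method: str = "wilson"
    conf_level: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.gap_days or any(g <= 0 for g in self.gap_days):
            raise ConfigError("gap_days must be a non-empty list of positive ints")
        if not 0 < self.conf_level < 1:
            raise ConfigError("conf_level must be in (0, 1)")
        for attr in ("study_start", "study_end"):
            v = getattr(self, attr)
            if isinstance(v, str):
                setattr(self, attr, _dt.date.fromisoformat(v))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {}
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            if isinstance(v, (Path, _dt.date)):
                v = str(v)
            d[k] = v
        return d


def _metric_row(metric, group, level, term, est, gap_days):
    gname = group.value if isinstance(group, PatternCategory) else str(group)
    return {
        "metric": metric,
        "group": gname,
        "level": level.value if level is not None else "",
        "term": term or "",
        "numerator": est.numerator,
        "denominator": est.denominator,
        "estimate_pct": round(est.pct, 1),
        "ci_low_pct": round(100 * est.ci_low, 1),
        "ci_high_pct": round(100 * est.ci_high, 1),
        "gap_days": gap_days,
    }


def metrics_from_counts(
    counts: ValidationCounts,
    gap_days: int = 180,
    conf_level: float = 0.95,
    ci_method: str = "wilson",
    cough_term: str = "cough",
) -> pd.DataFrame:
    """All predictive values derivable from a contingency table alone:
    PPVs at the three ascertainment levels, the cough-only PPVs, and the
    NPVs at the two defined levels, each with a two-sided CI."""
    rows = []
    for group in _PPV_GROUPS:
        if counts.group_n(group) == 0:  # graceful on empty cohorts
            continue
        for level in AscertainmentLevel:
            est = ppv(counts, group, level, conf_level=conf_level, method=ci_method)
            rows.append(_metric_row("ppv", group, level, None, est, gap_days))
        est = ppv(
            counts,
            group,
            AscertainmentLevel.DEFINITE,
            term_filter=cough_term,
            conf_level=conf_level,
            method=ci_method,
        )
        rows.append(
            _metric_row("ppv_cough", group, AscertainmentLevel.DEFINITE, cough_term, est, gap_days)
        )
    for group in _NPV_GROUPS:
        if counts.group_n(group) == 0:
            continue
        for level in (AscertainmentLevel.AT_LEAST_POSSIBLE, AscertainmentLevel.AT_LEAST_PROBABLE):
            est = npv(counts, group, level, conf_level=conf_level, method=ci_method)
            rows.append(_metric_row("npv", group, level, None, est, gap_days))
    return pd.DataFrame(rows)


def _matched_metrics(
    patterns: pd.DataFrame,
    adjud: pd.DataFrame,
    events: pd.DataFrame,
    gap_days: int,
    conf_level: float,
    ci_method: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Duration-matched sensitivity/specificity rows (definite ADRs only)."""
    from .adjudication import adjudicate_control, _events_from_frame

    if patterns.empty:
        return pd.DataFrame()
    by_patient = _events_from_frame(events)
    merged = patterns.merge(adjud[["patient_id", "patient_class"]], on="patient_id")
    continuers = merged[merged["category"].map(lambda c: c.is_continuation)]
    pool = list(zip(continuers["patient_id"], continuers["acei_duration_days"]))
    info = merged.set_index("patient_id")
    rows = []
    for group in _MATCH_GROUPS:
        if isinstance(group, PatternCategory):
            cases = merged[merged["category"] == group]
        else:  # switchers total
            cases = merged[
                merged["category"].isin(
                    [PatternCategory.SWITCH_ARB, PatternCategory.SWITCH_OTHER]
                )
            ]
        if cases.empty:
            continue
        pairs, unmatched = match_controls(
            list(zip(cases["patient_id"], cases["acei_duration_days"])), pool, rng
        )
        if not pairs:
            continue
        case_classes = [
            PatientClass(info.loc[p.case_id, "patient_class"]) for p in pairs
        ]
        control_classes = []
        for p in pairs:
            start = pd.Timestamp(info.loc[p.control_id, "episode_start"]).date()
            res = adjudicate_control(
                p.control_id,
                by_patient.get(p.control_id, []),
                start,
                int(p.evaluation_duration_days),
            )
            control_classes.append(res.patient_class)
        sens, spec = sensitivity_specificity(
            case_classes, control_classes, conf_level, ci_method
        )
        for metric, est in (("sensitivity", sens), ("specificity", spec)):
            row = _metric_row(metric, group, AscertainmentLevel.DEFINITE, None, est, gap_days)
            row["n_unmatched"] = len(unmatched)
            rows.append(row)
    return pd.DataFrame(rows)


def durations_table(patterns: pd.DataFrame, gap_days: int) -> pd.DataFrame:
    """Treatment-duration summary per category (count, %, median/mean/SD)."""
    rows = []
    total = len(patterns)
    for cat in PatternCategory:
        sub = patterns[patterns["category"] == cat]["acei_duration_days"]
        rows.append(
            {
                "category": cat.value,
                "n": len(sub),
                "pct_of_total": round(100 * len(sub) / total, 1) if total else 0.0,
                "median_duration_days": float(sub.median()) if len(sub) else float("nan"),
                "mean_duration_days": round(float(sub.mean()), 1) if len(sub) else float("nan"),
                "sd_duration_days": round(float(sub.std()), 1) if len(sub) > 1 else float("nan"),
                "gap_days": gap_days,
            }
        )
    rows.append(
        {
            "category": "TOTAL",
            "n": total,
            "pct_of_total": 100.0 if total else 0.0,
            "median_duration_days": float(patterns["acei_duration_days"].median())
            if total
            else float("nan"),
            "mean_duration_days": round(float(patterns["acei_duration_days"].mean()), 1)
            if total
            else float("nan"),
            "sd_duration_days": round(float(patterns["acei_duration_days"].std()), 1)
            if total > 1
            else float("nan"),
            "gap_days": gap_days,
        }
    )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run classification, adjudication, tabulation and metrics for every
    configured gap setting; write the report bundle to ``config.out_dir``.

    Returns the report frames keyed by output name.  On failure every
    partially written output is removed.
    """
    disp, fu, events = read_inputs(
        config.dispensing_path, config.followup_path, config.events_path
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        starters = identify_starters(
            disp, fu, config.study_start, config.lookback_days
        )
        rng = np.random.default_rng(config.rng_seed)
        all_counts, all_metrics, all_durations, classifications = [], [], [], {}
        for gap in config.gap_days:
            patterns = classify_cohort(
                disp,
                fu,
                gap_days=gap,
                switch_window_days=config.switch_window_days,
                study_start=config.study_start,
                lookback_days=config.lookback_days,
                starters=starters,
            )
            classifications[gap] = patterns
            cohort_events = events[events["patient_id"].isin(starters)]
            adjud = adjudicate_cohort(
                patterns, cohort_events, config.before_days, config.after_days
            )
            counts = tabulate(patterns, adjud)
            cf = counts.to_frame()
            cf.insert(0, "gap_days", gap)
            all_counts.append(cf)
            mf = metrics_from_counts(counts, gap, config.conf_level, config.ci_method)
            sf = _matched_metrics(
                patterns, adjud, cohort_events, gap, config.conf_level, config.ci_method, rng
            )
            all_metrics.append(pd.concat([mf, sf], ignore_index=True))
            all_durations.append(durations_table(patterns, gap))

        reports: dict[str, pd.DataFrame] = {
            "counts": pd.concat(all_counts, ignore_index=True),
            "metrics": pd.concat(all_metrics, ignore_index=True),
            "durations": pd.concat(all_durations, ignore_index=True),
        }
        if len(config.gap_days) >= 2:
            g1, g2 = min(config.gap_days), max(config.gap_days)
            a, b = classifications[g1], classifications[g2]
            merged = a[["patient_id", "category"]].merge(
                b[["patient_id", "category"]], on="patient_id", suffixes=("_a", "_b")
            )
            rec = (
                merged.assign(
                    category_a=merged["category_a"].map(lambda c: c.value),
                    category_b=merged["category_b"].map(lambda c: c.value),
                )
                .groupby(["category_a", "category_b"])
                .size()
                .reset_index(name="n")
            )
            rec.insert(0, "gap_days_a", g1)
            rec.insert(1, "gap_days_b", g2)
            reports["reclassification"] = rec

        for name, df in reports.items():
            p = out / f"{name}.csv"
            serial = df.copy()
            for col in serial.columns:
                if serial[col].map(lambda v: isinstance(v, PatternCategory)).any():
                    serial[col] = serial[col].map(
                        lambda v: v.value if isinstance(v, PatternCategory) else v
                    )
            serial.to_csv(p, index=False)
            written.append(p)
        log = {
            "software": f"adrproxy {__version__}",
            "config": config.to_dict(),
            "n_starters": len(starters),
        }
        p = out / "run_log.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=True)
        written.append(p)
        return reports
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
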