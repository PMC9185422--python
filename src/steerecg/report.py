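"""Scenario- and study-level aggregation of usability and SNR results.

Percentage bookkeeping follows the study's reporting convention: each
scenario's usable percentage is ``round(100 * usable / total, 2)``, and
the headline driving figure is the unweighted mean of the three driving
scenarios' rounded percentages (rest is excluded — it is not driving),
itself rounded to two decimals.  The unweighted mean is used rather than
minute-weighted pooling because the per-scenario totals are equal anyway
and the convention keeps scenario percentages and the headline mutually
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DRIVING_SCENARIOS = ("city", "highway", "rural")


@dataclass
class SubjectScenarioResult:
    """One subject's outcome in one scenario."""

    subject_id: str
    scenario: str
    total_minutes: float
    usable_minutes: float
    snr_db: float


@dataclass
class ScenarioSummary:
    """Scenario-level roll-up across subjects."""

    scenario: str
    n_subjects: int
    total_minutes: float
    usable_minutes: float
    usable_pct: float
    mean_snr_db: float
    subject_snr_db: list[float] = field(default_factory=list)


@dataclass
class StudySummary:
    """Whole-study roll-up.

    ``driving_mean_usable_pct`` averages the city/highway/rural usable
    percentages; ``daily_usable_minutes`` projects that rate onto an
    average daily driving time.
    """

    scenarios: dict[str, ScenarioSummary]
    driving_mean_usable_pct: float
    daily_driving_min: float
    daily_usable_minutes: float


def usable_pct(usable_minutes: float, total_minutes: float) -> float:
    """Usable percentage, rounded to two decimals."""
    if total_minutes <= 0:
        raise ValueError(f"total_minutes must be positive, got {total_minutes}")
    return round(100.0 * usable_minutes / total_minutes, 2)


def summarize_scenario(results: list[SubjectScenarioResult]) -> ScenarioSummary:
    """Aggregate one scenario across subjects.

    Minutes are summed, the percentage recomputed from the summed
    minutes, and SNR averaged across subjects.
    """
    if not results:
        raise ValueError("no results to summarize")
    scenarios = {r.scenario for r in results}
    if len(scenarios) != 1:
        raise ValueError(f"results mix scenarios: {sorted(scenarios)}")
    total = sum(r.total_minutes for r in results)
    usable = sum(r.usable_minutes for r in results)
    snrs = [r.snr_db for r in results]
    return ScenarioSummary(
        scenario=results[0].scenario,
        n_subjects=len(results),
        total_minutes=total,
        usable_minutes=usable,
        usable_pct=usable_pct(usable, total),
        mean_snr_db=float(np.mean(snrs)),
        subject_snr_db=snrs,
    )


def summarize_study(
    summaries: dict[str, ScenarioSummary] | list[ScenarioSummary],
    daily_driving_min: float = 30.0,
) -> StudySummary:
    """Roll scenario summaries up to the study headline.

    Requires the three driving scenarios; rest is optional and excluded
    from the headline percentage.
    """
    if isinstance(summaries, list):
        summaries = {s.scenario: s for s in summaries}
    missing = [s for s in DRIVING_SCENARIOS if s not in summaries]
    if missing:
        raise ValueError(f"missing driving scenarios: {missing}")
    driving = round(
        float(np.mean([summaries[s].usable_pct for s in DRIVING_SCENARIOS])), 2
    )
    return StudySummary(
        scenarios=dict(summaries),
        driving_mean_usable_pct=driving,
        daily_driving_min=daily_driving_min,
        daily_usable_minutes=driving / 100.0 * daily_driving_min,
    )


def export_snr_distribution(
    results: list[SubjectScenarioResult],
) -> pd.DataFrame:
    """Long-format SNR table (subject, scenario, snr_db) for raincloud plots."""
    return pd.DataFrame(
        [
            {"subject": r.subject_id, "scenario": r.scenario, "snr_db": r.snr_db}
            for r in results
        ],
        columns=["subject", "scenario", "snr_db"],
    )


def summary_frame(summaries: dict[str, ScenarioSummary]) -> pd.DataFrame:
    """Scenario summaries as a tidy DataFrame."""
    rows = []
    for name, s in summaries.items():
        rows.append(
            {
                "scenario": name,
                "n_subjects": s.n_subjects,
                "total_minutes": s.total_minutes,
                "usable_minutes": s.usable_minutes,
                "usable_pct": s.usable_pct,
                "mean_snr_db": s.mean_snr_db,
            }
        )
    return pd.DataFrame(rows)
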