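"""Intraindividual standard deviation (IISD) of model residuals.

For each subject and outcome, the IISD is the sample SD (denominator
n-1) of that subject's conditional residuals across visits — the core
longitudinal-inconsistency metric.  Outcome-level summaries are the
unweighted mean IISD over subjects with a percentile cluster bootstrap
(subjects resampled with replacement) for the 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IISDResult",
    "compute_iisd",
    "summarize_iisd",
    "rank_outcomes_by_iisd",
]

log = logging.getLogger(__name__)


@dataclass
class IISDResult:
    outcome: str
    per_subject: pd.Series        # subject -> IISD (subjects with >= 2 visits)
    visit_counts: pd.Series
    n_excluded: int               # subjects with < 2 residuals
    mean_iisd: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_boot: int = 0
    seed: int | None = None
    weighted: bool = False

    def summary_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "mean_iisd": self.mean_iisd,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_subjects": int(self.per_subject.size),
            "n_excluded": self.n_excluded,
            "n_boot": self.n_boot, "seed": self.seed,
            "weighted": self.weighted,
        }


def compute_iisd(
    residuals: pd.Series, subject_ids: np.ndarray | pd.Series,
    outcome: str = "",
) -> IISDResult:
    """Per-subject sample SD of residuals; subjects with < 2 residuals
    are excluded (and counted), not an error."""
    frame = pd.DataFrame({
        "subject_id": np.asarray(subject_ids),
        "resid": np.asarray(residuals, dtype=float),
    }).dropna(subset=["resid"])
    grouped = frame.groupby("subject_id")["resid"]
    counts = grouped.size()
    ok = counts[counts >= 2].index
    iisd = grouped.std(ddof=1).loc[ok]
    iisd.name = outcome or "iisd"
    return IISDResult(
        outcome=outcome, per_subject=iisd, visit_counts=counts.loc[ok],
        n_excluded=int((counts < 2).sum()),
    )


def summarize_iisd(
    result: IISDResult, n_boot: int = 1000, seed: int = 0,
    weighted: bool = False,
) -> IISDResult:
    """Mean IISD over subjects with a percentile cluster bootstrap CI.

    Subjects are the resampling unit; deterministic given ``seed``.
    ``weighted=True`` weights each subject by its visit count (the
    default treats subjects equally regardless of visit count).
    """
    values = result.per_subject.to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 subjects to summarize IISD")
    if n_boot < 100:
        log.warning("bootstrap replicate count %d < 100; CI will be crude",
                    n_boot)
    weights = (result.visit_counts.to_numpy(dtype=float) if weighted
               else np.ones_like(values))

    def wmean(idx: np.ndarray) -> np.ndarray:
        v, w = values[idx], weights[idx]
        return (v * w).sum(axis=-1) / w.sum(axis=-1)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot_means = wmean(idx)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    result.mean_iisd = float((values * weights).sum() / weights.sum())
    result.ci_low, result.ci_high = float(lo), float(hi)
    result.n_boot, result.seed, result.weighted = n_boot, seed, weighted
    return result


def rank_outcomes_by_iisd(results: list[IISDResult]) -> list[str]:
    """Outcomes ordered by ascending mean IISD; ties broken
    alphabetically."""
    if len(results) < 2:
        raise ValueError("need >= 2 outcomes to rank")
    return [r.outcome for r in
            sorted(results, key=lambda r: (r.mean_iisd, r.outcome))]


def iisd_table(results: list[IISDResult]) -> pd.DataFrame:
    """Outcome-level summary table (one row per outcome)."""
    return pd.DataFrame([r.summary_dict() for r in results]).set_index("outcome")
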