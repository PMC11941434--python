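"""Shot-locked Psi analysis: pre-event curves, random baselines, statistics.

For every shot, the Psi values of the 60 windows ending in the 60 s before
the shot (window ends shot-60 .. shot-1) form one curve per role: the
shooting team is labelled *attacker*, the opponent *defender*, and the
labels persist even when possession changes inside the window.  A baseline
set of randomly placed same-half intervals, matched in number to the shots,
is drawn from the attacking team's series.  Group differences per relative
timepoint use Welch's t-test with Bonferroni correction; temporal trends
are ordinary least squares on the across-event mean curve.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .emergence import PsiSeries
from .tracking import EventLog

logger = logging.getLogger(__name__)


class EventAnalysisError(ValueError):
    pass


@dataclasses.dataclass
class EventAlignedCurves:
    """Shot-aligned Psi curves at relative times -duration .. -1 s.

    ``attacker``/``defender``/``baseline`` are (n_events, duration) arrays;
    ``dropped`` records shots without full Psi coverage and why.
    """

    rel_times: np.ndarray
    attacker: np.ndarray
    defender: np.ndarray
    baseline: np.ndarray | None = None
    shots: list[tuple[float, str]] = dataclasses.field(default_factory=list)
    dropped: list[tuple[float, str]] = dataclasses.field(default_factory=list)

    def group(self, name: str) -> np.ndarray:
        out = getattr(self, name)
        if out is None:
            raise EventAnalysisError(f"group {name!r} not populated")
        return out

    def mean(self, name: str) -> np.ndarray:
        return self.group(name).mean(axis=0)

    def sem(self, name: str) -> np.ndarray:
        g = self.group(name)
        return g.std(axis=0, ddof=1) / np.sqrt(g.shape[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        names = ["attacker", "defender"] + (["baseline"] if self.baseline is not None else [])
        for name in names:
            rows.append(
                pd.DataFrame(
                    {
                        "relative_t": self.rel_times,
                        "group": name,
                        "mean": self.mean(name),
                        "sem": self.sem(name),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclasses.dataclass
class TrendResult:
    """OLS trend of a mean Psi curve against relative time (seconds)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    label: str = ""
    degenerate: bool = False


def _time_index(psi: PsiSeries) -> dict[float, int]:
    return {float(t): i for i, t in enumerate(psi.times)}


def _curve_at(psi: PsiSeries, index: dict[float, int], end_times: np.ndarray) -> np.ndarray | None:
    """Psi values at the given window-end times, or None if any is missing/flagged."""
    idx = np.empty(len(end_times), dtype=int)
    for k, t in enumerate(end_times):
        i = index.get(float(t))
        if i is None:
            return None
        idx[k] = i
    if not psi.valid[idx].all():
        return None
    return psi.psi[idx]


def extract_pre_event_curves(
    psi_by_team: Mapping[str, PsiSeries],
    events: EventLog,
    duration_s: int = 60,
) -> EventAlignedCurves:
    """Attacker and defender Psi curves for every shot with full coverage.

    ``psi_by_team`` maps team label to that team's (possibly multi-half,
    concatenated) PsiSeries.  Shots whose pre-event interval is not fully
    covered by valid windows in both teams' series are dropped with a
    logged reason.
    """
    indexes = {team: _time_index(s) for team, s in psi_by_team.items()}
    rel_times = np.arange(-duration_s, 0, dtype=float)
    attacker_rows, defender_rows, kept, dropped = [], [], [], []
    for t_shot, shooter in zip(events.shots()["t"], events.shots()["team"]):
        t_shot = float(t_shot)
        opponent = next(t for t in psi_by_team if t != shooter)
        ends = t_shot + rel_times  # shot-60 .. shot-1
        atk = _curve_at(psi_by_team[shooter], indexes[shooter], ends)
        dfd = _curve_at(psi_by_team[opponent], indexes[opponent], ends)
        if atk is None or dfd is None:
            reason = "incomplete attacker coverage" if atk is None else "incomplete defender coverage"
            dropped.append((t_shot, reason))
            logger.info("dropping shot at t=%s: %s", t_shot, reason)
            continue
        attacker_rows.append(atk)
        defender_rows.append(dfd)
        kept.append((t_shot, str(shooter)))
    if not attacker_rows:
        raise EventAnalysisError("no shot with full pre-event Psi coverage")
    return EventAlignedCurves(
        rel_times=rel_times,
        attacker=np.asarray(attacker_rows),
        defender=np.asarray(defender_rows),
        shots=kept,
        dropped=dropped,
    )


def sample_baseline_intervals(
    psi_by_team: Mapping[str, PsiSeries],
    half_bounds: list[tuple[float, float]],
    shots: list[tuple[float, str]],
    duration_s: int = 60,
    rng_seed=0,
) -> np.ndarray:
    """Randomly placed baseline curves matched in number to the shots.

    For each retained shot one pseudo-anchor is drawn uniformly from the
    anchor times of the same half at which the shooting team's series has
    full valid coverage (the same windowing as the real extraction, so
    baseline curves may overlap shot windows).  Reproducible from
    ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    rel_times = np.arange(-duration_s, 0, dtype=float)
    indexes = {team: _time_index(s) for team, s in psi_by_team.items()}

    anchors_cache: dict[tuple[str, int], np.ndarray] = {}

    def valid_anchors(team: str, half: int) -> np.ndarray:
        key = (team, half)
        if key not in anchors_cache:
            s, e = half_bounds[half]
            if e - s + 1 < duration_s:
                raise EventAnalysisError(f"half [{s}, {e}] shorter than {duration_s} s")
            cand = np.arange(s, e + 2.0)  # anchor may sit one past the last frame
            good = [
                a for a in cand
                if _curve_at(psi_by_team[team], indexes[team], a + rel_times) is not None
            ]
            anchors_cache[key] = np.asarray(good, dtype=float)
        return anchors_cache[key]

    curves = []
    for t_shot, shooter in shots:
        half = next(
            h for h, (s, e) in enumerate(half_bounds) if s - 1e-9 <= t_shot <= e + 1e-9
        )
        anchors = valid_anchors(shooter, half)
        if len(anchors) == 0:
            raise EventAnalysisError(f"no valid baseline anchor in half {half}")
        a = float(rng.choice(anchors))
        curves.append(_curve_at(psi_by_team[shooter], indexes[shooter], a + rel_times))
    return np.asarray(curves) if curves else np.empty((0, duration_s))


def align_shots(
    psi_by_team: Mapping[str, PsiSeries],
    events: EventLog,
    duration_s: int = 60,
    rng_seed=0,
) -> EventAlignedCurves:
    """Convenience: extract attacker/defender curves and matched baselines."""
    curves = extract_pre_event_curves(psi_by_team, events, duration_s)
    curves.baseline = sample_baseline_intervals(
        psi_by_team, events.half_bounds(), curves.shots, duration_s, rng_seed
    )
    return curves


def timepoint_significance(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
) -> np.ndarray:
    """Per-timepoint Welch t-test with Bonferroni correction.

    Returns a boolean mask over relative timepoints; degenerate columns
    (zero variance in both groups) are flagged non-significant.
    """
    group_a, group_b = np.asarray(group_a, float), np.asarray(group_b, float)
    if group_a.shape[0] < 2 or group_b.shape[0] < 2:
        raise EventAnalysisError("need at least 2 curves per group")
    if n_comparisons is None:
        n_comparisons = group_a.shape[1]
    with np.errstate(all="ignore"):
        _, p = stats.ttest_ind(group_a, group_b, axis=0, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    return p < alpha / n_comparisons


def trend_regression(mean_curve: np.ndarray, times: np.ndarray, label: str = "") -> TrendResult:
    """OLS of a mean Psi curve on relative time; slope in Psi per second."""
    mean_curve = np.asarray(mean_curve, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(mean_curve) < 3:
        raise EventAnalysisError("need at least 3 points for a trend")
    if np.ptp(mean_curve) == 0:
        return TrendResult(0.0, float(mean_curve[0]), 0.0, 1.0, label, degenerate=True)
    res = stats.linregress(times, mean_curve)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        label=label,
    )
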