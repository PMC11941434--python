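"""Half-level home-vs-away summaries and the Psi-possession correlation.

Each (match, half) yields one scatter point: the home-minus-away difference
in mean Psi against the home-minus-away difference in possession rate.
Pearson's R over these paired differences quantifies how strongly emergent
team dynamics track ball control.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .emergence import PsiSeries
from .tracking import EventLog, TEAMS

logger = logging.getLogger(__name__)


class MatchLevelError(ValueError):
    pass


def possession_rate(events: EventLog, half_bounds: tuple[float, float], team: str) -> float:
    """Fraction of the half's seconds labelled as this team's possession.

    Errors if more than 1% of the half's seconds carry no label.
    """
    s, e = half_bounds
    labels = events.possession_series(s, e)
    n = len(labels)
    if n == 0:
        raise MatchLevelError(f"no possession labels in half [{s}, {e}]")
    missing = np.sum(labels == "") / n
    if missing > 0.01:
        raise MatchLevelError(
            f"{missing:.1%} of half [{s}, {e}] has no possession label"
        )
    return float(np.sum(labels == team) / n)


def half_mean_psi(psi: PsiSeries, half_bounds: tuple[float, float]) -> float:
    """Mean Psi over valid windows ending inside the half."""
    s, e = half_bounds
    sel = psi.valid & (psi.times >= s - 1e-9) & (psi.times <= e + 1e-9)
    if not sel.any():
        raise MatchLevelError(f"no valid Psi window ends inside half [{s}, {e}]")
    return float(psi.psi[sel].mean())


def half_summaries(
    match_id,
    psi_by_team: Mapping[str, PsiSeries],
    events: EventLog,
) -> pd.DataFrame:
    """Per-(half, team) mean Psi and possession rate for one match."""
    rows = []
    for h, bounds in enumerate(events.half_bounds()):
        for team in TEAMS:
            if team not in psi_by_team:
                continue
            rows.append(
                {
                    "match": match_id,
                    "half": h + 1,
                    "team": team,
                    "mean_psi": half_mean_psi(psi_by_team[team], bounds),
                    "possession_rate": possession_rate(events, bounds, team),
                }
            )
    return pd.DataFrame(rows)


def paired_differences(summaries: pd.DataFrame) -> pd.DataFrame:
    """Home-minus-away (dPsi, dPossession) per (match, half).

    Halves missing either team are skipped with a log message.
    """
    rows = []
    for (match, half), grp in summaries.groupby(["match", "half"]):
        by_team = grp.set_index("team")
        if not {"home", "away"} <= set(by_team.index):
            logger.warning("skipping match %s half %s: missing a team", match, half)
            continue
        rows.append(
            {
                "match": match,
                "half": half,
                "d_psi": by_team.loc["home", "mean_psi"] - by_team.loc["away", "mean_psi"],
                "d_possession": by_team.loc["home", "possession_rate"]
                - by_team.loc["away", "possession_rate"],
            }
        )
    return pd.DataFrame(rows)


def correlate_differences(pairs: pd.DataFrame) -> tuple[float, float]:
    """Pearson R and two-sided p over the (dPsi, dPossession) pairs."""
    if len(pairs) < 3:
        raise MatchLevelError(f"need at least 3 pairs, got {len(pairs)}")
    x = pairs["d_psi"].to_numpy(dtype=float)
    y = pairs["d_possession"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MatchLevelError("zero variance in the paired differences")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
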