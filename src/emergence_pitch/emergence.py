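"""Gaussian mutual information and the practical causal-emergence statistic.

The practical criterion compares the predictive information carried by a
macroscopic feature V about its own next value with the summed predictive
information of the individual micro variables:

    Psi = I(V_t ; V_t') - sum_i I(X_t^i ; V_t'),        t' = t + lag.

Positive Psi indicates synergy (the macro predicts its future beyond what
individual players explain); negative Psi indicates redundancy (players
duplicate the macro's information).  Mutual information is estimated under
a joint-Gaussian assumption from maximum-likelihood (1/n) covariances:

    I(X; Y) = 1/2 * ln( det S_XX det S_YY / det S_[X,Y] ),

in nats by default.  A small ridge is added to the joint covariance
diagonal before taking determinants to guard near-singular windows, and
negative estimates (possible after ridging) are clamped to zero before the
Psi subtraction.  Psi is evaluated over sliding windows anchored at their
end time, so event-locked curves read "Psi of the window ending at t".
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .features import MacroMicroSeries

_LN2 = float(np.log(2.0))

#: window flag values, in order of precedence
FLAG_OK = ""
FLAG_MASKED = "masked"
FLAG_DEGENERATE = "degenerate"
FLAG_SINGULAR = "singular"


class EmergenceError(ValueError):
    pass


@dataclasses.dataclass
class EmergenceConfig:
    """Sliding-window and estimator settings.

    window_s, step_s, lag_s in seconds (1 Hz series); ``mi_units`` is
    ``nats`` or ``bits``; ``ridge`` is added to the joint covariance
    diagonal; ``order_l`` is fixed at 1 (individual micro variables only).
    """

    window_s: int = 60
    step_s: int = 1
    lag_s: int = 1
    mi_units: str = "nats"
    ridge: float = 1e-10
    order_l: int = 1

    def __post_init__(self) -> None:
        if not self.window_s > self.lag_s >= 1:
            raise EmergenceError("need window_s > lag_s >= 1")
        if self.step_s < 1:
            raise EmergenceError("step_s must be >= 1")
        if self.ridge < 0:
            raise EmergenceError("ridge must be >= 0")
        if self.mi_units not in ("nats", "bits"):
            raise EmergenceError("mi_units must be 'nats' or 'bits'")
        if self.order_l != 1:
            raise EmergenceError("only order_l = 1 is supported")

    @property
    def n_pairs(self) -> int:
        """Lagged sample pairs contributing to each window."""
        return self.window_s - self.lag_s


@dataclasses.dataclass
class PsiSeries:
    """Per-window Psi decomposition for one team and one macro feature.

    ``times`` are window END times.  ``psi = macro_mi - micro_mi_sum`` holds
    exactly by construction on unflagged windows; flagged windows carry NaN.
    """

    times: np.ndarray
    psi: np.ndarray
    macro_mi: np.ndarray
    micro_mi_sum: np.ndarray
    flags: np.ndarray
    feature_name: str
    team: str
    n_pairs: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.macro_mi = np.asarray(self.macro_mi, dtype=float)
        self.micro_mi_sum = np.asarray(self.micro_mi_sum, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)

    @property
    def valid(self) -> np.ndarray:
        return (self.flags == FLAG_OK) & np.isfinite(self.psi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_end": self.times,
                "team": self.team,
                "feature": self.feature_name,
                "psi": self.psi,
                "macro_mi": self.macro_mi,
                "micro_mi_sum": self.micro_mi_sum,
                "flags": self.flags,
            }
        )


def concat_psi(series: list[PsiSeries]) -> PsiSeries:
    """Concatenate per-half PsiSeries of one team/feature along time."""
    if not series:
        raise EmergenceError("nothing to concatenate")
    first = series[0]
    return PsiSeries(
        times=np.concatenate([s.times for s in series]),
        psi=np.concatenate([s.psi for s in series]),
        macro_mi=np.concatenate([s.macro_mi for s in series]),
        micro_mi_sum=np.concatenate([s.micro_mi_sum for s in series]),
        flags=np.concatenate([s.flags for s in series]),
        feature_name=first.feature_name,
        team=first.team,
        n_pairs=first.n_pairs,
    )


# ---------------------------------------------------------------------------
# Gaussian mutual information
# ---------------------------------------------------------------------------


def _as_2d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def gaussian_mutual_information(
    X: np.ndarray,
    Y: np.ndarray,
    config: EmergenceConfig | None = None,
    *,
    ridge: float | None = None,
    units: str | None = None,
) -> float:
    """Gaussian MI between samples X (n, p) and Y (n, q).

    Covariances are maximum-likelihood (1/n).  If the unridged joint
    covariance is (numerically) singular — e.g. Y duplicates X — the
    sentinel ``inf`` is returned.  Otherwise the estimate is clamped at 0.
    """
    cfg = config or EmergenceConfig()
    ridge = cfg.ridge if ridge is None else ridge
    units = cfg.mi_units if units is None else units
    X, Y = _as_2d(X), _as_2d(Y)
    n, p = X.shape
    q = Y.shape[1]
    if Y.shape[0] != n:
        raise EmergenceError(f"sample-count mismatch: {n} vs {Y.shape[0]}")
    if n < p + q + 2:
        raise EmergenceError(f"need n >= p + q + 2 samples (n={n}, p={p}, q={q})")
    Z = np.hstack([X, Y])
    if not np.all(np.isfinite(Z)):
        raise EmergenceError("non-finite data")
    C = np.cov(Z.T, bias=True).reshape(p + q, p + q)

    eig = np.linalg.eigvalsh(C)
    if eig[-1] <= 0 or eig[0] <= 1e-13 * eig[-1]:
        return float("inf")

    Cr = C + ridge * np.eye(p + q)
    _, ld_j = np.linalg.slogdet(Cr)
    _, ld_x = np.linalg.slogdet(Cr[:p, :p])
    _, ld_y = np.linalg.slogdet(Cr[p:, p:])
    mi = max(0.0, 0.5 * (ld_x + ld_y - ld_j))
    return mi / _LN2 if units == "bits" else mi


def psi_statistic(
    macro_t: np.ndarray,
    macro_tp: np.ndarray,
    micro_t: np.ndarray,
    config: EmergenceConfig | None = None,
) -> tuple[float, float, float]:
    """Psi from explicit lagged sample pairs.

    ``macro_t``/``macro_tp`` are (n, p) samples of V at t and t'; ``micro_t``
    is (n, N, q) (or a list of (n, q_i) arrays) of per-player samples at t.
    Returns ``(psi, macro_mi, micro_mi_sum)``; negative psi is permitted.
    """
    cfg = config or EmergenceConfig()
    macro_t, macro_tp = _as_2d(macro_t), _as_2d(macro_tp)
    n = macro_t.shape[0]
    if macro_tp.shape[0] != n:
        raise EmergenceError("macro_t and macro_tp sample counts differ")
    if isinstance(micro_t, np.ndarray) and micro_t.ndim == 3:
        micros = [micro_t[:, i, :] for i in range(micro_t.shape[1])]
    else:
        micros = [_as_2d(m) for m in micro_t]
    for m in micros:
        if m.shape[0] != n:
            raise EmergenceError("micro sample count differs from macro")
    macro_mi = gaussian_mutual_information(macro_t, macro_tp, cfg)
    micro_mi_sum = float(sum(gaussian_mutual_information(m, macro_tp, cfg) for m in micros))
    return macro_mi - micro_mi_sum, macro_mi, micro_mi_sum


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------


def _window_covs(rows: np.ndarray, starts: np.ndarray, m: int) -> np.ndarray:
    """ML covariances of ``m`` consecutive rows at each start, via prefix sums.

    ``rows`` is (n_rows, d); returns (n_windows, d, d).
    """
    n, d = rows.shape
    s1 = np.zeros((n + 1, d))
    np.cumsum(rows, axis=0, out=s1[1:])
    outer = rows[:, :, None] * rows[:, None, :]
    s2 = np.zeros((n + 1, d, d))
    np.cumsum(outer, axis=0, out=s2[1:])
    sum1 = s1[starts + m] - s1[starts]
    sum2 = s2[starts + m] - s2[starts]
    mean = sum1 / m
    return sum2 / m - mean[:, :, None] * mean[:, None, :]


def _batched_mi(covs: np.ndarray, p: int, ridge: float, units: str) -> tuple[np.ndarray, np.ndarray]:
    """MI for a batch of joint covariances (W, p+q, p+q); X block is the first p dims.

    Returns (mi, singular_mask).  Singular joints (unridged smallest
    eigenvalue <= 1e-13 of the largest) yield inf and are flagged.
    """
    d = covs.shape[-1]
    eig = np.linalg.eigvalsh(covs)
    singular = (eig[:, -1] <= 0) | (eig[:, 0] <= 1e-13 * eig[:, -1])
    Cr = covs + ridge * np.eye(d)
    _, ld_j = np.linalg.slogdet(Cr)
    _, ld_x = np.linalg.slogdet(Cr[:, :p, :p])
    _, ld_y = np.linalg.slogdet(Cr[:, p:, p:])
    mi = np.clip(0.5 * (ld_x + ld_y - ld_j), 0.0, None)
    mi[singular] = np.inf
    if units == "bits":
        mi = mi / _LN2
    return mi, singular


def sliding_window_psi(series: MacroMicroSeries, config: EmergenceConfig | None = None) -> PsiSeries:
    """Psi over sliding windows of a macro/micro series.

    For each window end e (stepping by ``step_s``) the lagged pairs are
    ``(t, t + lag)`` for t in ``[e - window + 1, e - lag]`` — all inside the
    window, ``window_s - lag_s`` pairs.  Windows containing masked frames
    are flagged ``masked``; windows whose macro has (numerically) zero
    variance are flagged ``degenerate``; windows with singular joint
    covariances are flagged ``singular``.  Flagged windows carry NaN psi.
    """
    cfg = config or EmergenceConfig()
    T = len(series.times)
    w, lag, step = cfg.window_s, cfg.lag_s, cfg.step_s
    m = cfg.n_pairs
    if T < w:
        raise EmergenceError(f"series length {T} shorter than window {w}")
    if T > 1 and not np.allclose(np.diff(series.times), series.times[1] - series.times[0]):
        raise EmergenceError("series must be uniformly sampled")

    macro = _as_2d(series.macro)
    p = macro.shape[1]
    micro = series.micro
    if micro.ndim == 2:
        micro = micro[:, :, None]
    N, q = micro.shape[1], micro.shape[2]

    ends = np.arange(w - 1, T, step)
    starts = ends - (w - 1)  # first pair row of each window
    n_win = len(ends)

    # lagged pair rows: row t holds (value at t, macro at t+lag)
    macro_rows = np.hstack([macro[:-lag], macro[lag:]])

    flags = np.full(n_win, FLAG_OK, dtype=object)

    invalid = (~series.valid).astype(int)
    bad_prefix = np.concatenate([[0], np.cumsum(invalid)])
    n_bad = bad_prefix[ends + 1] - bad_prefix[starts]  # frames e-w+1 .. e
    flags[n_bad > 0] = FLAG_MASKED

    macro_covs = _window_covs(macro_rows, starts, m)
    macro_var = np.diagonal(macro_covs, axis1=1, axis2=2)[:, :p]
    degenerate = macro_var.max(axis=1) < 1e-12
    flags[(flags == FLAG_OK) & degenerate] = FLAG_DEGENERATE

    macro_mi, singular = _batched_mi(macro_covs, p, cfg.ridge, cfg.mi_units)
    micro_mi_sum = np.zeros(n_win)
    for i in range(N):
        rows_i = np.hstack([micro[:-lag, i, :], macro[lag:]])
        mi_i, sing_i = _batched_mi(_window_covs(rows_i, starts, m), q, cfg.ridge, cfg.mi_units)
        micro_mi_sum += mi_i
        singular |= sing_i
    flags[(flags == FLAG_OK) & singular] = FLAG_SINGULAR

    with np.errstate(invalid="ignore"):  # inf - inf on flagged windows
        psi = macro_mi - micro_mi_sum
    ok = flags == FLAG_OK
    psi[~ok] = np.nan
    macro_mi = np.where(ok, macro_mi, np.nan)
    micro_mi_sum = np.where(ok, micro_mi_sum, np.nan)

    return PsiSeries(
        times=series.times[ends],
        psi=psi,
        macro_mi=macro_mi,
        micro_mi_sum=micro_mi_sum,
        flags=flags,
        feature_name=series.feature_name,
        team=series.team,
        n_pairs=m,
    )
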