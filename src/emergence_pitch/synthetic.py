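"""Synthetic football-match generator.

The generator emulates the statistical structure the emergence analysis
assumes: two teams of ten outfield players sampled at 1 Hz over two
2700 s halves on a 105 x 68 m pitch, a per-second possession label driven
by a two-state Markov chain, and shot events drawn from a per-second hazard.

Team movement follows a latent-centre model.  The team centre V_t is a 2-D
AR(1) process around an attractor that tracks possession (pushed toward the
opponent goal while in possession, pulled back toward the own half while
defending), with possession-state-dependent persistence phi.  Player i sits
at ``V_t + F_i + D_{i,t}``: a fixed formation offset plus an AR(1)
idiosyncratic deviation.  Offsets and deviations are centred across the ten
players at every frame, so the empirical centre of mass equals V_t exactly
and the closed-form Psi limits of :func:`theoretical_psi_limit` apply.

The idiosyncratic scale sigma_idio is the redundancy/synergy dial: small
sigma_idio makes every player a near-copy of the centre (micro variables
duplicate the macro; Psi < 0), large sigma_idio makes individual players
uninformative about the future centre (Psi > 0, up to the macro's own
predictive information).  Pre-shot "ramps" scale sigma_idio multiplicatively
over the 60 s before each shot: up for the shooting team, down for the
opponent, by default.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .tracking import EventLog, MatchTracking, TEAMS


class SyntheticParamsError(ValueError):
    """Generator parameters violate an invariant."""


def default_formation(n_players: int = 10, pitch_length: float = 105.0, pitch_width: float = 68.0) -> np.ndarray:
    """A centred 4-4-2 formation offset grid, scaled to the pitch.

    Rows are (x, y) offsets in metres from the team centre, x toward the
    opponent goal.  Offsets are centred so they sum to zero.
    """
    if n_players == 10:
        xs = [-0.29, -0.29, -0.29, -0.29, -0.10, -0.10, -0.10, -0.10, 0.10, 0.10]
        ys = [-0.33, -0.11, 0.11, 0.33, -0.33, -0.11, 0.11, 0.33, -0.15, 0.15]
    else:  # generic two-line layout for non-standard squad sizes
        half = (n_players + 1) // 2
        xs = [-0.2] * half + [0.05] * (n_players - half)
        ys = list(np.linspace(-0.33, 0.33, half)) + list(
            np.linspace(-0.33, 0.33, n_players - half)
        )
    offsets = np.column_stack([np.array(xs) * pitch_length, np.array(ys) * pitch_width])
    return offsets - offsets.mean(axis=0)


@dataclasses.dataclass
class SyntheticParams:
    """Tunable parameters of the synthetic match generator.

    Defaults describe the study conditions: ~33 s mean possession spells,
    roughly 13 shots per match per team-pair, moderate idiosyncratic motion
    (sigma_idio = 8 m) so that the possession-persistent regime is
    synergy-leaning, and pre-shot ramps that raise the shooter's player
    noise while damping the defender's.
    """

    n_players: int = 10
    pitch_length: float = 105.0
    pitch_width: float = 68.0
    half_length_s: int = 2700
    halftime_gap_s: int = 900
    #: AR(1) persistence of the latent centre while in / out of possession
    phi_possess: float = 0.9
    phi_defend: float = 0.7
    #: innovation SD of the latent centre (m per second step)
    sigma_macro: float = 1.0
    #: AR(1) persistence and innovation SD (m) of per-player deviations
    rho_idio: float = 0.5
    sigma_idio: float = 8.0
    formation_offsets: np.ndarray | None = None
    #: per-second probability the current holder keeps possession
    p_stay_home: float = 0.97
    p_stay_away: float = 0.97
    #: per-second shot probability for the possessing team
    shot_hazard: float = 0.005
    #: shots closer together than this are thinned so ramps do not stack
    min_shot_gap_s: int = 90
    #: per-second multiplicative sigma_idio scaling during the pre-shot ramp
    gamma_attack: float = 1.02
    gamma_defend: float = 0.98
    ramp_duration_s: int = 60
    #: per-second pull of the centre attractor toward its possession target
    attractor_gain: float = 0.02
    #: attractor x-positions (m from centre, + toward the opponent goal)
    attack_x: float = 20.0
    defend_x: float = -15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.formation_offsets is None:
            self.formation_offsets = default_formation(
                self.n_players, self.pitch_length, self.pitch_width
            )
        self.formation_offsets = np.asarray(self.formation_offsets, dtype=float)

    def validate(self) -> "SyntheticParams":
        for name in ("phi_possess", "phi_defend", "rho_idio"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise SyntheticParamsError(f"{name}={v} outside [0, 1)")
        for name in ("sigma_macro", "sigma_idio", "shot_hazard"):
            if getattr(self, name) < 0:
                raise SyntheticParamsError(f"{name} must be >= 0")
        for name in ("p_stay_home", "p_stay_away"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise SyntheticParamsError(f"{name}={v} outside (0, 1]")
        if self.formation_offsets.shape != (self.n_players, 2):
            raise SyntheticParamsError("formation_offsets must have shape (n_players, 2)")
        if self.half_length_s < 2:
            raise SyntheticParamsError("half_length_s must be >= 2")
        return self


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def simulate_possession(
    rng: np.random.Generator,
    length: int,
    p_stay_home: float,
    p_stay_away: float,
    start_team: str = "home",
) -> np.ndarray:
    """Two-state Markov possession labels ('home'/'away') of given length."""
    labels = np.empty(length, dtype=object)
    cur = start_team
    u = rng.random(length)
    for t in range(length):
        labels[t] = cur
        stay = p_stay_home if cur == "home" else p_stay_away
        if u[t] >= stay:
            cur = "away" if cur == "home" else "home"
    return labels


def draw_shots(
    rng: np.random.Generator,
    labels: np.ndarray,
    hazard: float,
    min_gap_s: int,
) -> list[tuple[int, str]]:
    """Shot times (half-relative seconds) drawn by per-second hazard, thinned."""
    hits = np.where(rng.random(len(labels)) < hazard)[0]
    shots: list[tuple[int, str]] = []
    last = -np.inf
    for t in hits:
        if t - last >= min_gap_s:
            shots.append((int(t), str(labels[t])))
            last = t
    return shots


def ramp_profile(
    length: int,
    shots: list[tuple[int, str]],
    team: str,
    gamma_attack: float,
    gamma_defend: float,
    ramp_duration_s: int,
) -> np.ndarray:
    """Per-second sigma_idio multiplier for one team given this half's shots.

    During the ``ramp_duration_s`` seconds before a shot the multiplier grows
    geometrically, reaching gamma**ramp_duration_s at the frame before the
    shot: gamma_attack for the shooting team, gamma_defend for the opponent.
    Overlapping ramps (rare after thinning) combine multiplicatively.
    """
    scale = np.ones(length)
    for t_shot, shooter in shots:
        gamma = gamma_attack if shooter == team else gamma_defend
        k0 = max(0, t_shot - ramp_duration_s)
        steps = np.arange(k0 + 1 - (t_shot - ramp_duration_s), ramp_duration_s + 1)
        scale[k0:t_shot] *= gamma ** steps[: t_shot - k0].astype(float)
    return scale


def generate_team_trajectory(
    params: SyntheticParams,
    in_possession: np.ndarray,
    sigma_scale: np.ndarray | None,
    attack_sign: int,
    seed,
) -> np.ndarray:
    """Player positions (length, n_players, 2) for one team over one half.

    ``in_possession`` is a boolean per-second array for this team;
    ``sigma_scale`` an optional per-second multiplier on sigma_idio (the
    pre-shot ramps); ``attack_sign`` is +1 when the team attacks toward +x.
    ``seed`` may be an int, SeedSequence or Generator.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    L = len(in_possession)
    in_possession = np.asarray(in_possession, dtype=bool)
    if sigma_scale is None:
        sigma_scale = np.ones(L)
    sigma_scale = np.asarray(sigma_scale, dtype=float)

    targets = np.where(
        in_possession[:, None],
        np.array([params.attack_x, 0.0]) * attack_sign,
        np.array([params.defend_x, 0.0]) * attack_sign,
    )
    eta = rng.standard_normal((L, 2)) * params.sigma_macro
    c = np.empty((L, 2))
    V = np.empty((L, 2))
    c[0] = targets[0]
    V[0] = c[0] + eta[0]
    g = params.attractor_gain
    for t in range(1, L):
        c[t] = c[t - 1] + g * (targets[t] - c[t - 1])
        phi = params.phi_possess if in_possession[t - 1] else params.phi_defend
        V[t] = c[t] + phi * (V[t - 1] - c[t - 1]) + eta[t]

    # idiosyncratic AR(1) deviations with time-varying innovation scale,
    # centred across players so the empirical CoM equals V exactly
    eps = rng.standard_normal((L, params.n_players, 2))
    eps *= (params.sigma_idio * sigma_scale)[:, None, None]
    D = lfilter([1.0], [1.0, -params.rho_idio], eps, axis=0)
    D -= D.mean(axis=1, keepdims=True)

    F = params.formation_offsets * np.array([attack_sign, 1.0])
    F = F - F.mean(axis=0)
    return V[:, None, :] + F[None, :, :] + D


# ---------------------------------------------------------------------------
# full match
# ---------------------------------------------------------------------------


def generate_match(params: SyntheticParams, seed=None) -> tuple[MatchTracking, EventLog]:
    """Generate one synthetic match: two halves of tracking data plus events.

    Home attacks toward +x in the first half; directions swap at half time.
    Home kicks off the first half, away the second.  Fully reproducible from
    ``seed`` (falls back to ``params.seed``).
    """
    params.validate()
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(8)

    L = params.half_length_s
    all_times: list[np.ndarray] = []
    pos = {team: [] for team in TEAMS}
    event_rows: list[dict] = []
    poss_times: list[np.ndarray] = []
    poss_team: list[np.ndarray] = []
    half_bounds: list[tuple[float, float]] = []

    for h in range(2):
        t0 = h * (L + params.halftime_gap_s)
        start_team = "home" if h == 0 else "away"
        attack_sign = {"home": 1 - 2 * h, "away": 2 * h - 1}
        rng_poss = np.random.default_rng(children[4 * h])
        labels = simulate_possession(rng_poss, L, params.p_stay_home, params.p_stay_away, start_team)
        rng_shot = np.random.default_rng(children[4 * h + 1])
        shots = draw_shots(rng_shot, labels, params.shot_hazard, params.min_shot_gap_s)

        for j, team in enumerate(TEAMS):
            scale = ramp_profile(
                L, shots, team, params.gamma_attack, params.gamma_defend, params.ramp_duration_s
            )
            traj = generate_team_trajectory(
                params,
                in_possession=(labels == team),
                sigma_scale=scale,
                attack_sign=attack_sign[team],
                seed=children[4 * h + 2 + j],
            )
            pos[team].append(traj)

        times = np.arange(t0, t0 + L, dtype=float)
        all_times.append(times)
        half_bounds.append((float(t0), float(t0 + L - 1)))
        poss_times.append(times)
        poss_team.append(labels)

        event_rows.append({"t": float(t0), "team": "", "event_type": "half_start"})
        event_rows.append({"t": float(t0), "team": start_team, "event_type": "possession_gain"})
        prev = labels[0]
        for k in range(1, L):
            if labels[k] != prev:
                event_rows.append(
                    {"t": float(t0 + k), "team": str(labels[k]), "event_type": "possession_gain"}
                )
                prev = labels[k]
        for t_shot, shooter in shots:
            event_rows.append({"t": float(t0 + t_shot), "team": shooter, "event_type": "shot"})
        event_rows.append({"t": float(t0 + L - 1), "team": "", "event_type": "half_end"})

    positions = {team: np.concatenate(pos[team], axis=0) for team in TEAMS}
    excess = max(
        float(np.abs(p[..., 0]).max()) - params.pitch_length / 2 for p in positions.values()
    )
    excess_y = max(
        float(np.abs(p[..., 1]).max()) - params.pitch_width / 2 for p in positions.values()
    )
    margin = max(5.0, excess + 1.0, excess_y + 1.0)

    tracking = MatchTracking(
        times=np.concatenate(all_times),
        positions=positions,
        pitch_length=params.pitch_length,
        pitch_width=params.pitch_width,
        sample_rate_hz=1.0,
        half_bounds=half_bounds,
        margin=margin,
    ).validate()

    ev = pd.DataFrame(event_rows).sort_values("t", kind="stable").reset_index(drop=True)
    events = EventLog(
        events=ev,
        possession_times=np.concatenate(poss_times),
        possession_team=np.concatenate(poss_team),
    ).validate()
    return tracking, events


def season_params(
    base: SyntheticParams,
    n_matches: int,
    seed,
    possession_spread: float = 0.01,
) -> list[SyntheticParams]:
    """Per-match parameter sets with a random home/away possession asymmetry.

    Each match draws delta ~ U(-spread, +spread) and sets
    ``p_stay_home = p + delta``, ``p_stay_away = p - delta`` around the base
    retention probability, producing realistic match-to-match variation in
    possession share (roughly 33-67% at the defaults).
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_matches):
        delta = rng.uniform(-possession_spread, possession_spread)
        p = dataclasses.replace(
            base,
            p_stay_home=min(1.0, base.p_stay_home + delta),
            p_stay_away=min(1.0, base.p_stay_away - delta),
        )
        out.append(p)
    return out


def theoretical_psi_limit(phi, n_players: int = 10, regime: str = "synergy") -> float:
    """Closed-form Psi limit for the CoM macro of the latent-centre model.

    For a 2-D isotropic AR(1) centre with persistence phi, the lag-1 mutual
    information of the macro is ``-ln(1 - phi**2)`` nats.  As sigma_idio
    grows without bound every player becomes uninformative about the future
    centre and Psi tends to that macro information ('synergy' regime); as
    sigma_idio -> 0 every player is an affine copy of the centre, each
    contributing the full macro information, and Psi tends to
    ``(1 - N) * (-ln(1 - phi**2))`` ('redundancy' regime).

    ``phi`` may be a float or a :class:`SyntheticParams` (uses phi_possess).
    """
    if isinstance(phi, SyntheticParams):
        phi = phi.phi_possess
    phi = float(phi)
    if not 0.0 <= phi < 1.0:
        raise SyntheticParamsError(f"phi={phi} outside [0, 1)")
    macro_mi = -np.log(1.0 - phi**2)
    if regime == "synergy":
        return float(macro_mi)
    if regime == "redundancy":
        return float((1 - n_players) * macro_mi)
    raise ValueError(f"unknown regime {regime!r} (use 'synergy' or 'redundancy')")
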