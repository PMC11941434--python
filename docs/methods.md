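# Methods

## The statistic

For a team of N = 10 outfield players with micro states `X_t^i` and a
supervenient macro feature `V_t` (a deterministic function of the frame's
micro states), the practical causal-emergence criterion at order 1 is

```
Ψ_{t,t'}(V) = I(V_t ; V_{t'}) − Σ_{i=1..N} I(X_t^i ; V_{t'}),   t' = t + lag.
```

Only individual players enter the micro sum; subsets of two or more players
(higher decomposition orders) are out of scope. Ψ > 0 indicates synergistic
macro-level predictive power; Ψ < 0 indicates that the players' individual
information about the macro future is redundant with (and in sum exceeds)
the macro's own. Both signs are meaningful and reported.

### Mutual information estimator

`I(X; Y)` is estimated under a joint-Gaussian assumption:

```
I = ½ · ln( det Σ_XX · det Σ_YY / det Σ_[X,Y] )
```

with maximum-likelihood (1/n) covariances. Numerical choices:

- **ridge** (default 1e−10) is added to the joint covariance diagonal
  before determinants; the marginal blocks are taken from the ridged joint.
  This guards near-singular windows — at the default window a 60 s window
  supplies only n = 59 lagged pairs against up to 4 joint dimensions.
- If the *unridged* joint covariance is numerically singular (smallest
  eigenvalue ≤ 1e−13 of the largest, e.g. Y duplicates X), the estimator
  returns the sentinel `inf` rather than a ridge-dependent large number.
- Negative estimates (possible after ridging) are clamped to 0 before the
  Ψ subtraction.
- Units are nats by default; bits are available via configuration. Nothing
  downstream depends on the choice, which is why it is exposed rather than
  asserted.
- No small-sample bias correction is applied. At n = 59 the estimator has
  an upward bias of roughly p·q/(2n) nats per term; because the micro sum
  contains ten terms and the macro one, Ψ carries a small negative offset
  that is common to all windows and cancels in the home-away differences
  and trend slopes the analyses consume.

### Sliding windows

Windows are anchored at their **end** time: the window ending at `e` uses
lagged pairs `(t, t+lag)` for `t ∈ [e−window+1, e−lag]`, i.e.
`window − lag` pairs, all inside the window, so event-locked curves read
"Ψ of the 60 s up to t". Defaults: window 60 s, step 1 s, lag 1 s — the
minimal faithful lag at 1 Hz; all three are configurable. Windows never
cross a half boundary (series are computed per half). Windows containing
frames with placeholder velocities are flagged `masked`, zero-variance
macros `degenerate`, singular joints `singular`; flagged windows carry NaN
and are excluded from all downstream averages.

## Macro features

| name | macro | micro (per player) |
|---|---|---|
| `com` | mean player position (2-D) | position (x, y) |
| `relative_distance` | CoM-to-centre distance (default) or mean player-to-centre distance | distance to pitch centre |
| `clust_vel` | team-average weighted clustering, velocity-similarity graph | velocity (vx, vy) |
| `clust_dist` | team-average weighted clustering, inverse-distance graph | position (x, y) |

Coordinates are pitch-centred (origin at the centre spot, x along the long
axis of a 105 × 68 m pitch), so "distance to the field's centre" is a plain
Euclidean norm. Velocities are first differences of the 1 Hz positions and
are never taken across the half-time gap; the first frame of each half
carries a placeholder velocity and is masked.

The two `relative_distance` variants exist because either aggregation — the
CoM's distance to the centre, or the mean of the players' distances — is a
defensible scalar summary of the same micro variables; the CoM variant is
the default and the other is one flag away. The mean-distance variant
always dominates the CoM variant (triangle inequality), which the test
suite checks.

Player graphs are **complete** weighted graphs on the ten players
(adjacency 1 for every ordered pair j ≠ k; thresholding is available but
off by default, since no threshold is part of the method). Edge weights:

- velocity similarity: `w_uv = S_u · S_v · (cos Δθ + 1)` with speeds `S`
  and movement-angle difference Δθ — zero for anti-parallel motion or a
  stationary player, maximal (`2 S_u S_v`) for co-directed motion;
- inverse distance: `w_uv = 1 / max(‖p_u − p_v‖, ε)` with ε = 0.1 m
  guarding coincident positions.

The node clustering coefficient sums half-sums of incident weights over
ordered neighbour pairs,
`C_i = (k_i (k_i − 1))^{-1} Σ_{j,k≠i, j≠k} ((w_ij + w_ik)/2) a_jk`,
and the team value is the mean over players. Weights are **not**
max-normalised. The implementation uses the algebraically identical
vectorised form `C_i = Σ_j w_ij (deg_j − a_ji) / (k_i(k_i−1))`; the test
suite checks it against a literal triple-loop oracle to 1e−12 on random
graphs up to N = 12. (On a complete graph this reduces to the mean
incident weight — a useful closed form: uniform-weight graphs return the
weight itself.)

## Synthetic match generator

The generator emulates the *statistical structure* the analysis assumes,
not football physics: two teams × 10 players at 1 Hz, two 2700 s halves, a
per-second possession label, and shot events.

**Team motion.** Each team has a latent centre `V_t` following a 2-D AR(1)
process around an attractor `c_t` that relaxes (gain 0.02 /s) toward an
attacking target (+20 m along the attack direction) while in possession
and a defensive target (−15 m) otherwise:

```
V_{t+1} = c_{t+1} + φ·(V_t − c_t) + η_t,    η_t ~ N(0, σ_macro² I₂),
```

with possession-dependent persistence φ (`phi_possess` while holding the
ball, `phi_defend` otherwise). Player i sits at `V_t + F_i + D_{i,t}`:
fixed formation offsets `F` (a 4-4-2 grid scaled to the pitch) plus AR(1)
idiosyncratic deviations `D` (persistence `rho_idio`, innovation SD
`sigma_idio`).

**Centring.** Offsets and deviations are centred across the ten players at
every frame, so the empirical CoM equals `V_t` exactly. This is a
modelling choice with a purpose: it makes the generator's Ψ limits exact
closed forms. For a 2-D isotropic AR(1) centre the lag-1 macro information
is `−ln(1−φ²)` nats; as `sigma_idio → ∞` every player becomes
uninformative about the future centre and windowed Ψ(com) tends to that
value (synergy limit), while as `sigma_idio → 0` every player is an affine
copy of the centre and Ψ tends to `(1−N)·(−ln(1−φ²))` (redundancy limit).
Both are exposed via `theoretical_psi_limit` and verified by simulation in
the tests. Without centring, the averaged player noise (variance
σ²_idio/N) would contaminate the CoM and neither limit would be clean.

**Defaults** (the study conditions; chosen once, with the rationale here):

| parameter | default | why |
|---|---|---|
| `half_length_s` | 2700 | a regulation 45 min half at 1 Hz |
| `phi_possess` / `phi_defend` | 0.9 / 0.7 | the possessing team's centre moves more persistently (build-up play) than the reacting defence; the contrast is the mechanism coupling Ψ to possession |
| `sigma_macro` | 1.0 m | centre innovation per second; keeps the stationary centre SD (~2–3 m around the drifting attractor) small enough that higher φ raises Ψ rather than flooding the micro channels with shared signal |
| `rho_idio` / `sigma_idio` | 0.5 / 8 m | moderately persistent individual runs of realistic amplitude; places the default regime mildly synergy-leaning, with both signs of Ψ reachable |
| `p_stay_home/away` | 0.97 | ~33 s mean possession spells. Spells much shorter than the 60 s Ψ window average the two φ states inside every window and erase the possession signal; 0.97 keeps windows predominantly single-state while remaining in the range of real possession sequences |
| `shot_hazard` | 0.005 /s | ~13 shots per team per match, a realistic volume |
| `min_shot_gap_s` | 90 | shots are thinned so pre-shot ramps never stack |
| `gamma_attack` / `gamma_defend` | 1.02 / 0.98 | per-second multiplicative ramp of `sigma_idio` over the 60 s before a shot: the shooter's player noise grows ×3.3 (individuals decouple from the centre → Ψ rises), the defender's shrinks ×0.3 (players lock into formation → Ψ falls). These are knobs reproducing the qualitative attack/defence sign pattern, not claims about real football |
| `possession_spread` | 0.01 | per-match home/away asymmetry of `p_stay`, giving realistic 33–67% possession shares across a season |

**What the generator does *not* emulate** — and hence what passing tests do
not show about real data: no ball, no opponent-aware tactics, no pass/foul
microstructure, no measurement noise, and Gaussian (occasionally off-pitch)
player excursions, especially during attack ramps where `sigma_idio`
triples. Players can therefore stray far outside the pitch; the tracking
validator's off-pitch margin is configurable (default 5 m for real-data
hygiene; the generator records the margin its own output needs, and the
CLI reads synthetic files with a permissive margin). Conclusions from the
synthetic pipeline are about the *method* — its estimators, window
accounting, sign conventions and statistics — not about football.

## Downstream analyses

**Event-locked.** For each shot the 60 window-ends `shot−60 … shot−1`
must exist unflagged in both teams' series, else the shot is dropped with a
logged reason; attacker/defender labels follow the shooting team and
persist through possession changes inside the window. Baseline curves are
drawn per retained shot from the same half and the shooting team's series,
uniformly over anchors with full valid coverage; overlap with shot windows
is permitted (they are random intervals, nothing more). Per-timepoint
comparisons use Welch's t-test (unequal variances — the attacker and
defender ensembles have no reason to share a variance) at Bonferroni-
corrected α/60. Trends are OLS fits to the **across-event mean** curve;
fitting pooled raw points instead is possible but mean-curve fits are what
the R² values of event-locked analyses of this kind refer to, and both the
slope and its two-sided p are reported.

**Match level.** Possession rate is the fraction of a half's seconds
labelled for the team (an error if >1% of seconds are unlabelled); mean Ψ
is taken over valid windows ending inside the half. Each (match, half)
contributes one (ΔΨ, Δpossession) home-minus-away pair; Pearson's R with a
two-sided p is computed over all pairs, and `n_pairs` is always reported.
Swapping the home/away labels negates both differences and leaves R
unchanged, which the tests verify.

## Reproducibility

Every stochastic stage takes an explicit seed. The pipeline fans a single
global seed out to per-stage seeds by stable hashing of stage names
(blake2s, reduced below 2³¹), so stages are independently reproducible and
identical configs produce byte-identical outputs (tracking CSVs are
written with shortest round-trip float representation and read back with
round-trip parsing, making save/load lossless).

## Problem sizes

The validation suite uses windows of 600–2000 s on trajectories of
1300–4200 s for the Ψ-limit checks (Monte-Carlo tolerance ±0.15 nats at
window 2000), 200 pooled synthetic shots for the event-locked sign
recovery, 20 ramp-free seeds for the significance null, and a 30-match
season (60 half-level pairs) for the match-level correlation. These sizes
give comfortable statistical margins for every property checked while a
full run of suite plus acceptance script stays around two minutes.

## Known limitations

- Order-1 micro sums only; player-subset synergies are invisible.
- The Gaussian estimator is blind to non-linear dependence; on strongly
  non-Gaussian macros (e.g. `relative_distance` near the origin) it
  measures linear-Gaussian structure only.
- The finite-window bias of the micro sum (~10·pq/(2n) nats) shifts Ψ
  downward uniformly; absolute Ψ values should be compared only across
  equal window configurations.
- Substitutions are modelled as identity changes on fixed slots; red-card
  periods are excluded rather than modelled.
- The generator's possession chain is memoryless and independent of field
  position, and shots are exogenous hazard draws rather than consequences
  of play.
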