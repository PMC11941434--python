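# emergence-pitch

Causal-emergence analysis of football tracking data: does a team's
macroscopic configuration predict its own future better than the sum of its
players does?

Given per-second positions of the ten outfield players of each team, the
package builds macroscopic team features — the centre of mass (CoM), the
team's distance to the pitch centre, and weighted clustering coefficients of
per-frame player graphs — and evaluates, over sliding windows, the practical
causal-emergence criterion

```
Ψ(V) = I(V_t ; V_{t'}) − Σ_i I(X_t^i ; V_{t'}),      t' = t + 1 s,
```

where `V_t` is the macro feature, `X_t^i` the i-th player's micro feature,
and `I` the Gaussian mutual-information estimator (½·ln of a covariance
determinant ratio, in nats). Ψ > 0 means the macro carries *synergistic*
predictive information beyond the individual players; Ψ < 0 means the
players' information is *redundant* with the macro. Two downstream analyses
are provided:

- **Match level** — per half, the home-minus-away difference in mean Ψ is
  correlated (Pearson) against the home-minus-away difference in ball
  possession rate.
- **Event locked** — Ψ curves over the 60 s before each shot (window ends
  at shot−60 … shot−1 s), for the shooting team ("attacker"), the opponent
  ("defender"), and randomly placed same-half baseline intervals matched in
  number; per-timepoint Welch tests with Bonferroni correction and OLS
  trends of the mean curves.

Real tracking feeds of this kind are proprietary, so the package ships a
synthetic match generator with the statistical structure the method
assumes: a latent team centre following a possession-coupled AR(1) process,
players placed at centred formation offsets plus AR(1) idiosyncratic
deviations, a two-state Markov possession chain, hazard-drawn shots, and
pre-shot ramps of the player-level noise. The player-noise scale
`sigma_idio` moves the system continuously between the redundancy-dominated
(Ψ < 0) and synergy-dominated (Ψ > 0) regimes, with closed-form limits for
validation. See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
import numpy as np
import emergence_pitch as ep

params = ep.SyntheticParams()                      # default study conditions
tracking, events = ep.generate_match(params, seed=42)
psi = ep.compute_match_psi(tracking, events, ["com"], ep.EmergenceConfig())

home = psi["com"]["home"]
print(f"windows: {home.valid.sum()} valid of {len(home.times)}")
print(f"mean psi (home): {np.nanmean(home.psi):+.3f} nats")

curves = ep.align_shots(psi["com"], events, duration_s=60, rng_seed=0)
print(f"shots retained: {len(curves.shots)}")
for group in ("attacker", "defender", "baseline"):
    t = ep.trend_regression(curves.mean(group), curves.rel_times, group)
    print(f"{group:9s} slope {t.slope:+.4f} nats/s   R^2 {t.r_squared:.2f}   p {t.p_value:.1e}")
```

prints

```
windows: 5282 valid of 5282
mean psi (home): -0.079 nats
shots retained: 22
attacker  slope +0.0124 nats/s   R^2 0.91   p 1.4e-31
defender  slope -0.0182 nats/s   R^2 0.80   p 9.0e-22
baseline  slope +0.0019 nats/s   R^2 0.47   p 1.4e-09
```

One synthetic match yields ~5300 sixty-second Ψ windows (both halves, one
per second). The attacking team's Ψ rises toward the shot (micro noise ramps
up, so individual players explain less of the team's motion — synergy), the
defending team's Ψ falls (players lock into formation — redundancy), and the
baseline stays comparatively flat.

A CLI mirrors the library:

```sh
emergence-pitch simulate --seed 1 --n-matches 2 --out-dir matches/
emergence-pitch emergence --tracking matches/tracking_000.csv \
    --events matches/events_000.csv --feature com --out psi.csv
emergence-pitch event-analysis --psi psi.csv --events matches/events_000.csv \
    --seed 1 --out-prefix shot
emergence-pitch run --config pipeline.toml     # full pipeline from TOML
```

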