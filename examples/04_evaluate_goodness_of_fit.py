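"""Evaluate a simulation against noisy pseudo-observations.

Simulates the low-S configuration, generates five noisy pseudo-harvests
(5% replicate noise, three replicates — the usual destructive-harvest
design), matches them to the trajectory on thermal time and prints the
per-variable RMSE and Willmott index of agreement, the two statistics used
to judge the simulator.  d close to 1 means the simulated time course
tracks the observations; RMSE is in the variable's own units.
"""

from sulfosim import (
    ObsGenSpec,
    constant_weather,
    evaluate_trajectory,
    generate_pseudo_observations,
    load_fixture,
    simulate,
)

params, init = load_fixture("ls_exp1")
weather = constant_weather(60, t_min=10.0, t_max=20.0, par=5.0)
obs, traj = generate_pseudo_observations(
    ObsGenSpec(
        params=params,
        init=init,
        weather=weather,
        noise_sd=0.05,
        n_replicates=3,
        seed=17,
        critical_status=False,
    ),
    return_trajectory=True,
)
report = evaluate_trajectory(traj.to_frame(), obs, tolerance=10.0)

print(f"{'variable':14s} {'RMSE':>10s} {'d':>8s} {'n':>4s}")
for _, row in report.iterrows():
    if row["n"] == 0:
        continue
    d = f"{row['d']:.3f}" if row["d"] == row["d"] else "  —"
    print(f"{row['variable']:14s} {row['rmse']:10.4g} {d:>8s} {int(row['n']):4d}")
print()
print("With 5% replicate noise the index of agreement stays near 1 for every")
print("growth variable; the sulfate pools are exactly zero under low S, so")
print("their pseudo-observations carry no scatter at all.")
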