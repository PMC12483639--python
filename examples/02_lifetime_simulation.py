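"""One simulated lifetime of the complete daily-step model.

Samples a woman's life history (menarche, cycles, menopause, possibly HRT),
runs the stochastic daily map with binomial mutations and the square-wave
immune response, and reports the threshold events it finds: rescues (the
moving threshold overtakes the cluster) and, on some seeds, the transition
to cancer.
"""

import numpy as np

import oncodyn as od

pre = od.breast_preset(case=3)
print("growth:", pre.growth)
print(f"immune: s_min={pre.immune.s_min:g}, s_max={pre.immune.s_max:g} cells/day")
print(f"mutations: n={pre.mutation.n:g} cells, p0={pre.mutation.p0:g}/day, "
      f"+{pre.mutation.delta:g}% over {pre.mutation.T / 365:.0f} years")

for seed in (3, 4, 5):
    rng = np.random.default_rng(seed)
    life = od.sample_life_history(rng, pre.life)
    traj = od.simulate_lifetime(pre.growth, pre.mutation, life, pre.immune, 85.0, rng)
    events = ", ".join(f"{kind} at age {day / 365:.1f}" for kind, day in traj.events) or "none"
    print(f"\nseed {seed}: menopause {life.menopause_age:.1f} y"
          f"{f' + {life.hrt_years:.1f} y HRT' if life.hrt_years else ''}")
    print(f"  events: {events}")
    if traj.transition_day is not None:
        d = traj.transition_day
        print(f"  -> transition (cancer onset) at age {d / 365:.2f} in the "
              f"{od.phase_label_at(d, life)} phase; threshold there was "
              f"{traj.A_bar[d]:.0f} cells")
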