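"""Integrate one spore through a double germinant pulse and watch it commit.

A spore with 1500 germinant receptors sees two 5-min pulses of 3.5 mM
germinant (at t = 0 and t = 30 min).  Receptor activation feeds channel
activation; once a few channels are open, cooperative opening takes over
and the whole 6500-channel population opens — the germination event.
"""

from sporegerm import get_preset, integrate_spore, classify_outcome, release_interval

preset = get_preset("fig3")
traj = integrate_spore(1500.0, preset.params, preset.protocol)
outcome = classify_outcome(traj.t_open, preset.protocol, release_interval(traj))

print(f"initial GR copies        : {traj.ri0:.0f}")
print(f"T_open (Co >= 50)        : {traj.t_open:.2f} min")
print(f"outcome                  : {outcome.outcome}")
print(f"T_lag after pulse end    : {outcome.t_lag:.2f} min")
print(f"release interval proxy   : {outcome.t_release_proxy:.2f} min")
print(f"peak activated channels  : {traj.Cca.max():.1f} of {preset.params.c_total:.0f}")
print(f"open channels at 60 min  : {traj.Co[-1]:.0f}")
print()
print("The threshold crossing during the first pulse window (t < 30 min)")
print("classes this spore as a first-pulse germinator; only ~25 channels are")
print("ever GR-activated, yet cooperative opening drives all ~6400 open.")
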