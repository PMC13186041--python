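"""Reproduce the double-pulse memory experiment over a 500-spore population.

GR copy numbers vary spore-to-spore as gamma(shape 25, scale 44) — mean
1100, sd 220.  Two 5-min 3.5 mM pulses split the population into first-
pulse germinators, second-pulse germinators (the memory effect), and
non-germinators.  The exact population percentages (gamma tail mass above
the deterministic recruitment boundaries) are printed alongside the
realized 500-spore cycle.
"""

from sporegerm import (
    GammaSpec,
    asymptotic_pulse_fractions,
    get_preset,
    germination_curve,
    pulse_summary,
    run_ensemble,
)
from sporegerm.ensemble import EnsembleConfig

preset = get_preset("fig1")
gamma = GammaSpec(preset.gamma_shape, preset.gamma_scale)

config = EnsembleConfig(
    gamma=gamma, params=preset.params, protocol=preset.protocol, n_spores=500, seed=0
)
result = run_ensemble(config)
summary = pulse_summary(result)
curve = germination_curve(result)

print(f"gamma GR distribution    : mean {gamma.mean:.0f}, sd {gamma.sd:.0f}")
print(f"fitted from the draws    : shape {result.fit.shape:.2f} "
      f"[{result.fit.shape_ci[0]:.2f}, {result.fit.shape_ci[1]:.2f}]")
print(f"first-window germination : {summary.first_window_pct:.1f} % (cycle of 500)")
print(f"cumulative at 60 min     : {summary.cumulative_pct:.1f} %")
print(f"second-window increment  : {summary.second_window_pct:.1f} %")

exact = asymptotic_pulse_fractions(gamma, preset.params, preset.protocol)
print()
print(f"population (exact) values: first {exact['first_window_pct']:.1f} %, "
      f"cumulative {exact['cumulative_pct']:.1f} %")
print(f"recruitment boundaries   : germination at {exact['germination_boundary']:.0f} "
      f"copies, first-pulse at {exact['first_pulse_boundary']:.0f} copies")
print()
print("Far more spores germinate on the second pulse than the first: the")
print("sub-threshold channel activation left by pulse one is the memory.")
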