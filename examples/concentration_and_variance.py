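"""How germinant dose and population heterogeneity shape the memory effect.

Two sweeps over the wild-type configuration (n = 200 spores per point to
keep this example quick):

- germinant concentration 2.0-3.5 mM at fixed gamma(25, 44) GR distribution:
  low doses recruit nobody on the first pulse yet still prime a fraction
  of the population for the second one;
- distribution sd 110/220/440 at fixed mean 1100: a heavier right tail
  pushes more spores over the first-pulse recruitment boundary.
"""

import numpy as np

from sporegerm import GammaSpec, concentration_scan, get_preset, variance_scan
from sporegerm.ensemble import EnsembleConfig

preset = get_preset("fig1")
cfg = EnsembleConfig(
    gamma=GammaSpec(preset.gamma_shape, preset.gamma_scale),
    params=preset.params,
    protocol=preset.protocol,
    n_spores=200,
    seed=0,
)

print("Germinant concentration sweep (first / second window %):")
table = concentration_scan(np.array([2.0, 2.5, 3.0, 3.5]), cfg)
for _, row in table.iterrows():
    print(
        f"  {row['concentration_mM']:.1f} mM : "
        f"{row['first_window_pct']:5.1f} / {row['second_window_pct']:5.1f}"
    )

print()
print("GR-distribution width sweep at mean 1100 (first window %):")
vtable = variance_scan(np.array([110.0, 220.0, 440.0]), 1100.0, cfg)
for _, row in vtable.iterrows():
    print(
        f"  sd {row['sd']:5.0f} (shape {row['gamma_shape']:6.2f}) : "
        f"{row['first_window_pct']:5.1f}"
    )

print()
print("At 2 mM the first pulse recruits nobody but primes spores that then")
print("fire on pulse two; wider GR distributions trade second-pulse memory")
print("for immediate first-pulse germination from the high-copy tail.")
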