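# sporegerm

Kinetic network simulator of **germination memory in *Bacillus subtilis*
spores**.

Dormant spores sense nutrient germinants through germinant receptors (GRs)
in the inner membrane; the signal is relayed to SpoVA channels whose opening
releases the spore's CaDPA depot and commits it to germinate. Spore
populations show *memory*: a brief germinant pulse that triggers few spores
primes many more to fire on a second pulse half an hour later. `sporegerm`
implements the minimal mass-action network that reproduces this behaviour
and the analysis tools around it: single-spore trajectories with
germination-event detection, gamma-heterogeneous population ensembles and
percentage-germination curves, deterministic parameter scans, and the
closed-form reductions of the receptor and channel subsystems.

It is aimed at quantitative microbiologists and systems biologists who want
to simulate double-pulse germination protocols, fit or compare percentage-
germination curves, or probe how receptor copy-number heterogeneity and
channel cooperativity shape population outcomes.

## The model

Five species per spore: inactive/active receptors `Ri`, `Ra` and closed /
activated-closed / open channels `Cc`, `Cca`, `Co` (copies per spore), driven
by a square-wave germinant concentration `S(t)` (mM; minutes throughout):

```
dRi/dt  = -k1·S·Ri + k-1·Ra
dRa/dt  = +k1·S·Ri - k-1·Ra
dCc/dt  = -k2·Ra·Cc - k4·Co^n/(Co^n + θ^n) + k5·Co
dCca/dt = +k2·Ra·Cc - k3·Cca
dCo/dt  = +k3·Cca + k4·Co^n/(Co^n + θ^n) - k5·Co
```

The Hill term (`n = 3`, `θ = 20`) makes channel opening cooperative and
bistable: below a separatrix the open-channel count decays back, above it
the whole `C_total = 6500` channel population opens autocatalytically to the
plateau `k4/k5`. A spore germinates when `Co` reaches 50 copies (`T_open`);
`T_lag = T_open − T_block` measures the lag after the triggering pulse ends.
Population heterogeneity enters solely through the initial receptor count
`Ri(0) ~ Gamma(a, b)` (mean `ab`, sd `√a·b`); the percentage-germination
curve is the cumulative distribution of `T_open` over the population.

Memory lives in the slow relaxation between pulses: active receptors
(timescale `1/k-1`), activated-closed channels (`1/k3`) and sub-threshold
open channels (`1/β`, `β = k5 + k2·Ra`) all outlast the pulse, so the second
pulse starts from a pre-loaded network.

Named presets carry the published configurations: `fig1` (wild type,
two 5-min 3.5 mM pulses, gamma mean 1100/sd 220), `fig2c`/`fig2d` (2-min
10 mM pulses; broad wild-type vs narrow overexpression GR distributions)
and `fig3` (deterministic copy-number scan).

## Worked example

```bash
python examples/memory_ensemble.py
```

```
gamma GR distribution    : mean 1100, sd 220
fitted from the draws    : shape 26.98 [23.66, 30.30]
first-window germination : 11.6 % (cycle of 500)
cumulative at 60 min     : 62.8 %
second-window increment  : 51.2 %

population (exact) values: first 13.0 %, cumulative 65.7 %
recruitment boundaries   : germination at 999 copies, first-pulse at 1351 copies
```

Reading this: of a 500-spore cycle, 11.6% crossed the germination threshold
before the second pulse began and 62.8% by the 60-min horizon — the
second pulse recruited over four times as many spores as the first, which
is the memory effect. Because the per-spore dynamics are deterministic,
each percentage is just the gamma tail mass above a critical receptor
count; those *exact* population values (13.0% / 65.7%, boundaries at 999
and 1351 copies) are printed below the realized cycle, which scatters
around them with binomial noise (sd ≈ 1.5 points at n = 500).

Other examples: `single_spore_trajectory.py` (one spore's commitment,
`T_open = 13.37 min`), `gr_copy_scan.py` (the three subpopulation bands
950/1000/1400), `analytic_reductions.py` (occupancy, bistability, membrane
geometry) and `concentration_and_variance.py` (dose and heterogeneity
sweeps). The same capabilities are available from the shell, e.g.:

```bash
sporegerm ensemble --preset fig1 --seed 1 -o out/
sporegerm scan-gr --preset fig3 -o out/
sporegerm analytic occupancy --k1 350e-5 --s 10 --k-1 100e-3
```

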