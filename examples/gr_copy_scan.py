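"""Deterministic scan over GR copy numbers: the three response subpopulations.

One spore per copy number from 600 to 1800 (step 50), all under the same
double-pulse protocol.  The scan splits cleanly into three contiguous
bands — never germinates / recruited by the second pulse only / already
recruited by the first pulse — because the germination decision is
monotone in the receptor count.
"""

from sporegerm import FIG3_SCAN_VALUES, get_preset, gr_copy_scan
from sporegerm.scans import peak_channel_activation

preset = get_preset("fig3")
scan = gr_copy_scan(FIG3_SCAN_VALUES, preset.params, preset.protocol)

for name, value in scan.boundaries.items():
    print(f"{name:28s}: {value:.0f} copies/spore")

peaks = peak_channel_activation(scan)
germ = [o.outcome != "no_germination" for o in scan.outcomes]
print(f"{'scan-wide peak Cca':28s}: {peaks['peak_cca'].max():.1f} channels")
print(f"{'Co plateau (germinators)':28s}: {peaks.loc[germ, 'co_final'].mean():.0f} channels")
print()
print("Spores up to 950 copies never fire; 1000-1350 fire only after the")
print("second pulse (memory band); 1400+ fire on the first pulse.  Direct")
print("GR contact activates at most ~27 channels - cooperative opening")
print("relays the signal to the full ~6400-channel plateau.")
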