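"""How tone frequency and amplitude drive Stockwell entropy.

Builds unit sines at the band-edge frequencies, runs the
S-transform -> band waveform -> sliding differential entropy pipeline,
and prints the entropy-stability grid: the standard deviation of each
entropy sequence for window widths 5, 10 and 20 samples.

Low-frequency tones give large stds (a 5-sample window at 200 Hz sees
only a sliver of a 1 Hz cycle, so the local variance -- hence the
entropy -- swings wildly across the cycle).  From ~30 Hz upward every
window covers a full cycle and the entropy flattens: Gamma-band entropy
features are temporally stable, which is what makes them usable for
classification.
"""

import numpy as np

from stentropy import build_std_grid, run_scenarios

grid = build_std_grid()  # 200 Hz, 3 s epoch, windows 5/10/20
print("Entropy-stability grid (std of the sliding-entropy sequence,")
print("study reporting units of 0.05 nat):\n")
print(grid.table.to_string(index=False, float_format=lambda v: f"{v:7.2f}"))

gamma = grid.table[grid.table.frequency >= 41.0]
print(
    f"\nMax std over 41-45 Hz tones, all windows: "
    f"{gamma[['std_w5', 'std_w10', 'std_w20']].to_numpy().max():.2f} "
    "(< 1: the Gamma band is stable)"
)

scenarios = run_scenarios()
for name, claim in [
    ("chirp_amp_up", "rising amplitude on a 0->46 Hz sweep"),
    ("chirp_amp_down", "falling amplitude on a 0->46 Hz sweep"),
]:
    df = scenarios[name]
    half = len(df) // 2
    slope = np.polyfit(df["time"][half:], df["entropy_w20"][half:], 1)[0]
    print(
        f"{claim}: late entropy slope {slope:+.2f} nats/s "
        "(entropy tracks log amplitude once the sweep is fast enough)"
    )
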