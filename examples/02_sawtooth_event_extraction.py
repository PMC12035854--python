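"""Build a noisy sawtooth force-extension curve and extract its events.

The selection rules mirror single-molecule practice: peaks are reported
relative to the post-peak baseline, and peaks over 500 pN absolute /
200 pN relative, peak-to-peak gaps over 30 nm, or curves shorter than
100 nm are excluded from unfolding statistics.
"""

from fibrinpull import SelectionRules, detect_events, make_sawtooth
from fibrinpull.synthetic import SawtoothSpec

spec = SawtoothSpec(
    peak_forces=(220.0, 65.0, 90.0, 75.0, 640.0),
    peak_positions=(30.0, 58.0, 85.0, 110.0, 175.0),
    baseline=8.0,
    rise_stiffness=12.0,
    noise_sd=2.0,
    total_extension=200.0,
)
curve = make_sawtooth(spec, seed=7)
det = detect_events(curve, SelectionRules())

print(f"curve accepted: {det.curve_accepted}")
print("peak(pN)  baseline  rel(pN)  x(nm)   p2p(nm)  K(pN/nm)  flags")
for e in det.events:
    print(
        f"{e.peak_force_abs:7.1f}  {e.baseline:7.1f}  {e.peak_force_rel:6.1f}  "
        f"{e.extension_at_peak:6.1f}  {e.peak_to_peak:6.1f}  {e.stiffness:7.1f}  "
        f"{','.join(sorted(e.flags)) or '-'}"
    )
print(
    "\nThe large first and last peaks are surface desorption and tip "
    "detachment; the 640 pN peak also trips the 500 pN absolute rule. "
    "The three interior peaks are retained unfolding events whose rising "
    "slopes estimate the chain stiffness (~12 pN/nm here)."
)
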