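"""Extract spectral and temporal features from one epoch.

Estimates the individual alpha frequency (IAF) from the eyes-closed
baseline as the spectral center of gravity over occipital channels,
anchors the five frequency bands on it, and computes normalized band
powers and Hjorth parameters for a tasting epoch.
"""

import eegflavor as ef
from eegflavor.montage import OCCIPITAL

config = ef.PanelConfig(n_subjects=2, seed=7, baseline_duration=30.0)
subjects, sessions = ef.simulate_panel(config)
subject, session = subjects[0], sessions[0]

iaf = ef.estimate_iaf(session.baseline, OCCIPITAL)
print(f"true IAF {subject.true_iaf:.2f} Hz, estimated {iaf:.2f} Hz")

bands = ef.define_bands(iaf)
print("\nIAF-anchored bands (Hz):")
for name, (lo, hi) in bands.intervals.items():
    print(f"  {name:>5}: [{lo:5.2f}, {hi:5.2f}]")

tl = session.tl_epochs[("Be", 1)]
powers = ef.band_powers(ef.welch_psd(tl), bands)
hj = ef.hjorth(tl)
print("\nchannel Cz during the first tasting trial:")
for band in ("delta", "theta", "alpha", "beta", "gamma"):
    print(f"  p_{band:<6} = {powers.p['Cz'][band]:.3f}")
print(f"  activity   = {hj.activity['Cz']:8.2f} uV^2  (signal variance)")
print(f"  mobility   = {hj.mobility['Cz']:8.2f} rad/s (dominant frequency proxy)")
print(f"  complexity = {hj.complexity['Cz']:8.2f}       (bandwidth proxy, >= 1)")
print("\nNormalized band powers sum to at most 1 per channel; together "
      "with the three Hjorth parameters they form the 8 features each "
      "channel contributes per epoch.")
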