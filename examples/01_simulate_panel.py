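"""Simulate a virtual expert tasting panel.

Generates subjects with individual alpha frequencies, expertise groups
and latent flavor intensities, then synthesizes one subject's recording
session (baseline + water-rinse and tasting epochs for 2 phases × 4
trials) together with noisy 0-10 attribute ratings.
"""

import eegflavor as ef

config = ef.PanelConfig(n_subjects=5, seed=42, baseline_duration=20.0)
subjects, sessions = ef.simulate_panel(config)

print("subject  age  group  true IAF (Hz)")
for s in subjects:
    print(f"{s.subject_id:>7}  {s.age:>3}  {s.group:>5}  {s.true_iaf:.2f}")

session = sessions[0]
print(f"\n{session.subject_id}: baseline {session.baseline.duration:.0f} s, "
      f"{len(session.tl_epochs)} tasting epochs, "
      f"{len(session.wr_epochs)} rinse epochs")
print("\nratings of the first benchmark-phase trial (0-10 scale):")
for attr in ef.ATTRIBUTES:
    print(f"  {attr:>10}: {session.ratings[('Be', 1, attr)]:.2f}")
print("\nRatings are the subject's latent intensity plus Gaussian noise, "
      "clipped to the scale; the EEG band powers of the tasting epochs "
      "are coupled to the same latent intensities.")
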