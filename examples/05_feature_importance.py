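"""Inspect which features drive a fitted model.

Fits the boosted ensemble on a full dataset, extracts impurity-based
feature importance (normalized to sum 1), sums it across channels into
feature classes, and prints the channel-level topography data.
"""

import eegflavor as ef
from eegflavor.dataset import (
    assemble_dataset,
    demographics_frame,
    extract_panel_features,
    ratings_frame,
)
from eegflavor.evaluation import aggregate_importance
from eegflavor.models import LSBoostHyperParams, feature_importance, fit_lsboost

effect_map = dict(ef.DEFAULT_EFFECT_MAP)
effect_map["sweet"] = ef.EffectSpec("central", "alpha", 0.5)
config = ef.PanelConfig(n_subjects=6, seed=3, effect_map=effect_map,
                        baseline_duration=20.0)
subjects, sessions = ef.simulate_panel(config)
records = extract_panel_features(subjects, sessions)
table = assemble_dataset(
    records, demographics_frame(subjects), ratings_frame(sessions), "Be"
)

hp = LSBoostHyperParams(n=40, rho=0.2, leaf_size=2, max_splits=8)
model = fit_lsboost(table.X.to_numpy(), table.y["sweet"].to_numpy(), hp,
                    seed=0, feature_names=list(table.X.columns))
imp = feature_importance(model)

summary = aggregate_importance([("Be", "sweet", imp, list(table.X.columns))])
row = summary.class_table.iloc[0]
print("importance by feature class (sums to 1 with Age and Group):")
for cls in ("p_delta", "p_theta", "p_alpha", "p_beta", "p_gamma",
            "A", "M", "C", "Age", "Group"):
    print(f"  {cls:>8}: {row[cls]:.3f}")

topo = summary.topography.sort_values("score", ascending=False)
print("\ntop 5 channels (per-channel importance, scalp x/y for topography):")
print(topo.head(5).to_string(index=False,
                             formatters={"score": "{:.3f}".format}))
print("\nThe planted central-alpha coupling should surface as high "
      "p_alpha class importance concentrated on central channels.")
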