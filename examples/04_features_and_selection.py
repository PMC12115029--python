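"""Extract the nine sliding-window features and select a subset by Lasso."""

import eogstress as eog
from eogstress.features import FEATURE_NAMES, lasso_select

session, _ = eog.render_session(eog.SynthConfig(seed=7), 0)
prep = eog.preprocess_session(session)
events = eog.detect_blinks(prep.eog_v, session.sampling_rate)
table = eog.build_feature_table(session, prep, events)

print(f"{len(table)} labelled 3 s windows (1 s step; boundary windows dropped)")
print(table["label3"].value_counts().to_string())

sel = lasso_select(table[FEATURE_NAMES], table["label2"].to_numpy(), seed=0)
print(f"\nLasso penalty (1-SE rule): alpha = {sel.alpha:.4f}")
print("selected:", ", ".join(sel.selected))
dropped = [n for n in FEATURE_NAMES if n not in sel.selected]
print("removed: ", ", ".join(dropped) or "none")
print("\nFeatures with exactly-zero L1 coefficients are removed; on one "
      "subject the penalty typically discards the weakest window statistics.")
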