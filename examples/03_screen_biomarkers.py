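"""Screen differential metabolites: OPLS-DA VIP > 1 and BH-adjusted P < 0.05.

Screens the early phase (4-12 h) against control, reports the OPLS-DA model
quality (R2Y, cross-validated Q2, permutation test, CV-ANOVA), and assembles
the hierarchical panels used by the tandem classifier.
"""

from woundage import SyntheticConfig, generate_study
from woundage.chemometrics import cv_anova, opls_fit, permutation_test, q2_crossval
from woundage.screen import assemble_panels, screen_features
from woundage.tandem import default_scheme

config = SyntheticConfig(seed=1)
study = generate_study(config)
scheme = default_scheme()

result = screen_features(study, scheme.labels_of_group("I"))
selected = result[result["selected"]]
print(f"phase I vs control: {len(selected)} of {len(result)} features selected")
print(selected.head(8).round(3).to_string(), "\n")

contused = study.subset_labels(set(scheme.coarse))
X = contused.log_areas().to_numpy()
phases = [scheme.coarse_of(l) for l in contused.meta["label"]]
model = opls_fit(X, phases)
cv = q2_crossval(X, phases, seed=1)
print(f"three-phase OPLS-DA: R2Y = {model.r2y:.3f}, Q2 = {cv.q2:.3f}, "
      f"CV-ANOVA p = {cv_anova(cv):.2e}")
perm = permutation_test(X, phases, n_perm=20, seed=1)
print(f"permutation test: original Q2 beats {100 * perm.q2_quantile():.0f}% "
      f"of {perm.n_perm} label-shuffled refits\n")

panels = assemble_panels(study, scheme)
print(f"union panel: {len(panels.union)} features "
      f"(per-group screens: {panels.per_group_counts})")
for group, node_panel in panels.per_node.items():
    print(f"  second-level panel {group}: {len(node_panel)} features")
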