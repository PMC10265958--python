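"""Train the two-level tandem classifier and validate it internally/externally.

Level 1 assigns the coarse phase (I: 4-12 h, II: 16-32 h, III: 36-48 h); the
routed level-2 node assigns one of seven wound-age windows.  Each node picks
the best of LR / SVM / RF / MLP by held-out validation accuracy.
"""

from woundage import SyntheticConfig, generate_external, generate_study
from woundage.evaluate import run_external_validation, run_internal_validation
from woundage.tandem import build_tandem, default_scheme

config = SyntheticConfig(seed=1)
study = generate_study(config)
tandem = build_tandem(study, default_scheme(), seed=1)

print("selected learners per node:")
print(f"  level 1: {tandem.level1.spec.kind} "
      f"(val acc {tandem.level1.candidate_accuracies})")
for group, node in tandem.level2.items():
    print(f"  level 2/{group}: {node.spec.kind} (val acc {node.candidate_accuracies})")

internal = run_internal_validation(tandem, study)
print(f"\ninternal validation: {internal.n_correct}/{internal.n} correct "
      f"(accuracy {100 * internal.accuracy:.1f}%)")
print("confusion matrix (true x predicted window):")
print(internal.confusion.to_string())

external, key = generate_external(config, 13)
ext = run_external_validation(tandem, external, key)
print(f"\nexternal validation (13 held-out samples): "
      f"{ext.n_correct}/{ext.n} correct (accuracy {100 * ext.accuracy:.1f}%)")
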