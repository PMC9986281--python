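"""Budget-of-uncertainty protection against uncertain casualty counts.

Shows the protection function on a bare list of deviation impacts, then
sweeps the budget on a small generated instance: the robust objective
climbs from the nominal model (budget 0) to the fully conservative
Soyster limit.
"""

from casevac import (
    GeneratorSpec,
    evaluate,
    expand_groups,
    generate,
    protection_value,
    robust_objective,
)

# worst-case impacts fhat_i * P_i of three uncertain casualty groups
impacts = [0.4, 0.3, 0.1]
for gamma in (0, 1, 1.5, 3):
    r = protection_value(impacts, gamma)
    print(f"budget {gamma:>3}: protection {r.phi:.2f}  (dual check {r.dual_value():.2f})")

instance = generate(
    GeneratorSpec(n_affected=5, n_medical=3, casualty_range={"R": (10, 60), "G": (20, 90)}, seed=42)
)
groups = expand_groups(instance)
assignment = [(g.id % 3) + 1 for g in groups]
nominal = evaluate(assignment, instance, instance.scenarios[0]).objective
print(f"\nnominal expected deaths: {nominal:.3f}")
print("budget  robust objective  protection  gap vs nominal")
for gamma in (0, 1, 2, 4, 5):
    ro = robust_objective(assignment, instance, instance.scenarios[0], gamma)
    gap = 100 * (ro.f - nominal) / nominal
    print(f"{gamma:6}  {ro.f:16.3f}  {ro.phi_total:10.3f}  {gap:13.2f}%")
# With budget Gamma the worst Gamma casualty counts deviate 20% above
# nominal; the protection term is the extra expected deaths that
# adversarial deviation can cause, so the objective rises with Gamma
# and saturates once every count deviates (Soyster model).
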