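"""Simulate one subject's weight trajectory under a very-low-energy diet.

A 93.31 kg woman (the cohort-mean baseline) with a moderately active
lifestyle (PAL 1.6) follows an 800 kcal/d total-diet-replacement plan for
8 weeks. The model integrates daily energy balance, with expenditure
falling as fat-free mass shifts and adaptive thermogenesis develops, and
prints the weekly weigh-in weights it predicts.
"""

from ebsim import ModelConfig, SubjectBaseline, simulate
from ebsim.intake import IntakeSchedule

subject = SubjectBaseline(w0=93.31, sex="female", pal=1.6)
schedule = IntakeSchedule.constant(800.0)
traj = simulate(subject, schedule, 8, ModelConfig.original())

print("week  weight(kg)  loss(kg)")
for week, w in traj.weekly_weights().items():
    print(f"{week:4d}  {w:9.2f}  {subject.w0 - w:7.2f}")
print(f"\nend weight {traj.end_weight:.2f} kg, total loss {traj.total_loss:.2f} kg")
print("Weekly losses shrink over time: expenditure falls with weight, so a")
print("fixed intake buys progressively less deficit.")
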