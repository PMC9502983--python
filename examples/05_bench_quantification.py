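"""The bench quantification formulas on constructed readings.

Relative expression by delta-delta-Ct, ChIP-qPCR percent input, dual-
luciferase fold over a reporter backbone, and the FAIRE-qPCR free/total DNA
recovery ratio.
"""

from ecdyn.assays import (
    CtMeasurement,
    LuciferaseMeasurement,
    ddct_fold_sem,
    ddct_relative_expression,
    faire_recovery_from_ct,
    faire_recovery_ratio,
    luciferase_fold,
    percent_input,
)

# ddCt: treated target amplifies two cycles earlier than control -> 4-fold
control = CtMeasurement("control", "E75B", "RP49",
                        (24.05, 23.98, 24.01), (20.02, 19.97, 20.00))
treated = CtMeasurement("treated", "E75B", "RP49",
                        (22.01, 21.95, 22.03), (19.99, 20.03, 20.01))
fold = ddct_relative_expression(treated, control)
sem = ddct_fold_sem(treated, control)
print(f"ddCt relative expression: {fold:.2f} +/- {sem:.2f}")
print("  (triplicate means; ~2 fewer target cycles vs the RP49 reference")
print("   after treatment means ~4x more transcript)")

# ChIP-qPCR percent input at a 1% input dilution
print(f"percent input, IP 2 cycles behind 1% input: "
      f"{percent_input(27.0, 25.0, 0.01):.2f}%")

# dual luciferase
enhancer = LuciferaseMeasurement("enhancer", "stim", firefly=4200.0,
                                 renilla=700.0)
backbone = LuciferaseMeasurement("backbone", "stim", firefly=300.0,
                                 renilla=500.0)
print(f"luciferase fold over backbone: {luciferase_fold(enhancer, backbone):.1f}")

# FAIRE recovery
print(f"FAIRE recovery (free 12 ng / total 80 ng): "
      f"{faire_recovery_ratio(12.0, 80.0):.3f}")
print(f"FAIRE recovery from Ct (free 24.3 vs total 22.1): "
      f"{faire_recovery_from_ct(24.3, 22.1):.3f}")
print()
print("All Ct arithmetic assumes perfect doubling per cycle; the renilla")
print("channel normalizes transfection efficiency before comparing firefly")
print("activity to the promoter-only backbone.")
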