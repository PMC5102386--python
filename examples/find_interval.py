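"""Find the Uncertain Interval on a simulated binormal test and compare it
with the maximized Youden threshold and TG-ROC's Intermediate Range."""

import trithresh as tt

model = tt.get_model(4)  # healthy N(0,1), diseased N(3,1), prevalence 0.5
data = tt.binormal_sample(model, n=1000, seed=42)
print(f"model {model.model_id}: diseased N({model.mu1}, {model.sd1}^2), "
      f"prevalence {model.prevalence}, analytic AUC {model.auc:.3f}")
print(f"empirical AUC {tt.empirical_auc(data):.3f}\n")

youden = tt.optimal_threshold(data, "youden")
print(f"Youden threshold {youden.threshold:.3f}: CCR {youden.ccr:.3f}  "
      f"Se {youden.se:.3f}  Sp {youden.sp:.3f}")

ui = tt.find_uncertain_interval(data, select=0.55)
if ui.found:
    tri = tt.quality_threshold(data, ui.lower, ui.upper)
    print(f"Uncertain Interval [{ui.lower:.3f}, {ui.upper:.3f}] around "
          f"intersection {ui.intersection:.3f}: {ui.n_inside} subjects, "
          f"within-interval CCR {ui.ui_ccr:.3f}")
    print(f"outside it (MCI):  CCR {tri.mci_ccr:.3f}  Se {tri.mci_se:.3f}  "
          f"Sp {tri.mci_sp:.3f}")
else:
    print(f"no uncertain interval: {ui.reason}")

tg = tt.tgroc_thresholds(data, level=0.9)
print(f"TG-ROC intermediate range [{tg.lower:.3f}, {tg.upper:.3f}] "
      f"(reversed: {tg.reversed}); valid-range CCR {tg.quality.mci_ccr:.3f}")
print("\nWithholding a decision inside the Uncertain Interval raises the")
print("classification rate for everyone else above the single-threshold CCR.")
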