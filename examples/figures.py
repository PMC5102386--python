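"""Render the three diagnostic figures for a simulated test into scratch/."""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import trithresh as tt

out = Path("scratch")
out.mkdir(exist_ok=True)

data = tt.binormal_sample(tt.get_model(7), n=1000, seed=3)

for name, plot in [
    ("mixed_histogram", tt.viz.plot_mixed_histogram),
    ("tgroc_curves", tt.viz.plot_tgroc_curves),
    ("density_curves", tt.viz.plot_density_curves),
]:
    ax = plot(data)
    path = out / f"{name}.png"
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
    print(f"wrote {path}")

print("\nThe density figure marks the estimated intersection; the mixed")
print("histogram shows where the two classes' scores intermix.")
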