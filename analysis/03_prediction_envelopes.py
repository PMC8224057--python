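"""Simulate uncertainty envelopes for the fitted translocation model.

Runs the 2000-replicate stochastic simulation, writes per-compartment
envelope tables (simulated mean, 95% confidence band, Savitzky-Golay
smoothed 68% prediction band) and a two-panel figure of the apical and
basolateral fractions over time.
"""

import pathlib
import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from nanotrans.nlme import ModelSpec, TranslocationDataset, fit
from nanotrans.simulate import envelope, simulate_ensemble

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = TranslocationDataset.read_csv(OUT / "translocation_au.csv")
    result = fit(data, spec=ModelSpec(eta_phi=True), seed=SEED)
    times = np.linspace(0.0, 240.0, 60)
    ens = simulate_ensemble(result, times, n=2000, seed=SEED)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, compartment in zip(axes, ("apical", "basolateral")):
        env = envelope(ens, compartment=compartment).smoothed_pi(
            degree=2, window_fraction=0.75)
        env.to_csv(OUT / f"envelope_{compartment}.csv")
        ax.plot(env.times, env.mean, color="k", label="simulated mean")
        ax.fill_between(env.times, env.ci_lo, env.ci_hi, alpha=0.3,
                        label="95% CI")
        ax.plot(env.times, env.pi_lo, "k--", lw=0.8, label="68% PI")
        ax.plot(env.times, env.pi_hi, "k--", lw=0.8)
        obs = data.frame[data.frame["compartment"] == compartment]
        ax.plot(obs["time_min"], obs["fraction"], "o", ms=3, alpha=0.5)
        ax.set_xlabel("time (min)")
        ax.set_ylabel(f"{compartment} fraction of applied dose")
        mid = env.mean[len(env.mean) // 2]
        print(f"{compartment}: mean fraction {env.mean[-1]:.3f} at 240 min "
              f"(95% CI {env.ci_lo[-1]:.3f}-{env.ci_hi[-1]:.3f})")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "envelopes.png", dpi=150)
    print(f"wrote {OUT / 'envelopes.png'}")


if __name__ == "__main__":
    main()
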