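"""Replicate reproducibility: robotic vs manual scratching regimes.

Synthetic wound masks are generated with two jitter settings — 1.6%
between-replicate width jitter (robotic) and 16% (manual) — then measured
with the same quantification used for simulated toolpaths.  The
coefficient of variation (CV, 100*SD/mean) of the mean widths separates
the regimes by an order of magnitude.
"""

import scratchkit as sk


def measure_cv(width_sd_percent: float, edge_sd: float, seed0: int, n: int = 24):
    widths = []
    for rep in range(n):
        model = sk.JitterModel(base_width=900.0, edge_sd=edge_sd,
                               width_sd_percent=width_sd_percent, seed=seed0 + rep)
        mask = sk.make_scratch_mask(model, length=5.0, pixel_size=20.0)
        widths.append(sk.wound_metrics(mask, axis="x").mean_width)
    return sk.cv(widths)


robotic = measure_cv(1.6, 15.0, 100)
manual = measure_cv(16.0, 80.0, 200)

print(f"robotic regime: n={robotic.n}  mean width {robotic.mean:.0f} um  "
      f"CV {robotic.cv_percent:.2f}%")
print(f"manual regime:  n={manual.n}  mean width {manual.mean:.0f} um  "
      f"CV {manual.cv_percent:.2f}%")
print(f"separation:     {manual.cv_percent / robotic.cv_percent:.1f}x")
# A plotter-driven scratch reproduces its width to ~1-2% across replicates;
# hand scratching scatters around 10-20% — the difference this tool removes.
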