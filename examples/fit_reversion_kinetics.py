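"""Global exponential fitting of noisy thermal-reversion data.

Generates three technical replicates of a biexponential Pfr decay
(the 1-908 fragment's published constants, 90% fast amplitude) with
realistic measurement noise, fits each globally across the nine analysis
wavelengths, selects between one and two exponentials by AICc, and
summarizes the replicates as mean (±SD).
"""

from phykin import (
    fit_global_single,
    fit_global_double,
    generate_replicates,
    get_entry,
    load_table1,
    replay_config,
    replicate_stats,
    select_model,
)

entry = get_entry(load_table1(), "1-908", "PPhiB")
cfg = replay_config(entry, "thermal_reversion", noise_sd=0.002, seed=2024)
replicates = generate_replicates(cfg, 3)

fits = []
for i, ds in enumerate(replicates, start=1):
    single = fit_global_single(ds)
    double = fit_global_double(ds)
    choice = select_model(single, double)
    best = double if choice.n_exp == 2 else single
    fits.append(best)
    print(
        f"replicate {i}: {choice.n_exp} exponential(s) selected "
        f"(delta-AICc = {choice.delta_aicc:.1f}), "
        f"k = {', '.join(f'{k:.4g}' for k in best.rates)} min^-1, "
        f"fast fraction at 720 nm = {best.fast_amplitude_fraction(720.0):.3f}"
    )

summary = replicate_stats(fits)
print("\nacross replicates (mean ±SD, x1000 min^-1):")
for mean, sd in zip(summary.mean_k, summary.sd_k):
    print(f"  k = {mean * 1e3:.0f} (±{sd * 1e3:.0f})")
print("truth: k1 = 320, k2 = 34 (x1000 min^-1), fast amplitude 0.90")
# The fast phase dominates the decay; the slow phase holds only 10% of
# the amplitude, so its constant carries the larger replicate scatter.
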