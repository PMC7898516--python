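"""Camera pipeline: per-image colors -> composites -> transition dates.

Filters low-sun and snowy images, computes per-image Gcc/GRVI, composites
them to 3-day products with the 90th-percentile statistic, smooths with
LOESS, and extracts the days on which the smoothed index crosses 10/25/50%
of its seasonal amplitude (SOS rising, EOS falling), with bootstrap
uncertainty on the 50% dates.
"""

from conipheno import indices, phenology, synth

cfg = synth.SyntheticSiteConfig(seed=1)
weather = synth.generate_weather(cfg, n_years=3)
sim = synth.generate_greenness(cfg, weather)
roi = synth.generate_roi_colors(cfg, sim.observations)

filtered, counts = indices.filter_images(roi, return_counts=True)
print(f"images: {len(roi)} recorded, removed {counts['low_sun']} low-sun "
      f"and {counts['snow']} snowy, kept {counts['retained']}")

comp = indices.composite(filtered, statistic="q90", window_days=3)
print(f"3-day q90 composites: {len(comp)}")

dates = phenology.bootstrap_transitions(
    comp["date"], comp["gcc"], n_boot=200, seed=1, thresholds=(0.5,)
)
print("\n50%-amplitude transition dates (day of year, 95% bootstrap interval):")
for _, row in dates.iterrows():
    label = "SOS" if row["direction"] == "rising" else "EOS"
    print(f"  {int(row['year'])} {label}50: {row['doy']:6.1f} "
          f"[{row['ci_low_doy']:.1f}, {row['ci_high_doy']:.1f}]")
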