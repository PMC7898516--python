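"""Generate one coupled synthetic site and summarize its data streams.

A single seed produces daily weather, a latent greenness trajectory driven
by that weather, noisy camera observations (with snow and gaps), and
half-hourly fluxes whose photosynthetic capacity tracks the same latent
state.  The printed SNR is the seasonal amplitude over the mean day-to-day
jitter of the raw daily observations; compositing multiple images per day
raises it before the site-screening rule (>= 20:1) is applied.
"""

import pandas as pd

from conipheno import indices, synth

cfg = synth.SyntheticSiteConfig(seed=1)
weather = synth.generate_weather(cfg, n_years=5)
sim = synth.generate_greenness(cfg, weather)
fluxes = synth.generate_fluxes(cfg, sim.latent, weather)

obs = sim.observations
print(f"weather days:        {len(weather)}")
print(f"greenness obs:       {len(obs)} ({obs['snow_flag'].sum()} snow-flagged)")
print(f"half-hourly fluxes:  {len(fluxes)}")
print(f"Gcc range:           {obs['gcc'].min():.3f} - {obs['gcc'].max():.3f}")
print(f"seasonal SNR:        {indices.snr(obs):.1f} : 1")
truth = sim.truth["transitions"]
sos50 = truth[(truth.direction == "rising") & (truth.threshold == 0.5)]
print("true SOS50 by year: ",
      {int(y): round(d, 1) for y, d in zip(sos50["year"], sos50["doy"])})
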