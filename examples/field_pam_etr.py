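"""Diurnal electron transport from a field PAM-fluorometer log.

Generates a synthetic field day sampled every 3 min (the PAM cadence),
computes per-record PSII operating efficiency and ETR via
ETR = 0.5 x 0.84 x (Fm'-Fs)/Fm' x PPFD, integrates ETR over the day,
and bins ETR against PPFD to show the saturating light response.
"""

import sunfleck as sf

regime = sf.generate_diurnal_regime(peak_ppfd=1400.0, interval=180.0, seed=19)
pam = sf.generate_pam_trace(regime, phi0=0.78, K=450.0, noise_sd=3.0, seed=19)

trace = sf.etr_trace(pam)
print(f"records: {len(trace.etr)} at {trace.sampling_interval:.0f}-s sampling")
print(f"integrated ETR = {trace.integrated_etr:.2f} mol e- m-2 day-1 "
      "(field values for rice sit near 3 mol m-2 day-1)")

print("ETR vs PPFD (bin mean ± SE):")
binned = sf.etr_vs_ppfd(trace, [0, 200, 400, 600, 800, 1000, 1200, 1400])
for _, row in binned.iterrows():
    print(f"  PPFD {str(row['bin']):>14}: "
          f"{row['mean']:6.1f} ± {row['se']:4.1f} umol e- m-2 s-1 "
          f"(n = {int(row['n'])})")
print("the response saturates: extra photons drive less extra transport")
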