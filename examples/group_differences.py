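"""Group mean spectra, subtraction spectrum and peak attribution.

Positions are significant when |dI| >= 0.01 on normalized intensities
AND |dI| exceeds the propagated standard error of the difference of
means; each one is attributed to the nearest canonical salivary band
within +/-8 cm^-1.
"""

from ramanfp import (SyntheticConfig, simulate_cohort, run_mva_chain,
                     summarize_group, subtraction_spectrum)

config = SyntheticConfig(n_ctrl=12, n_pd=12, n_ad=4,
                         spectra_per_subject=(8, 8), seed=2)
processed = run_mva_chain(simulate_cohort(config))

ctrl = summarize_group(processed, "CTRL")
pd_group = summarize_group(processed, "PD")
print(f"CTRL: {ctrl.n} spectra, mean sd band {ctrl.sd.mean():.4f}")
print(f"PD:   {pd_group.n} spectra, mean sd band {pd_group.sd.mean():.4f}")

report = subtraction_spectrum(ctrl, pd_group, threshold=0.01)
print(f"\nCTRL - PD subtraction: {len(report.significant_positions)} "
      f"significant positions (|dI| >= {report.threshold} and above "
      f"propagated error):")
for pos in report.significant_positions:
    print(f"  {pos:7.1f} cm^-1  ->  {report.attributions[pos]}")
print("\nConfigured group effects sit at protein/lipid bands; positions "
      "within 8 cm^-1 of a configured band are true recoveries.")
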