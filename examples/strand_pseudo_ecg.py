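"""Pseudo-ECG of the transmural strand for the three genotypes.

Simulates the 15 mm ENDO->MIDDLE->EPI strand paced from the ENDO end and
computes the far-field pseudo-ECG at an electrode 2 cm beyond the EPI
end.  Prints QT interval, T-wave width (Tpeak-Tend) and T amplitude:
the short-QT phenotype appears as an abbreviated QT with a broadened
T wave.
"""

from sqt2sim.strand_ecg import simulate_strand, pseudo_ecg, ecg_metrics

for gt in ("WT", "WT-V307L", "V307L"):
    met = ecg_metrics(pseudo_ecg(simulate_strand(genotype=gt)))
    print(f"{gt:9s}: QT = {met.qt:5.0f} ms | Tpeak-Tend = "
          f"{met.t_width:4.0f} ms | T amplitude = "
          f"{met.t_amplitude:+.4f} a.u.")
print("\nQT shortens with mutant dose while the T wave stays upright; "
      "wider Tpeak-Tend reflects increased repolarisation dispersion.")
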