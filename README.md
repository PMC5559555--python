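# sqt2sim

Multi-scale in-silico platform for the short-QT-syndrome type 2 (SQT2)
**V307L KCNQ1** mutation: a 17-state Markov-chain model of the slow
delayed-rectifier potassium current (IKs) — wild type, homozygous
mutant and 50:50 heterozygote — fitted to voltage-clamp constraints,
embedded in a human ventricular action-potential model (ten Tusscher
2006, EPI/MIDDLE/ENDO), and scaled up to a 1D transmural strand with a
pseudo-ECG and an idealised 2D re-entry sheet.

It is written for cardiac electrophysiology modellers who want to ask,
quantitatively: *how does a gain-of-function IKs mutation shorten the
action potential and the QT interval, how does it change
refractoriness and vulnerability to re-entry, and how much selective
IKs block would undo it?*

## The model in brief

IKs gating is a Markov chain with 15 closed states (four voltage
sensors, two sequential transitions each, combinatorial multiplicities)
and two open states:

    C(n1,n2,n3) --n1·α / n2·β--> ...  --θ/η--> O1 --ψ/ω--> O2
    rate(V) = a·exp(b·V),     I_Ks = g_Ks·(O1+O2)·(V − E_Ks)

The V307L mutation is expressed purely through refitted rate
coefficients: activation half-voltage shifted −36 mV, two-fold faster
activation, two-fold slower deactivation. The heterozygote is two
independent half-populations sharing the membrane potential. One
conductance anchor (wild-type EPI APD90 = 325.6 ms at 1 Hz) and one
coupling anchor (planar CV = 70 cm/s) are set once; everything else is
a prediction. See `docs/methods.md` for the full account.

## Worked example

```python
from sqt2sim.tnnp2006 import PacingSpec
from sqt2sim.ventricle_cell import pace, apd90
from sqt2sim.strand_ecg import simulate_strand, pseudo_ecg, ecg_metrics

for gt in ("WT", "WT-V307L", "V307L"):
    a = apd90(pace("EPI", gt, PacingSpec(1000.0, 50)))
    met = ecg_metrics(pseudo_ecg(simulate_strand(genotype=gt)))
    print(f"{gt:9s} EPI APD90 {a:5.1f} ms | QT {met.qt:5.0f} ms "
          f"| T amp {met.t_amplitude:+.4f}")
```

prints

```
WT        EPI APD90 325.6 ms | QT   382 ms | T amp +0.0358
WT-V307L  EPI APD90 233.9 ms | QT   294 ms | T amp +0.0354
V307L     EPI APD90 192.0 ms | QT   250 ms | T amp +0.0320
```

— the mutation abbreviates the epicardial action potential by 29 %
(heterozygote) and 41 % (homozygote), and the strand ECG shows the
corresponding dose-ordered QT shortening with an upright T wave.
Restoring the wild-type behaviour takes deep IKs block:

```python
from sqt2sim.ventricle_cell import titrate_block
ref = apd90(pace("EPI", "WT", PacingSpec(1000.0, 50)))
print(titrate_block("EPI", "WT-V307L", ref),   # 0.63
      titrate_block("EPI", "V307L", ref))      # 0.78
```

i.e. ~63 % block normalises the heterozygous APD and ~78 % the
homozygous one.

The `examples/` directory holds one short narrative script per
capability (channel clamp, single-cell APs, strand pseudo-ECG, block
titration, parameter-recovery fitting, 2D re-entry). A thin CLI mirrors
the workflows:

```bash
sqt2sim cell --type EPI --genotype V307L
sqt2sim strand --genotype WT-V307L
sqt2sim titrate --mode strand --genotype V307L
sqt2sim reproduce          # full regression pipeline -> results/
```

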