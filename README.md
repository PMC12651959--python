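# polyspike

Quantification of translational-efficiency shifts from polysome-profiling
RT-qPCR data, with cross-species spike-in normalization.

Polysome profiling separates mRNAs on a sucrose gradient by how many
ribosomes they carry: 20 fractions are collected from light (free mRNPs,
monosomes) to heavy (large polysomes), and a transcript's distribution
across fractions reads out its translational efficiency. Per-fraction RNA
isolation is lossy and uneven, which distorts those distributions. Adding an
equal amount of cheap cross-species total RNA (e.g. yeast) to every fraction
before isolation, and normalizing each target measurement to a yeast
reference amplicon (RLP24) in the same fraction, cancels per-fraction losses
— because target and spike-in in one tube experience the same loss.

`polyspike` is for anyone analyzing fraction-resolved RT-qPCR from gradient
experiments: it takes a tidy table of quantification cycles (Cq) and
produces loss-corrected distributions and shift statistics, and it ships a
generative simulator of the whole measurement process so the correction can
be validated against known truth.

## The statistics

For one gene in one sample-replicate, with per-cycle amplification
efficiency *E* (default 2.0):

- **Relative quantity (ΔCq):** RQ_i = E^(Cq_min − Cq_i) per fraction *i*.
- **Normalized relative quantity (ΔΔCq):** NRQ_i = RQ_i / RQ_i^spike,
  dividing by the spike-in reference in the same fraction.
- **Percent distribution:** p_i = 100 · v_i / Σ_j v_j over the analysis
  window (fractions 2–16, covering 40S/60S/80S and polysomes).
- **Weighted average:** F_W = Σ_i f_i · p_i / 100, the signal-weighted mean
  fraction number — larger F_W means mass in heavier, better-translated
  fractions.
- **Shift:** ΔF_W = F_W(treated) − F_W(control), computed per replicate.
- **Comparison:** one-tailed paired Student t-test on per-replicate ΔF_W
  between two treatment arms, plus the Pearson "pairing effectiveness"
  correlation of the paired values.

## Worked example

Simulate a two-arm knockdown experiment (control siRNA vs siARK5, each with
untreated/DMEM and sorbitol/SOR conditions, 3 replicates, realistic
per-fraction isolation loss and Cq noise), then quantify it both ways:

```python
import polyspike as ps

cfg = ps.SimulationConfig(loss_sigma=0.5, cq_sigma=0.2, seed=42)
table, truths = ps.simulate_study(cfg, {"siCTRL": 0.3, "siARK5": 1.0})

profiles = ps.profiles_from_table(table)
norm = ps.normalize_profiles(profiles)                      # ΔΔCq mode
raw = [p for p in profiles if p.gene != "RLP24"]            # ΔCq mode
shifts = ps.compute_shift_results(raw + norm)
print(ps.shift_table(shifts).round(3).to_string(index=False))

report = ps.compare_normalization_modes(shifts, arms=("siCTRL", "siARK5"))
for mode in ("raw", "spikein_normalized"):
    m = report["modes"][mode]
    print(f"{mode}: t={m['t_statistic']:.3f}  p={m['p_one_tailed']:.4f}  "
          f"pairing r={m['pairing_r']:.4f}")
```

Output (abridged):

```
sample_id   gene  replicate               mode  fw_control  fw_treated  delta_fw
   siARK5 Bcl-xL          1                raw       8.393       8.695     0.302
   siARK5 Bcl-xL          1 spikein_normalized       7.916       9.195     1.278
   siARK5 Bcl-xL          2                raw       7.397       8.854     1.457
   ...
raw: t=0.943  p=0.2227  pairing r=0.7063
spikein_normalized: t=14.561  p=0.0023  pairing r=0.7308
```

The true shifts were 0.3 (siCTRL) and 1.0 (siARK5). Raw ΔCq estimates are
scattered by per-fraction isolation loss (note the siCTRL replicates ranging
from −0.37 to +1.40), and the paired test cannot resolve the arms
(p = 0.22). Spike-in normalization cancels the loss, the per-replicate
shifts tighten around their true values, and the same test becomes clearly
significant (p = 0.0023) — the benefit the spike-in design exists to buy.

The same chain is available from a shell:

```bash
polyspike simulate --config sim.yaml --out-prefix exp --seed 2
polyspike quantify --cq exp.cq.csv --spikein-gene RLP24 --out exp.quant.csv
polyspike fw --quant exp.quant.csv --window 2:16 --mode both --out-prefix exp
polyspike compare --fw exp.fw.csv --arms siCTRL,siARK5 --direction greater --out exp
polyspike run --config run.yaml --seed 7     # end-to-end with a manifest
```

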