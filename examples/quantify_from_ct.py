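"""Convert raw qPCR cycle-threshold records into CE/mg with spike QC.

Builds a tiny one-sample dataset by hand: duplicate reactions for two
species plus a *Geotrichum candidum* extraction spike, then inverts
each assay's standard curve (Ct = intercept + slope*log10 CE), averages
replicates on the CE scale, and divides by the 5 mg dust mass.  The
spike recovering within 3 cycles of its reference gives QC PASS.
"""

from moldscore import CtRecord, SpikeInRecord, build_default_panel, quantify_sample

panel = build_default_panel()
records = [
    CtRecord("s1", "Aspergillus fumigatus", ct=28.0, replicate=1),
    CtRecord("s1", "Aspergillus fumigatus", ct=28.3, replicate=2),
    CtRecord("s1", "Alternaria alternata", ct=33.5, replicate=1),
    # every other panel species: no amplification (non-detect)
]
spike = SpikeInRecord("s1", ct_observed=22.8, ct_reference=22.0)

values, detected, verdict = quantify_sample(records, spike, panel)
print(f"spike QC: {verdict.label} (delta = {verdict.delta_cycles:+.1f} cycles)")
for sp in ("Aspergillus fumigatus", "Alternaria alternata", "Stachybotrys chartarum"):
    tag = "detected" if detected[sp] else "non-detect"
    print(f"  {sp:26s} {values[sp]:10.1f} CE/mg  ({tag})")
print("non-detects are reported as 0 and floored to 1 CE/mg before scoring")
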