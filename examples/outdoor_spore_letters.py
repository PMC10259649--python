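"""Tukey HSD compact letters on a three-year outdoor spore series.

Draws yearly log10 outdoor mold-spore counts around the recorded
means (the middle year elevated after a hurricane defoliated the
surrounding vegetation) and labels the years with compact letters:
years sharing a letter are not significantly different.  The elevated
middle year typically earns its own letter (a, b, a).
"""

from moldscore import OutdoorSeriesConfig, anova_tukey, generate_outdoor_series

cfg = OutdoorSeriesConfig(seed=4)
series = generate_outdoor_series(cfg)
res = anova_tukey(series, alpha=0.05)

print(f"one-way ANOVA: F = {res.anova_f:.2f}, p = {res.anova_p:.2e}")
print(f"{'year':>6} {'mean':>8} {'sd':>8} {'letter':>7}")
for year in res.labels:
    print(f"{year:>6} {res.means[year]:8.4f} {res.sds[year]:8.4f} {res.letters[year]:>7}")
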