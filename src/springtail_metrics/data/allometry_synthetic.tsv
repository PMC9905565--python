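# SYNTHETIC length-mass regression coefficients per morphogroup.
# Stand-in values with realistic magnitudes for Collembola (log10 dry mass
# [ug] = intercept + slope * log10 body length [mm]); drop in measured
# coefficient tables with the same columns to use real regressions.
# dry_fresh_factor converts dry to fresh mass (>1; ~70% water -> ~3.3).
group	intercept	intercept_se	slope	slope_se	dry_fresh_factor	dry_fresh_se
entomobryomorpha	0.70	0.05	2.50	0.10	3.33	0.15
poduromorpha	0.60	0.06	2.40	0.12	3.20	0.18
symphypleona	0.85	0.07	2.65	0.11	3.45	0.20
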