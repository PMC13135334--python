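"""Run the complete analysis pipeline and write its report tables.

One master seed drives simulation, permutation tests, and LDA, so the
report is reproducible byte for byte. Tables land in
./scratch/example_report/ as TSVs whose header line records the seed
and a configuration hash.
"""

from aacsia import AnalysisConfig, run_full_analysis, scenario_defaults

config = AnalysisConfig(generator=scenario_defaults(seed=1), seed=1,
                        n_perm=999)
report = run_full_analysis(config)

perm = report.tables["permanova"]
print(perm[["block", "n", "pseudo_f", "r2", "p", "dispersion_p"]]
      .to_string(index=False))
print()
print(report.tables["lda_summary"].to_string(index=False))

paths = report.write("scratch/example_report")
print(f"\nwrote {len(paths)} tables; report hash {report.report_hash()[:12]}")

# Every feature block separates the three habitats (p = 0.001 at 999
# permutations is the smallest attainable p); the dispersion test stays
# non-significant, so location differences, not spread, drive the
# separation.
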