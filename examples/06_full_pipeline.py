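"""Run the complete analysis pipeline and print the human-readable report.

Chain: cohort -> threshold scan -> filter -> summaries -> distribution
fits -> exceedance limits (GPQ + noncentral-t + binomial) per tolerance
-> rank associations.  Identical config + seed reproduces the report
byte-for-byte (timestamp aside).
"""

from proctol import AnalysisConfig, GeneratorConfig, run_analysis

report = run_analysis(
    AnalysisConfig(
        generator=GeneratorConfig(seed=1),
        tolerances=(5.0, 4.0),
        replications_R=500_000,
        permutations_M=50_000,
        seed=1,
    )
)
print(report.to_text())
print("Full machine-readable output: report.to_json()")
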