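"""The full four-step pipeline on synthetic data, with manifest and report.

simulate -> screen -> correlation filter -> adjusted DE -> paired rat test
-> concordance, plus the null control vessel and the alternate-query
robustness check.  Stage outputs land as TSV files in the run directory;
the manifest records checksums so a rerun with the same seed is verifiably
identical.
"""

from flowsig.pipeline import PipelineConfig, report, run_pipeline

config = PipelineConfig(out_dir="scratch/example_run", seed=1, run_robustness=True)
manifest = run_pipeline(config)
print(report(manifest, include_table1=True))

# The funnel counts shrink monotonically: screened genes must also pass the
# correlation filter, the covariate-adjusted FDR cut, and the paired rat
# test; concordant genes are the subset moving the same way in both
# species.  The negative-control line must report no genes passed.
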