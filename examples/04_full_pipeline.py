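"""End-to-end pipeline on simulated streams.

Simulates label streams for a small cohort, validates wear time, computes
per-subject metrics, fits every model family, and writes the report
bundle — the same path the `actipart` command line drives.
"""

import tempfile
from pathlib import Path

from actipart import PipelineConfig, run_pipeline
from actipart.simulate import SimulationTruth, generate_cohort

truth = SimulationTruth(epoch_length_s=30.0, n_days=5, day_hours=14.0, sigma_eps=0.1)
cohort = generate_cohort(truth, 30, seed=21)
subjects = cohort.covariates.merge(cohort.outcomes, on="subject_id")

config = PipelineConfig(
    epoch_length_s=30.0,
    min_day_hours=10.0,
    min_valid_days=4,
    outcomes={"outcome": False},
)

outdir = Path(tempfile.mkdtemp()) / "report"
bundle = run_pipeline(config, cohort.streams, subjects, outdir=outdir)

for line in bundle.log:
    print(line)
row = bundle.compositional.iloc[0]
print(f"fitted |beta| = {row['beta_norm']:.3f}, model p = {row['model_p']:.2g}")
print(bundle.profile_contrasts.to_string(index=False))
print(f"bundle written to {outdir}")
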