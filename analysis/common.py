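"""Shared configuration for the numbered analysis drivers.

All drivers write into results/analysis/ and share one seed, so each stage
can be re-run independently on the previous stage's artifacts.
"""

from xsmm.pipeline import PipelineConfig, PipelineRunner

OUTDIR = "results/analysis"
SEED = 1

CONFIG = PipelineConfig(
    seed=SEED,
    outdir=OUTDIR,
    simulate={
        # ~11 probes per probeset mirrors a typical expression-array probeset;
        # 500 probesets keeps the demo run in seconds
        "n_probesets": 500,
        "probes_per_set": 11,
        "consensus_length": 120,
        "tissues": 5,
        "replicates": 2,
    },
)


def runner() -> PipelineRunner:
    return PipelineRunner(CONFIG)
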