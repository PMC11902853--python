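"""Shared configuration for the numbered analysis scripts.

One bundle directory under results/analysis holds every stage's outputs;
the scripts are thin drivers over the grangernet library and can be run
in order (01 -> 06) or replaced by `grangernet run-all`.
"""

from pathlib import Path

from grangernet.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def config() -> PipelineConfig:
    return PipelineConfig(out_dir=str(RESULTS), seed=1, order_mode="bic")
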