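"""Shared setup for the analysis drivers.

Every driver regenerates the same deterministic synthetic study (seed 1,
default configuration: 10 Mb genome, 200 genes, 1000 peaks per stage) so
each script is self-contained and reproducible in isolation.
"""

from pathlib import Path

from zicreg.simulate import SimulationConfig, generate

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 1
PIPELINE_SEED = 2


def study_dataset():
    RESULTS.mkdir(exist_ok=True)
    return generate(SimulationConfig(seed=SEED))
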