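"""zicreg: integrative regulatory-genomics analysis of two-stage TF binding.

Turns ChIP-seq peak calls, expression perturbation tables and conservation
tracks into annotated distal-binding landscapes and direct-target-gene
calls, with a ground-truthed synthetic data generator for end-to-end
validation.
"""

from importlib import resources

from .core import (
    GeneAnnotation,
    GenomicInterval,
    IntervalSet,
    PeakCall,
    ValidationError,
)
from .motifs import Pwm
from .simulate import SimulationConfig, SyntheticDataset, generate
from .tracks import IdentityTrack, SignalTrack

__version__ = "0.1.0"


def zic3_consensus_pwm() -> Pwm:
    """The packaged CAGCAG-core Zic3 consensus PWM."""
    from .io import read_meme

    path = resources.files("zicreg.data") / "zic3_consensus.meme"
    return read_meme(path)[0]
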