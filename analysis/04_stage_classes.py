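"""Classify merged binding regions as shared or stage-specific.

Merges +/-2 kb summit windows across the two stages, extracts
library-normalized signal density, labels classes I/II/III with the
5-fold-over-background rescue rule, and scores the labels against the
generator's ground truth.  Writes results/stage_classes.tsv.
"""

import numpy as np
import pandas as pd

from zicreg.core import IntervalSet
from zicreg.peaks import filter_peaks
from zicreg.simulate import STAGE_A, STAGE_B, true_region_classes
from zicreg.stages import (
    class_counts,
    classify_stage_binding,
    estimate_background_density,
    merge_summit_windows,
)

from common import PIPELINE_SEED, RESULTS, study_dataset


def main():
    ds = study_dataset()
    pa, _ = filter_peaks(ds.peaks[STAGE_A], repeat_mask=ds.repeat_mask)
    pb, _ = filter_peaks(ds.peaks[STAGE_B], repeat_mask=ds.repeat_mask)
    regions = merge_summit_windows(pa, pb)
    exclude = IntervalSet((r.chrom, r.start, r.end) for r in regions)
    rng = np.random.default_rng(PIPELINE_SEED)
    bg_a = estimate_background_density(ds.signal[STAGE_A], exclude, ds.chrom_sizes, rng=rng)
    bg_b = estimate_background_density(ds.signal[STAGE_B], exclude, ds.chrom_sizes, rng=rng)
    classified = classify_stage_binding(
        regions, ds.signal[STAGE_A], ds.signal[STAGE_B], STAGE_A, STAGE_B,
        background_a=bg_a, background_b=bg_b,
    )
    counts = class_counts(classified)
    truth = true_region_classes(ds.manifest_peaks, regions)
    accuracy = float(
        np.mean([t == c.region_class for t, c in zip(truth, classified)])
    )
    table = pd.DataFrame(
        [
            dict(
                n_regions=len(regions),
                n_class_I=counts["I"],
                n_class_II=counts["II"],
                n_class_III=counts["III"],
                background_density_8hpf=round(bg_a, 3),
                background_density_24hpf=round(bg_b, 3),
                accuracy_vs_truth=round(accuracy, 4),
            )
        ]
    )
    table.to_csv(RESULTS / "stage_classes.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print("\nClass I regions are bound at both stages; II only early, III only")
    print(f"late.  Signal-based classification recovers {accuracy:.1%} of truth.")


if __name__ == "__main__":
    main()
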