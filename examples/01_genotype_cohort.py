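"""Classify 9p21.3 copy states and stratify a cohort.

Builds a tiny copy-call table by hand, assigns each sample a 9p21 group,
and shows the expression surrogate on a simulated cohort.
"""

import pandas as pd

from ninep21.genotyping import genotype_cohort, surrogate_from_expression
from ninep21.io import CopyCallTable
from ninep21.simulate import SimulationConfig, generate_cohort

# thresholded calls: -2 homozygous deletion, -1 hemizygous loss, 0 diploid
calls = CopyCallTable(pd.DataFrame(
    {"P1": [-2, -2], "P2": [-1, -1], "P3": [0, 0], "P4": [-1, 0]},
    index=["CDKN2A", "MTAP"],
))
labels = genotype_cohort(calls)
print(labels)
# P1 has HD of both genes -> LOSS; P2 LOH at both -> LOH; P3 diploid -> WT;
# P4 single-locus LOH matches none of the named groups -> OTHER (excluded
# from WT-vs-LOSS contrasts explicitly, never silently).

cohort = generate_cohort(SimulationConfig(n_samples=200, seed=1))
surrogate = surrogate_from_expression(cohort.expression)
print(surrogate.value_counts())
# hi_hi = both CDKN2A and MTAP above their cohort medians (9p21-intact
# surrogate); lo_lo = both below (deletion surrogate); the rest are mixed.
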