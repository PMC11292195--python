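"""Filter a proteome matrix against the matrisome/adhesome catalog.

Builds a small abundance matrix of real gene symbols, restricts it to the
packaged catalog snapshot, and prints detection coverage per division.
"""

import numpy as np
import pandas as pd

from ecmnet.annotations import coverage_stats, filter_matrix, load_packaged_catalog
from ecmnet.cohort_io import AbundanceMatrix

rng = np.random.default_rng(0)
genes = ["COL1A1", "FN1", "DCN", "LUM", "CTSB", "MMP14", "LCP1", "TLN1",
         "ACTB", "GAPDH", "TUBB", "VIM"]          # last four are not ECM/adhesion
matrix = AbundanceMatrix(pd.DataFrame(
    rng.normal(20, 2, (len(genes), 4)), index=genes,
    columns=[f"patient{i}" for i in range(1, 5)]))

catalog = load_packaged_catalog()
filtered = filter_matrix(matrix, catalog)
print(f"kept {filtered.n_proteins}/{matrix.n_proteins} proteins: "
      f"{', '.join(filtered.protein_ids)}")

coverage = coverage_stats(matrix, catalog)
divisions = coverage[coverage.level == "division"]
print(divisions[["division", "n_detected", "n_catalog", "fraction"]].to_string(index=False))
# The fractions say how much of each catalog division this (tiny) proteome
# detects; on a real cohort they quantify matrisome/adhesome coverage.
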