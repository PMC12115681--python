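"""Convenience composition: phantom cohort -> feature maps, in memory.

Glues the stages together for studies that do not need intermediate files
on disk (simulation experiments, calibration runs, examples). The
file-based route — ``make_cohort`` + ``preprocess_volume`` +
``build_feature_map`` — produces identical numbers; this one just skips
the NIfTI round trip.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import Extractor, build_feature_map
from .phenotype import derive_ld_or_odd
from .synthetic import PhantomSpec, cohort_table, make_phantom_volume
from .volume import preprocess_array

__all__ = ["feature_cohort"]


def feature_cohort(spec: PhantomSpec, extractor: Extractor
                   ) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Run the full pipeline over a phantom cohort without touching disk.

    Returns ``(X, attrs, y)``: the (N, slices, features) feature-map
    stack, the raw attribute table the training harness expects (age,
    gender, handedness, full4_iq, ld_or_odd), and the binary labels.
    Rows the demographic filters would reject are excluded first, exactly
    as the file-based route would after ``pheno-prep``.
    """
    table = cohort_table(spec)
    # replicate the CSV-route filters on the in-memory table
    ok = ((table["QC_Athena"].astype(float) + table["QC_NIAK"].astype(float) > 0)
          & table["DX"].isin([0, 1, 2, 3]) & table["Full4_IQ"].notna())
    table = table[ok].reset_index(drop=True)

    maps = []
    for _, row in table.iterrows():
        vol = make_phantom_volume(int(row.true_class), spec, int(row.subject_seed),
                                  n_slices=int(row.native_slices))
        stack = preprocess_array(vol, source_id=str(row.Subject_ID))
        maps.append(build_feature_map(extractor, stack).matrix)
    X = np.stack(maps)
    attrs = pd.DataFrame(dict(
        age=table["Age"].astype(float),
        gender=table["Gender"].astype(float),
        handedness=table["Handedness"].astype(float),
        full4_iq=table["Full4_IQ"].astype(float),
        ld_or_odd=[derive_ld_or_odd(s) for s in table["Secondary_DX"]],
    ))
    y = (table["DX"].astype(int) > 0).astype(int).to_numpy()
    return X, attrs, y
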