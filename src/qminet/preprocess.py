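"""From bead distributions to the analysis-ready MFI matrix.

The pipeline order mirrors standard QMI practice: collapse each well's bead
distribution to its median (the MFI), average technical-duplicate wells on the
linear scale, remove interactions whose typical signal is below the noise
floor (MFI < 100), then log2-transform for clustering and batch correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import BeadEventTable, MFIMatrix, SampleMetadata
from .errors import ParameterError, ValidationError

#: instrument noise floor in MFI units; interactions below it carry no signal
DEFAULT_MFI_THRESHOLD = 100.0


def collapse_to_mfi(
    beads: BeadEventTable,
    meta: SampleMetadata,
    on_missing: str = "drop",
) -> MFIMatrix:
    """Collapse bead distributions into a single MFI per (interaction, sample).

    Per (interaction, well) the median bead fluorescence is taken; per
    (interaction, sample) the arithmetic mean of its technical-duplicate well
    medians.  Output columns follow metadata sample order; rows are sorted
    interaction identifiers.

    Parameters
    ----------
    on_missing:
        ``"drop"`` (default) removes interactions absent in some sample;
        ``"error"`` raises instead.
    """
    if on_missing not in ("drop", "error"):
        raise ParameterError(f"on_missing must be 'drop' or 'error', got {on_missing!r}")
    meta.validate_against(beads)
    df = beads.df
    work = pd.DataFrame(
        {
            "interaction": beads.interaction,
            "sample_id": df["sample_id"],
            "well_id": df["well_id"],
            "fluorescence": df["fluorescence"],
        }
    )
    well_median = work.groupby(["interaction", "sample_id", "well_id"], sort=True)[
        "fluorescence"
    ].median()
    sample_mfi = well_median.groupby(level=["interaction", "sample_id"]).mean()
    mat = sample_mfi.unstack("sample_id")
    mat = mat.reindex(columns=meta.sample_ids)
    incomplete = mat.isna().any(axis=1)
    if incomplete.any():
        if on_missing == "error":
            missing = list(mat.index[incomplete])
            raise ValidationError(f"interactions absent in some sample: {missing}")
        mat = mat.loc[~incomplete]
    mat = mat.sort_index()
    return MFIMatrix(mat, "linear")


def filter_low_mfi(
    matrix: MFIMatrix, threshold: float = DEFAULT_MFI_THRESHOLD
) -> tuple[MFIMatrix, list[str]]:
    """Remove interactions whose median MFI across all samples is below ``threshold``.

    Keys on the per-interaction median over samples (the pipeline's robust
    summary).  Returns the filtered matrix and the removed interaction ids.
    Idempotent; the sample set is unchanged.
    """
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    if matrix.scale != "linear":
        raise ValidationError("filter_low_mfi expects a linear-scale MFI matrix")
    med = matrix.values.median(axis=1)
    keep = med >= threshold
    removed = list(matrix.values.index[~keep])
    return MFIMatrix(matrix.values.loc[keep], "linear"), removed


def log2_transform(matrix: MFIMatrix) -> MFIMatrix:
    """Element-wise log2; requires a linear-scale matrix with positive entries."""
    if matrix.scale != "linear":
        raise ValidationError("log2_transform expects a linear-scale MFI matrix")
    arr = matrix.values.to_numpy()
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValidationError(
            f"cannot log2-transform non-positive value for interaction "
            f"{matrix.values.index[i]!r}, sample {matrix.values.columns[j]!r}"
        )
    return MFIMatrix(np.log2(matrix.values), "log2")
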