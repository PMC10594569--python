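"""Reading and writing the package's plain-text interchange formats.

All formats are UTF-8 text with "." decimal separators:

* bead events  -- CSV ``sample_id,well_id,batch_id,ip,probe,fluorescence``
* metadata     -- CSV ``sample_id,biological_replicate_id,condition,batch_id,
  technical_duplicate_index,pair_key``
* traits       -- CSV, first column the hypothesis name, one column per sample
* MFI matrix   -- TSV, interactions (``IP_probe``) as rows, samples as columns

Vendor binary exports (xPONENT / Bio-Plex native files) are out of scope; use
the instrument software's CSV export.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import BeadEventTable, MFIMatrix, SampleMetadata, TraitTable
from .errors import FormatError

_FLOAT_FORMAT = "%.10g"


def load_bead_events(path: str | Path) -> BeadEventTable:
    """Load a bead-level event CSV; validates columns and fluorescence values."""
    df = pd.read_csv(path, dtype={"sample_id": str, "well_id": str, "batch_id": str,
                                  "ip": str, "probe": str})
    return BeadEventTable(df)


def write_bead_events(table: BeadEventTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def load_sample_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, dtype=str)
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.df.to_csv(path, index=False)


def load_trait_table(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise FormatError("trait table has no sample columns")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return TraitTable(df)


def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    out = traits.df.copy()
    out.index.name = "hypothesis"
    out.to_csv(path, float_format=_FLOAT_FORMAT)


def load_mfi_matrix(path: str | Path, scale: str = "linear") -> MFIMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return MFIMatrix(df, scale)


def write_mfi_matrix(matrix: MFIMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "interaction"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


def load_experiment(
    beads_path: str | Path,
    metadata_path: str | Path,
    traits_path: str | Path | None = None,
) -> tuple[BeadEventTable, SampleMetadata, TraitTable | None]:
    """Load bead events with companion metadata (and optionally traits).

    Cross-validates that every sample in the bead table has metadata.
    """
    beads = load_bead_events(beads_path)
    meta = load_sample_metadata(metadata_path)
    meta.validate_against(beads)
    traits = load_trait_table(traits_path) if traits_path is not None else None
    return beads, meta, traits
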