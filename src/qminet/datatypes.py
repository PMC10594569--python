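"""Core containers for quantitative multiplex co-immunoprecipitation (QMI) data.

A QMI experiment captures many protein targets on distinguishable Luminex bead
classes by immunoprecipitation (IP) and probes each captured complex with a
fluorescently labeled antibody.  The ordered pair ``IP_probe`` is the unit of
measurement, called an *interaction*; the bead-level fluorescence distribution
of one interaction in one well summarizes the abundance of the corresponding
binary protein complex.  Self pairs (IP and probe against the same protein,
e.g. ``AKT_AKT``) act as proxies for apparent protein abundance.

Containers here are thin, validating wrappers around :class:`pandas.DataFrame`:

* :class:`BeadEventTable` -- raw bead-level fluorescence events.
* :class:`SampleMetadata` -- sample -> replicate / condition / batch / pair map.
* :class:`MFIMatrix`      -- interactions x samples median-fluorescence matrix.
* :class:`TraitTable`     -- coded experimental hypotheses x samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

BEAD_COLUMNS = ("sample_id", "well_id", "batch_id", "ip", "probe", "fluorescence")
META_COLUMNS = (
    "sample_id",
    "biological_replicate_id",
    "condition",
    "batch_id",
    "technical_duplicate_index",
    "pair_key",
)

#: separator between IP and probe names in an interaction identifier
INTERACTION_SEP = "_"


def interaction_id(ip: str, probe: str) -> str:
    """Ordered-pair identifier ``IP_probe``. IP and probe roles are not symmetric."""
    return f"{ip}{INTERACTION_SEP}{probe}"


def split_interaction(interaction: str) -> tuple[str, str]:
    """Inverse of :func:`interaction_id`; splits on the first underscore."""
    ip, _, probe = interaction.partition(INTERACTION_SEP)
    return ip, probe


@dataclass
class BeadEventTable:
    """Bead-level fluorescence events, one row per bead read.

    Invariants enforced on construction: all required columns present, all
    fluorescence values finite and strictly positive, identifiers stripped of
    surrounding whitespace.  Event order is preserved.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in BEAD_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"bead event table missing column(s): {', '.join(missing)}")
        df = self.df.loc[:, list(BEAD_COLUMNS)].copy()
        for col in BEAD_COLUMNS[:-1]:
            df[col] = df[col].astype(str).str.strip()
        fl = pd.to_numeric(df["fluorescence"], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(fl) | (fl <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"non-positive or non-finite fluorescence at row {row} "
                f"(value {df['fluorescence'].iloc[row]!r})"
            )
        df["fluorescence"] = fl
        df.reset_index(drop=True, inplace=True)
        self.df = df

    @property
    def interaction(self) -> pd.Series:
        """Per-event interaction identifier ``IP_probe``."""
        return (self.df["ip"] + INTERACTION_SEP + self.df["probe"]).rename("interaction")

    def interaction_ids(self) -> list[str]:
        """Sorted unique interaction identifiers."""
        return sorted(self.interaction.unique())

    def sample_ids(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class SampleMetadata:
    """One row per sample: biological replicate, condition, batch, pair key.

    The matched design requires at most one sample per (biological replicate,
    condition); matched samples share ``pair_key``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"sample metadata missing column(s): {', '.join(missing)}")
        df = self.df.loc[:, list(META_COLUMNS)].copy()
        for col in META_COLUMNS:
            if col != "technical_duplicate_index":
                df[col] = df[col].astype(str).str.strip()
        df["technical_duplicate_index"] = pd.to_numeric(df["technical_duplicate_index"]).astype(int)
        if (df["technical_duplicate_index"] < 1).any():
            raise ValidationError("technical_duplicate_index must be >= 1")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r} in metadata")
        dup_pair = df.duplicated(subset=["biological_replicate_id", "condition"])
        if dup_pair.any():
            rep = df.loc[dup_pair, "biological_replicate_id"].iloc[0]
            raise ValidationError(
                f"matched design violated: biological replicate {rep!r} has more than "
                "one sample for the same condition"
            )
        df.reset_index(drop=True, inplace=True)
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        return list(dict.fromkeys(self.df["condition"]))

    def condition_of(self) -> pd.Series:
        return self.df.set_index("sample_id")["condition"]

    def batch_of(self) -> pd.Series:
        return self.df.set_index("sample_id")["batch_id"]

    def validate_against(self, beads: BeadEventTable) -> None:
        """Every sample in the bead table must appear exactly once in metadata."""
        bead_samples = set(beads.df["sample_id"].unique())
        meta_samples = set(self.df["sample_id"])
        missing = bead_samples - meta_samples
        if missing:
            raise ValidationError(f"samples in bead table without metadata: {sorted(missing)}")


@dataclass
class MFIMatrix:
    """Interactions x samples matrix of median fluorescent intensities.

    ``scale`` is ``"linear"`` (raw MFI, all entries > 0) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale flag {self.scale!r}")
        values = self.values.astype(float)
        arr = values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("MFI matrix contains missing or non-finite values")
        if self.scale == "linear" and (arr <= 0).any():
            i, j = np.argwhere(arr <= 0)[0]
            raise ValidationError(
                f"non-positive MFI for interaction {values.index[i]!r}, "
                f"sample {values.columns[j]!r} on linear scale"
            )
        if values.index.duplicated().any() or values.columns.duplicated().any():
            raise ValidationError("duplicate interaction or sample identifiers in MFI matrix")
        self.values = values

    @property
    def interaction_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "MFIMatrix":
        return MFIMatrix(self.values.copy(), self.scale)


@dataclass
class TraitTable:
    """Coded hypotheses x samples (binary 0/1 or ordinal numeric rows).

    Each row encodes one experimental hypothesis (e.g. "refed vs starved" as a
    0/1 indicator, or "time since refeeding" as an ordinal code) and must be
    non-constant across samples.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.astype(float)
        if not np.isfinite(df.to_numpy()).all():
            raise ValidationError("trait table contains missing or non-finite codes")
        const = df.nunique(axis=1) <= 1
        if const.any():
            name = df.index[const.to_numpy()][0]
            raise ValidationError(f"trait row {name!r} is constant across samples")
        self.df = df

    @property
    def hypotheses(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    def for_samples(self, sample_ids: list[str]) -> "TraitTable":
        missing = [s for s in sample_ids if s not in self.df.columns]
        if missing:
            raise ValidationError(f"trait table missing samples: {missing}")
        return TraitTable(self.df.loc[:, list(sample_ids)])


@dataclass
class ScaledMatrix:
    """Row-median-scaled MFI matrix: every row divided by its across-sample median.

    Stores the medians so scaling is invertible.  By construction every row of
    ``values`` has median exactly 1.
    """

    values: pd.DataFrame
    row_medians: pd.Series = field(repr=False, default=None)

    def unscale(self) -> pd.DataFrame:
        return self.values.mul(self.row_medians, axis=0)
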