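"""Fusing ANC and CNA into high-confidence calls, and descriptive summaries.

An interaction is *high confidence* for a condition when it is a hit by both
independent statistical routes: the bead-distribution test (ANC) and the
correlation-network membership test (CNA).  This module also provides the
reporting quantities used alongside those calls: log2 fold changes between
condition groups, row-median-scaled matrices for heatmaps, per-module
activity summaries with one-way ANOVA and Bonferroni-corrected post hoc
tests, PCA sample coordinates, average-linkage sample dendrograms, and a
Cytoscape-compatible attributed edge list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway, ttest_ind

from .anc import ANCResult
from .cna import cna_hits
from .datatypes import MFIMatrix, SampleMetadata, ScaledMatrix, split_interaction
from .errors import ValidationError

_FLOAT_FORMAT = "%.10g"


@dataclass
class HighConfidenceSet:
    """Interactions called by both ANC and CNA for one contrast.

    ``table`` has one row per interaction: direction (sign of the shift),
    per-contrast log2FC, assigned module of interest, and evidence flags
    (both true by construction).
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    modules_of_interest: list[str]

    @property
    def interactions(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def intersect_hits(
    anc: ANCResult,
    membership: pd.DataFrame,
    module_trait: pd.DataFrame,
    hypothesis: str | list[str] | None = None,
    alpha: float = 0.05,
) -> HighConfidenceSet:
    """High-confidence set: ANC hits that are also CNA hits.

    CNA hits are interactions whose module-membership p-value is below
    ``alpha`` (with positive kME) in a module whose eigenvector correlates
    with the selected hypothesis (``p < alpha``).  ``hypothesis`` may be one
    trait name, several, or ``None`` for any trait.
    """
    cna_set, interest = cna_hits(membership, module_trait, hypothesis, alpha)
    anc_hits = set(anc.hits)
    members = sorted(anc_hits & cna_set)
    mem = membership[
        membership["interaction"].isin(members) & membership["module"].isin(interest)
    ]
    best_module = (
        mem.sort_values(["interaction", "kME"], ascending=[True, False])
        .groupby("interaction", sort=True)
        .first()["module"]
        if len(mem)
        else pd.Series(dtype=object)
    )
    sub = anc.table.loc[members]
    table = pd.DataFrame(
        {
            "direction": sub["modal_direction"].astype(int),
            "log2fc": sub["median_log2fc"],
            "module": best_module.reindex(members),
            "anc_hit": True,
            "cna_hit": True,
        },
        index=pd.Index(members, name="interaction"),
    )
    hcs = HighConfidenceSet(table=table, contrast=anc.contrast, modules_of_interest=interest)
    assert set(hcs.interactions) <= anc_hits and set(hcs.interactions) <= cna_set
    return hcs


def compute_log2fc(
    matrix: MFIMatrix,
    condition_a: str,
    condition_b: str,
    meta: SampleMetadata,
) -> pd.Series:
    """log2 of (mean MFI in condition_b) / (mean MFI in condition_a), per interaction."""
    if matrix.scale != "linear":
        raise ValidationError("compute_log2fc expects a linear-scale matrix")
    cond = meta.condition_of()
    groups = {}
    for c in (condition_a, condition_b):
        samples = [s for s in matrix.sample_ids if cond.get(s) == c]
        if not samples:
            raise ValidationError(f"condition {c!r} has no samples in the matrix")
        mean = matrix.values.loc[:, samples].mean(axis=1)
        if (mean <= 0).any():
            raise ValidationError(f"non-positive group mean in condition {c!r}")
        groups[c] = mean
    return np.log2(groups[condition_b] / groups[condition_a]).rename(
        f"log2fc_{condition_b}_vs_{condition_a}"
    )


def scale_by_row_median(matrix: MFIMatrix) -> ScaledMatrix:
    """Divide each interaction row by its across-sample median ("median scaled values").

    The result is unitless with per-row median exactly 1, making interactions
    comparable on heatmaps and in module-activity averages.
    """
    if matrix.scale != "linear":
        raise ValidationError("scale_by_row_median expects a linear-scale matrix")
    med = matrix.values.median(axis=1)
    if (med == 0).any():
        bad = list(med.index[med == 0])
        raise ValidationError(f"zero row median for interaction(s): {bad}")
    return ScaledMatrix(values=matrix.values.div(med, axis=0), row_medians=med)


@dataclass
class ModuleActivity:
    """Per-sample module activity with group statistics.

    ``activity`` is the mean scaled value of all module members per sample
    ("overall module behavior"); ``posthoc`` holds pairwise Welch t-tests
    with Bonferroni correction over the tested pairs.
    """

    activity: pd.Series
    anova_f: float
    anova_p: float
    posthoc: pd.DataFrame


def module_activity(
    scaled: ScaledMatrix,
    members: list[str],
    groups: pd.Series,
) -> ModuleActivity:
    """Mean scaled value of module members per sample, with ANOVA and post hoc tests.

    ``groups`` maps sample -> condition label.  Groups with fewer than two
    samples are excluded from the statistics with a warning.
    """
    if len(members) < 1:
        raise ValidationError("module_activity needs at least one member interaction")
    activity = scaled.values.loc[list(members)].mean(axis=0).rename("activity")
    groups = groups.reindex(activity.index)
    if groups.isna().any():
        raise ValidationError("group labels missing for some samples")
    arrays: dict[str, np.ndarray] = {}
    for g in list(dict.fromkeys(groups)):
        vals = activity[groups == g].to_numpy()
        if vals.size < 2:
            warnings.warn(
                f"group {g!r} has < 2 samples; excluded from statistics",
                UserWarning,
                stacklevel=2,
            )
            continue
        arrays[g] = vals
    if len(arrays) < 2:
        raise ValidationError("module_activity needs >= 2 groups with >= 2 samples")
    f_stat, p = f_oneway(*arrays.values())
    pairs = list(combinations(arrays, 2))
    rows = []
    for g1, g2 in pairs:
        res = ttest_ind(arrays[g1], arrays[g2], equal_var=False)
        rows.append(
            {
                "group_a": g1,
                "group_b": g2,
                "t": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_bonferroni": float(min(1.0, res.pvalue * len(pairs))),
            }
        )
    return ModuleActivity(
        activity=activity,
        anova_f=float(f_stat),
        anova_p=float(p),
        posthoc=pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p_raw", "p_bonferroni"]),
    )


def pca_coordinates(matrix: MFIMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA scores and explained-variance fractions.

    Interaction profiles are centered; sample scores come from the SVD of the
    centered samples x interactions matrix.  Score vectors are orthogonal and
    variance fractions sum to 1.  Component signs are fixed deterministically
    (largest-magnitude loading positive).
    """
    if matrix.shape[1] < 3:
        raise ValidationError("PCA needs at least 3 samples")
    X = matrix.values.to_numpy(dtype=float).T  # samples x interactions
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u * s
    total = float((s**2).sum())
    frac = s**2 / total if total > 0 else np.zeros_like(s)
    n_pc = scores.shape[1]
    cols = [f"PC{i + 1}" for i in range(n_pc)]
    return pd.DataFrame(scores, index=matrix.sample_ids, columns=cols), frac


@dataclass
class Dendrogram:
    """Sample dendrogram: SciPy linkage over lexicographically ordered samples."""

    sample_ids: list[str]
    merges: np.ndarray  # scipy linkage matrix

    def to_dict(self) -> dict:
        return {
            "samples": self.sample_ids,
            "merges": [
                {"left": int(a), "right": int(b), "height": float(h), "size": int(sz)}
                for a, b, h, sz in self.merges
            ],
        }


def hierarchical_cluster_samples(matrix: MFIMatrix) -> Dendrogram:
    """Average-linkage clustering of samples with correlation distance.

    Distance between samples is ``1 - Pearson`` over interaction profiles.
    Samples are ordered lexicographically before linkage so ties resolve
    deterministically.
    """
    if matrix.shape[1] < 3:
        raise ValidationError("sample clustering needs at least 3 samples")
    order = sorted(matrix.sample_ids)
    X = matrix.values.loc[:, order].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = order[int(np.flatnonzero(sd == 0)[0])]
        raise ValidationError(f"sample {bad!r} has a constant profile")
    corr = np.corrcoef(X.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(sample_ids=order, merges=z)


EDGE_COLUMNS = ("source", "target", "log2fc", "direction", "module", "is_abundance")


def export_edge_list(hcs: HighConfidenceSet, path: str | Path) -> None:
    """Write a Cytoscape-compatible attributed edge list (TSV).

    ``source`` is the IP target, ``target`` the probe target.  Self edges
    (IP = probe) are apparent-abundance proxies and flagged, not dropped.
    """
    rows = []
    for inter, row in hcs.table.iterrows():
        ip, probe = split_interaction(inter)
        rows.append(
            {
                "source": ip,
                "target": probe,
                "log2fc": row["log2fc"],
                "direction": int(np.sign(row["log2fc"])),
                "module": row["module"],
                "is_abundance": ip == probe,
            }
        )
    pd.DataFrame(rows, columns=list(EDGE_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FORMAT
    )


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Parse an edge list written by :func:`export_edge_list`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"edge list missing column(s): {missing}")
    return df
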