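"""Adaptive nonparametric comparison with an empirical alpha cutoff (ANC).

ANC does not collapse bead distributions into a single summary.  For each
interaction and each matched pair of samples (control vs. treated from the
same biological replicate), the two pooled bead distributions are compared
with a two-sample Kolmogorov-Smirnov test.  The significance level is the
Bonferroni level for the panel, tightened further if within-sample
technical-duplicate comparisons -- true nulls available in every experiment --
show an inflated fraction of small p-values (the "empirical alpha").  An
interaction is a hit when strictly more than 70% of its matched-pair
comparisons are significant *and* agree on the direction of the median shift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kstwobign

from .datatypes import BeadEventTable, SampleMetadata
from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: strict consistency threshold: a hit changes in >70% of pairwise comparisons
CONSISTENCY_THRESHOLD = 0.70


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on bead fluorescence values.

    Returns ``(D, p)`` where ``D`` is the supremum absolute difference of the
    two empirical CDFs and ``p`` the asymptotic two-sided p-value from the
    Kolmogorov distribution at effective size ``n_e = |a||b|/(|a|+|b|)``,
    clamped to [0, 1].  Bead counts in this assay (>= 50 per well) put the
    test comfortably in the asymptotic regime.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("ks_two_sample requires at least two values per sample")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("ks_two_sample requires finite values")
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    pooled = np.concatenate([a_sorted, b_sorted])
    cdf_a = np.searchsorted(a_sorted, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b_sorted, pooled, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    if d == 0.0:
        return 0.0, 1.0
    n_e = a.size * b.size / (a.size + b.size)
    p = float(np.clip(kstwobign.sf(np.sqrt(n_e) * d), 0.0, 1.0))
    return d, p


def empirical_alpha(
    null_pvalues, n_interactions: int, base_alpha: float = 0.05
) -> float:
    """Multiple-comparison-corrected alpha, calibrated on null comparisons.

    Starts at the Bonferroni level ``alpha_B = base_alpha / n_interactions``.
    If the supplied null p-values (e.g. from duplicate-well vs. duplicate-well
    comparisons) exceed ``alpha_B`` more often than ``base_alpha`` of the
    time, the cutoff is lowered to the largest level at which the null
    exceedance fraction is at most ``base_alpha``, stepping through the
    sorted null p-values.  With no null p-values the Bonferroni level is
    returned unchanged.
    """
    if not (0.0 < base_alpha < 1.0):
        raise ParameterError(f"base_alpha must be in (0, 1), got {base_alpha}")
    if n_interactions < 1:
        raise ParameterError("n_interactions must be >= 1")
    alpha_b = base_alpha / n_interactions
    p = np.asarray(null_pvalues, dtype=float)
    if p.size == 0:
        return alpha_b
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        logger.warning("degenerate null p-values; falling back to Bonferroni level")
        return alpha_b
    if float(np.mean(p <= alpha_b)) <= base_alpha:
        return alpha_b
    candidates = np.unique(p[p <= alpha_b])
    fractions = np.searchsorted(np.sort(p), candidates, side="right") / p.size
    feasible = candidates[fractions <= base_alpha]
    if feasible.size:
        return float(feasible.max())
    # Even the smallest observed null p-value is exceeded too often; step just
    # below it (null fraction 0).  Zero p-values leave no such level.
    smallest = float(candidates.min())
    if smallest <= 0.0:
        logger.warning("null p-values degenerate at 0; falling back to Bonferroni level")
        return alpha_b
    return smallest / 2.0


@dataclass
class ANCResult:
    """Per-interaction ANC statistics for one contrast.

    ``table`` is indexed by interaction with columns ``n_pairs``,
    ``n_significant``, ``f_consistent``, ``modal_direction``, ``hit``,
    ``median_log2fc``, ``pvalues`` and ``directions`` (per-pair tuples).
    """

    table: pd.DataFrame
    alpha_used: float
    base_alpha: float
    contrast: tuple[str, str]
    n_comparisons: int
    n_interactions_tested: int
    n_null_comparisons: int

    @property
    def hits(self) -> list[str]:
        return list(self.table.index[self.table["hit"]])

    def to_frame(self) -> pd.DataFrame:
        """Flat, text-serializable view (per-pair p-values as a ';' list)."""
        out = self.table.copy()
        out["pvalues"] = out["pvalues"].map(lambda ps: ";".join(f"{p:.6g}" for p in ps))
        out["directions"] = out["directions"].map(lambda ds: ";".join(f"{d:+d}" for d in ds))
        out.insert(0, "alpha_used", self.alpha_used)
        out.index.name = "interaction"
        return out


def _pooled_beads(work: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    """(interaction, sample) -> pooled fluorescence array (all wells)."""
    groups = work.groupby(["interaction", "sample_id"], sort=True)["fluorescence"]
    return {key: g.to_numpy() for key, g in groups}


def _well_beads(work: pd.DataFrame) -> dict[tuple[str, str], list[np.ndarray]]:
    """(interaction, sample) -> per-well fluorescence arrays, wells in id order."""
    out: dict[tuple[str, str], list[np.ndarray]] = {}
    for (inter, sid, _wid), g in work.groupby(
        ["interaction", "sample_id", "well_id"], sort=True
    )["fluorescence"]:
        out.setdefault((inter, sid), []).append(g.to_numpy())
    return out


def _sample_mfi(well_arrays: list[np.ndarray]) -> float:
    """MFI of a sample: mean of its technical-duplicate well medians."""
    return float(np.mean([np.median(w) for w in well_arrays]))


def anc_test(
    beads: BeadEventTable,
    meta: SampleMetadata,
    contrast: tuple[str, str],
    *,
    base_alpha: float = 0.05,
    consistency_threshold: float = CONSISTENCY_THRESHOLD,
    interactions: list[str] | None = None,
) -> ANCResult:
    """Run ANC for one condition contrast over all matched pairs.

    Parameters
    ----------
    contrast:
        ``(control, treated)`` condition labels; pairs are matched by
        ``pair_key``.  A pair missing one side is skipped with a warning.
    interactions:
        Optional restriction of the tested panel (e.g. after the low-MFI
        noise filter).  The multiple-comparison correction uses the size of
        the tested panel.
    """
    control, treated = contrast
    meta.validate_against(beads)
    present = set(meta.df["condition"])
    for cond in contrast:
        if cond not in present:
            raise ValidationError(f"contrast condition {cond!r} absent from metadata")

    pairs: list[tuple[str, str, str]] = []  # (pair_key, control sample, treated sample)
    for key, sub in meta.df.groupby("pair_key", sort=True):
        ctrl = sub.loc[sub["condition"] == control, "sample_id"]
        trt = sub.loc[sub["condition"] == treated, "sample_id"]
        if len(ctrl) == 1 and len(trt) == 1:
            pairs.append((key, ctrl.iloc[0], trt.iloc[0]))
        elif len(ctrl) + len(trt) == 1:
            warnings.warn(
                f"pair {key!r} missing one side of contrast {control}:{treated}; skipped",
                UserWarning,
                stacklevel=2,
            )
    if len(pairs) < 2:
        raise ValidationError(
            f"need >= 2 matched pairs for contrast {control}:{treated}, found {len(pairs)}"
        )

    df = beads.df
    work = pd.DataFrame(
        {
            "interaction": beads.interaction,
            "sample_id": df["sample_id"],
            "well_id": df["well_id"],
            "fluorescence": df["fluorescence"],
        }
    )
    contrast_samples = [s for _, c, t in pairs for s in (c, t)]
    work = work[work["sample_id"].isin(contrast_samples)]
    if interactions is not None:
        work = work[work["interaction"].isin(set(interactions))]
        tested = sorted(set(interactions) & set(work["interaction"].unique()))
    else:
        tested = sorted(work["interaction"].unique())
    if not tested:
        raise ValidationError("no interactions to test")

    by_well = _well_beads(work)
    pooled = {key: np.concatenate(wells) for key, wells in by_well.items()}

    # Null comparisons: technical duplicate wells of the same sample.
    null_ps: list[float] = []
    for inter in tested:
        for sid in contrast_samples:
            wells = by_well.get((inter, sid), [])
            if len(wells) >= 2 and all(w.size >= 2 for w in wells[:2]):
                null_ps.append(ks_two_sample(wells[0], wells[1])[1])
    alpha_star = empirical_alpha(null_ps, len(tested), base_alpha)

    rows = []
    for inter in tested:
        pvals: list[float] = []
        dirs: list[int] = []
        log2fcs: list[float] = []
        for _key, sid_c, sid_t in pairs:
            a = pooled.get((inter, sid_c))
            b = pooled.get((inter, sid_t))
            if a is None or b is None or a.size < 2 or b.size < 2:
                warnings.warn(
                    f"interaction {inter!r} missing beads in pair {_key!r}; comparison skipped",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            _d, p = ks_two_sample(a, b)
            pvals.append(p)
            dirs.append(int(np.sign(np.median(b) - np.median(a))))
            log2fcs.append(
                float(
                    np.log2(
                        _sample_mfi(by_well[(inter, sid_t)])
                        / _sample_mfi(by_well[(inter, sid_c)])
                    )
                )
            )
        n_pairs = len(pvals)
        sig = [d for p, d in zip(pvals, dirs) if p <= alpha_star]
        n_sig = len(sig)
        median_fc = float(np.median(log2fcs)) if log2fcs else np.nan
        if sig:
            counts = {d: sig.count(d) for d in set(sig)}
            best = max(counts.values())
            # deterministic tie-break: prefer the direction of the median log2FC
            fc_dir = int(np.sign(median_fc)) if np.isfinite(median_fc) else 1
            modal = max(
                sorted(counts),
                key=lambda d: (counts[d], d == fc_dir, d),
            )
            f_consistent = best / n_pairs if n_pairs else 0.0
        else:
            modal = 0
            f_consistent = 0.0
        hit = bool(n_pairs > 0 and f_consistent > consistency_threshold)
        rows.append(
            {
                "interaction": inter,
                "n_pairs": n_pairs,
                "n_significant": n_sig,
                "f_consistent": f_consistent,
                "modal_direction": modal,
                "hit": hit,
                "median_log2fc": median_fc,
                "pvalues": tuple(pvals),
                "directions": tuple(dirs),
            }
        )
    table = pd.DataFrame(rows).set_index("interaction")
    return ANCResult(
        table=table,
        alpha_used=alpha_star,
        base_alpha=base_alpha,
        contrast=(control, treated),
        n_comparisons=len(pairs),
        n_interactions_tested=len(tested),
        n_null_comparisons=len(null_ps),
    )
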