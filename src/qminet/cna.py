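"""Weighted correlation network analysis (CNA) over QMI interactions.

Treats each interaction's profile across samples as a node, builds an
unsigned soft-thresholded correlation network ``a_ij = |cor(x_i, x_j)|**beta``
with the power ``beta`` chosen for approximate scale-free topology, converts
it to a topological overlap matrix (TOM), groups interactions into modules by
average-linkage clustering of TOM dissimilarity with a static tree cut,
summarizes each module by its eigenvector (first principal component of the
standardized member profiles), and tests module eigenvectors against coded
experimental hypotheses and individual interactions for module membership
(kME).

Modules are named by the conventional arbitrary color sequence in decreasing
size order; "grey" collects unassigned interactions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as student_t

from .datatypes import MFIMatrix, TraitTable
from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: module color names, assigned in decreasing module-size order
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white",
)
GREY = "grey"
DEFAULT_BETA = 6


@dataclass
class CorrelationNetwork:
    """Soft-thresholded adjacency with node connectivity.

    ``adjacency`` is symmetric with entries in [0, 1]; the diagonal is 1 by
    convention but excluded from connectivity ``k``.
    """

    interaction_ids: list[str]
    beta: int
    adjacency: pd.DataFrame

    @property
    def connectivity(self) -> pd.Series:
        a = self.adjacency.to_numpy()
        return pd.Series(a.sum(axis=1) - np.diag(a), index=self.interaction_ids, name="k")


@dataclass
class ModuleSet:
    """Interaction -> module color assignment with per-module eigenvectors."""

    labels: pd.Series  # interaction -> color (GREY = unassigned)
    eigenvectors: pd.DataFrame  # samples x module colors, unit-norm columns

    @property
    def module_names(self) -> list[str]:
        return list(self.eigenvectors.columns)

    @property
    def sizes(self) -> dict[str, int]:
        counts = self.labels.value_counts()
        return {m: int(counts.get(m, 0)) for m in self.module_names}

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _interaction_correlations(values: pd.DataFrame) -> np.ndarray:
    """Pearson correlations between interaction profiles; constant rows -> 0."""
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant interaction profile(s); correlations set to 0",
            UserWarning,
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[np.isnan(corr)] = 0.0
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivity values are discretized into ``n_bins`` equal-width bins (the
    convention of the weighted network literature; equal-count bins would
    flatten the frequency axis by construction); the log10 frequency per bin
    is regressed on the mean log10 connectivity.  Returns
    ``-sign(slope) * R^2`` (positive when the fit is scale-free-like, i.e.
    frequency decreasing in connectivity), or NaN when degenerate.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or np.isclose(k.min(), k.max()):
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, edges.size - 2)
    log_k, log_f = [], []
    for b in range(edges.size - 1):
        sel = which == b
        if sel.sum() == 0:
            continue
        log_k.append(np.log10(k[sel].mean()))
        log_f.append(np.log10(sel.mean()))
    if len(log_k) < 3:
        return float("nan")
    log_k = np.asarray(log_k)
    log_f = np.asarray(log_f)
    if np.isclose(log_k.var(), 0.0):
        return float("nan")
    slope, intercept = np.polyfit(log_k, log_f, 1)
    pred = slope * log_k + intercept
    ss_res = float(((log_f - pred) ** 2).sum())
    ss_tot = float(((log_f - log_f.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    matrix: MFIMatrix,
    candidate_powers: range | tuple[int, ...] = range(1, 21),
    fit_threshold: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power by approximate scale-free topology.

    Returns the smallest candidate power whose signed fit reaches
    ``fit_threshold``, or the power maximizing the fit; the full fit table
    (power, fit, mean/max connectivity) is returned alongside and logged.

    Powers that leave the network with mean connectivity below 1 (fewer than
    one effective neighbor per node) are ineligible: the degree distribution
    of a near-empty network fits a power law spuriously well, which would
    otherwise drive the selection toward arbitrarily large powers.
    """
    if matrix.shape[1] < 8 or matrix.shape[0] < 10:
        raise ValidationError("soft-threshold selection needs >= 10 interactions and >= 8 samples")
    corr = np.abs(_interaction_correlations(matrix.values))
    rows = []
    for beta in candidate_powers:
        a = corr**beta
        k = a.sum(axis=1) - 1.0  # diagonal contributes corr**beta = 1
        rows.append(
            {
                "power": int(beta),
                "fit": scale_free_fit(k),
                "mean_k": float(k.mean()),
                "max_k": float(k.max()),
            }
        )
    fit_table = pd.DataFrame(rows).set_index("power")
    logger.info("scale-free fit table:\n%s", fit_table.to_string())
    eligible = fit_table[fit_table["mean_k"] >= 1.0]["fit"].dropna()
    if eligible.empty:
        warnings.warn(
            f"scale-free fit undefined or network empty for all candidate powers; "
            f"using default beta = {DEFAULT_BETA}",
            UserWarning,
            stacklevel=2,
        )
        return DEFAULT_BETA, fit_table
    reaching = eligible.index[eligible >= fit_threshold]
    beta = int(reaching.min()) if len(reaching) else int(eligible.idxmax())
    return beta, fit_table


def compute_adjacency(matrix: MFIMatrix, beta: int) -> CorrelationNetwork:
    """Unsigned power adjacency ``a_ij = |cor(x_i, x_j)|**beta``."""
    if beta < 1:
        raise ParameterError(f"soft power must be >= 1, got {beta}")
    corr = _interaction_correlations(matrix.values)
    a = np.abs(corr) ** beta
    np.fill_diagonal(a, 1.0)
    ids = matrix.interaction_ids
    return CorrelationNetwork(
        interaction_ids=ids,
        beta=int(beta),
        adjacency=pd.DataFrame(a, index=ids, columns=ids),
    )


def compute_tom(network: CorrelationNetwork) -> pd.DataFrame:
    """Topological overlap matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_{u != i,j} a_iu a_uj``; the diagonal is defined as 1.
    Symmetric with entries in [0, 1]; two nodes overlap fully when they share
    all their neighbors (a complete unit-weight graph has TOM = 1 everywhere).
    """
    a = network.adjacency.to_numpy(dtype=float).copy()
    a = (a + a.T) / 2.0  # enforce symmetry against round-off
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    tom = (l + a0) / np.maximum(denom, 1e-12)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    ids = network.interaction_ids
    return pd.DataFrame(tom, index=ids, columns=ids)


def module_eigenvector(matrix: MFIMatrix, members: list[str]) -> pd.Series:
    """First principal component of the members' standardized profiles.

    Each member profile is z-scored across samples; the eigenvector is the
    first right singular vector of the members x samples matrix, unit norm,
    sign-oriented so its mean correlation with member profiles is positive
    (ties broken toward a positive first coordinate).
    """
    if len(members) < 1:
        raise ParameterError("module_eigenvector needs at least one member")
    if matrix.shape[1] < 3:
        raise ValidationError("module_eigenvector needs at least 3 samples")
    sub = matrix.values.loc[list(members)]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        dropped = list(sub.index[sd == 0])
        warnings.warn(
            f"constant member profile(s) dropped from eigenvector: {dropped}",
            UserWarning,
            stacklevel=2,
        )
        sub = sub.loc[sd > 0]
        if sub.empty:
            raise ValidationError("all member profiles constant; eigenvector undefined")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    _u, _s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    v = vt[0]
    corr_sum = float((z.to_numpy() @ v).sum())  # z rows have zero mean, so this signs mean cor
    if corr_sum < 0:
        v = -v
    elif corr_sum == 0:
        nz = np.flatnonzero(v)
        if nz.size and v[nz[0]] < 0:
            v = -v
    return pd.Series(v, index=matrix.sample_ids, name="eigenvector")


def detect_modules(
    tom: pd.DataFrame,
    matrix: MFIMatrix,
    min_size: int = 5,
    cut_height_fraction: float = 0.9,
) -> ModuleSet:
    """Average-linkage clustering of TOM dissimilarity with a static cut.

    The tree of ``1 - TOM`` is cut at ``cut_height_fraction`` times the
    maximum merge height; clusters smaller than ``min_size`` become "grey".
    Remaining clusters are named by decreasing size with the standard color
    sequence (ties broken by first member position) and given eigenvectors.
    """
    if min_size < 2:
        raise ParameterError(f"min_size must be >= 2, got {min_size}")
    ids = list(tom.index)
    n = len(ids)
    labels = pd.Series(GREY, index=ids, name="module")
    if n >= min_size and n >= 2:
        dissim = 1.0 - tom.to_numpy(dtype=float)
        np.fill_diagonal(dissim, 0.0)
        z = linkage(squareform(dissim, checks=False), method="average")
        # the 1e-12 guard keeps numerically-zero trees (identical profiles) whole
        height = cut_height_fraction * float(z[:, 2].max()) + 1e-12 if len(z) else 0.0
        cl = fcluster(z, t=height, criterion="distance")
        order: list[tuple[int, int, int]] = []  # (-size, first member position, cluster id)
        for cid in np.unique(cl):
            members = np.flatnonzero(cl == cid)
            if members.size >= min_size:
                order.append((-members.size, int(members[0]), int(cid)))
        order.sort()
        for rank, (_neg, _first, cid) in enumerate(order):
            color = (
                COLOR_SEQUENCE[rank]
                if rank < len(COLOR_SEQUENCE)
                else f"module{rank + 1}"
            )
            labels.iloc[np.flatnonzero(cl == cid)] = color
    eig = {}
    for color in labels.unique():
        if color == GREY:
            continue
        eig[color] = module_eigenvector(matrix, list(labels.index[labels == color]))
    colors_by_rank = [c for c in list(COLOR_SEQUENCE) + sorted(set(eig) - set(COLOR_SEQUENCE)) if c in eig]
    eigvec = (
        pd.DataFrame({c: eig[c] for c in colors_by_rank})
        if eig
        else pd.DataFrame(index=matrix.sample_ids)
    )
    return ModuleSet(labels=labels, eigenvectors=eigvec)


def correlation_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the t transform.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` against Student's t with n - 2
    degrees of freedom; ``|r| = 1`` maps to p = 0.
    """
    if n < 3:
        raise ParameterError("correlation p-value needs n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t_stat = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * student_t.sf(abs(t_stat), df=n - 2))


def module_trait_correlation(modules: ModuleSet, traits: TraitTable) -> pd.DataFrame:
    """Pearson r and two-sided p between each module eigenvector and each trait row."""
    samples = list(modules.eigenvectors.index)
    tr = traits.for_samples(samples).df
    n = len(samples)
    if n < 4:
        raise ValidationError("module-trait correlation needs >= 4 samples")
    rows = []
    for module in modules.module_names:
        ev = modules.eigenvectors[module].to_numpy()
        for hyp in tr.index:
            r = float(np.corrcoef(ev, tr.loc[hyp].to_numpy())[0, 1])
            rows.append(
                {"module": module, "hypothesis": hyp, "r": r, "p": correlation_p(r, n)}
            )
    return pd.DataFrame(rows, columns=["module", "hypothesis", "r", "p"])


def module_membership(
    matrix: MFIMatrix,
    modules: ModuleSet,
    modules_of_interest: list[str] | None = None,
) -> pd.DataFrame:
    """kME table: correlation of each interaction profile with module eigenvectors.

    Returns one row per (interaction, module) with Pearson kME and its
    two-sided p-value.  ``modules_of_interest`` restricts the module columns.
    """
    names = modules_of_interest if modules_of_interest is not None else modules.module_names
    unknown = set(names) - set(modules.module_names)
    if unknown:
        raise ParameterError(f"unknown module(s): {sorted(unknown)}")
    samples = list(modules.eigenvectors.index)
    X = matrix.values.loc[:, samples].to_numpy(dtype=float)
    n = len(samples)
    rows = []
    for module in names:
        ev = modules.eigenvectors[module].to_numpy()
        evc = ev - ev.mean()
        ev_ss = float(np.sqrt((evc**2).sum()))
        Xc = X - X.mean(axis=1, keepdims=True)
        x_ss = np.sqrt((Xc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            kme = (Xc @ evc) / (x_ss * ev_ss)
        kme = np.clip(np.nan_to_num(kme, nan=0.0), -1.0, 1.0)
        for i, inter in enumerate(matrix.interaction_ids):
            rows.append(
                {
                    "interaction": inter,
                    "module": module,
                    "kME": float(kme[i]),
                    "p": correlation_p(float(kme[i]), n),
                }
            )
    return pd.DataFrame(rows, columns=["interaction", "module", "kME", "p"])


def cna_hits(
    membership: pd.DataFrame,
    module_trait: pd.DataFrame,
    hypothesis: str | list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[set[str], list[str]]:
    """CNA hit set: interactions significantly and positively correlated with a
    module of interest.

    Modules of interest are those whose eigenvector-trait correlation has
    ``p < alpha`` for the selected hypothesis (a name, a list of names, or
    ``None`` for any trait).  Returns (hit set, modules of interest).
    """
    hyps = list(module_trait["hypothesis"].unique())
    if hypothesis is None:
        selected = hyps
    else:
        selected = [hypothesis] if isinstance(hypothesis, str) else list(hypothesis)
        missing = set(selected) - set(hyps)
        if missing:
            raise ValidationError(f"hypothesis not in trait table: {sorted(missing)}")
    mt = module_trait[module_trait["hypothesis"].isin(selected)]
    interest = sorted(mt.loc[mt["p"] < alpha, "module"].unique())
    mem = membership[membership["module"].isin(interest)]
    hit = mem[(mem["p"] < alpha) & (mem["kME"] > 0)]
    return set(hit["interaction"]), interest
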