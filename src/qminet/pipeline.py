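"""End-to-end orchestration: beads -> MFI -> [ANC] + [CNA] -> high-confidence calls.

The pipeline executes the analysis sequence in its canonical order:
load or simulate bead events, collapse to MFI, remove the low-MFI noise
floor, run ANC on the bead distributions for each contrast, and in parallel
log2-transform, batch-correct and run CNA on the MFI matrix; finally
intersect the two hit lists per contrast, attach log2 fold changes, and write
all artifacts plus a machine-readable JSON report.  Given the same
configuration and seed, every artifact is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .anc import ANCResult, anc_test
from .batch import empirical_bayes_batch_correct
from .cna import (
    ModuleSet,
    compute_adjacency,
    compute_tom,
    detect_modules,
    module_membership,
    module_trait_correlation,
    pick_soft_threshold,
)
from .datatypes import BeadEventTable, MFIMatrix, SampleMetadata, TraitTable
from .errors import PipelineError, ValidationError
from .io import load_experiment, write_mfi_matrix
from .preprocess import DEFAULT_MFI_THRESHOLD, collapse_to_mfi, filter_low_mfi, log2_transform
from .report import (
    HighConfidenceSet,
    compute_log2fc,
    export_edge_list,
    hierarchical_cluster_samples,
    intersect_hits,
    module_activity,
    pca_coordinates,
    scale_by_row_median,
)
from .simulate import SimulationConfig, SimulationTruth, simulate_experiment

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, contrasts and thresholds for one pipeline run.

    Provide either ``simulation`` or the three input paths.  ``hypotheses``
    selects the traits defining modules of interest (None = any trait).
    """

    simulation: SimulationConfig | None = None
    beads_path: str | None = None
    metadata_path: str | None = None
    traits_path: str | None = None
    contrasts: tuple[tuple[str, str], ...] = ()
    hypotheses: tuple[str, ...] | None = None
    mfi_threshold: float = DEFAULT_MFI_THRESHOLD
    base_alpha: float = 0.05
    trait_alpha: float = 0.05
    membership_alpha: float = 0.05
    min_module_size: int = 5
    cut_height_fraction: float = 0.9
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))

    def __post_init__(self) -> None:
        if self.simulation is None and (self.beads_path is None or self.metadata_path is None):
            raise ValidationError("config needs either a simulation spec or input paths")
        if not self.contrasts:
            raise ValidationError("config needs at least one (control, treated) contrast")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "simulation": None,
            "beads_path": self.beads_path,
            "metadata_path": self.metadata_path,
            "traits_path": self.traits_path,
            "contrasts": [list(c) for c in self.contrasts],
            "hypotheses": list(self.hypotheses) if self.hypotheses is not None else None,
            "mfi_threshold": self.mfi_threshold,
            "base_alpha": self.base_alpha,
            "trait_alpha": self.trait_alpha,
            "membership_alpha": self.membership_alpha,
            "min_module_size": self.min_module_size,
            "cut_height_fraction": self.cut_height_fraction,
            "candidate_powers": list(self.candidate_powers),
        }
        if self.simulation is not None:
            from dataclasses import asdict

            payload["simulation"] = asdict(self.simulation)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        sim = payload.pop("simulation", None)
        if sim is not None:
            from .simulate import PlantedModule

            sim = SimulationConfig(
                **{
                    **sim,
                    "conditions": tuple(sim["conditions"]),
                    "beads_per_well": tuple(sim["beads_per_well"]),
                    "baseline_mfi_range": tuple(sim["baseline_mfi_range"]),
                    "planted_modules": tuple(
                        PlantedModule(m["name"], tuple(m["members"]), dict(m["effects"]))
                        for m in sim.get("planted_modules", ())
                    ),
                }
            )
        payload["contrasts"] = tuple(tuple(c) for c in payload.get("contrasts", ()))
        if payload.get("hypotheses") is not None:
            payload["hypotheses"] = tuple(payload["hypotheses"])
        if payload.get("candidate_powers") is not None:
            payload["candidate_powers"] = tuple(payload["candidate_powers"])
        return cls(simulation=sim, **payload)


@dataclass
class PipelineResult:
    """Everything a run computed, for programmatic use; artifacts live on disk."""

    config: PipelineConfig
    beads: BeadEventTable
    meta: SampleMetadata
    traits: TraitTable | None
    truth: SimulationTruth | None
    mfi: MFIMatrix
    removed_low_mfi: list[str]
    corrected: MFIMatrix
    soft_power: int
    fit_table: pd.DataFrame
    modules: ModuleSet
    module_trait: pd.DataFrame | None
    membership: pd.DataFrame
    anc_results: dict[tuple[str, str], ANCResult]
    high_confidence: dict[tuple[str, str], HighConfidenceSet]
    report: dict = field(repr=False, default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %-18s %.2fs", name, time.perf_counter() - t0)
            return out

        return run

    return wrap


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Execute the full analysis and optionally write all artifacts.

    ``seed`` overrides the simulation seed when the config simulates its
    input; runs are fully reproducible given config + seed.
    """
    sim = config.simulation
    if sim is not None and seed is not None:
        sim = replace(sim, seed=int(seed))

    if sim is not None:
        beads, meta, traits, truth = _stage("simulate")(simulate_experiment)(sim)
    else:
        beads, meta, traits = _stage("load")(load_experiment)(
            config.beads_path, config.metadata_path, config.traits_path
        )
        truth = None

    mfi_all = _stage("collapse")(collapse_to_mfi)(beads, meta)
    mfi, removed = _stage("filter")(filter_low_mfi)(mfi_all, config.mfi_threshold)

    anc_results: dict[tuple[str, str], ANCResult] = {}
    for contrast in config.contrasts:
        anc_results[contrast] = _stage(f"anc {contrast[0]}:{contrast[1]}")(anc_test)(
            beads,
            meta,
            contrast,
            base_alpha=config.base_alpha,
            interactions=mfi.interaction_ids,
        )

    log2 = _stage("log2")(log2_transform)(mfi)
    n_batches = meta.df["batch_id"].nunique()
    if n_batches > 1:
        corrected = _stage("batch-correct")(empirical_bayes_batch_correct)(
            log2, meta.batch_of(), meta.condition_of()
        )
    else:
        corrected = log2

    soft_power, fit_table = _stage("soft-threshold")(pick_soft_threshold)(
        corrected, config.candidate_powers
    )
    network = _stage("adjacency")(compute_adjacency)(corrected, soft_power)
    tom = _stage("tom")(compute_tom)(network)
    modules = _stage("modules")(detect_modules)(
        tom, corrected, min_size=config.min_module_size,
        cut_height_fraction=config.cut_height_fraction,
    )
    membership = _stage("membership")(module_membership)(corrected, modules)
    module_trait = None
    if traits is not None and modules.module_names:
        module_trait = _stage("module-trait")(module_trait_correlation)(modules, traits)

    high_confidence: dict[tuple[str, str], HighConfidenceSet] = {}
    hypotheses = list(config.hypotheses) if config.hypotheses is not None else None
    for contrast, anc in anc_results.items():
        if module_trait is None or module_trait.empty:
            hcs = HighConfidenceSet(
                table=pd.DataFrame(
                    columns=["direction", "log2fc", "module", "anc_hit", "cna_hit"],
                    index=pd.Index([], name="interaction"),
                ),
                contrast=contrast,
                modules_of_interest=[],
            )
        else:
            hcs = _stage(f"intersect {contrast[0]}:{contrast[1]}")(intersect_hits)(
                anc, membership, module_trait,
                hypothesis=hypotheses, alpha=config.membership_alpha,
            )
        high_confidence[contrast] = hcs

    scaled = _stage("scale")(scale_by_row_median)(mfi)
    pca_scores, pca_frac = _stage("pca")(pca_coordinates)(corrected)
    dendro = _stage("cluster-samples")(hierarchical_cluster_samples)(corrected)

    cond = meta.condition_of()
    activity_report = {}
    for color in modules.module_names:
        act = module_activity(scaled, modules.members(color), cond)
        activity_report[color] = {
            "anova_f": act.anova_f,
            "anova_p": act.anova_p,
            "posthoc": act.posthoc.to_dict(orient="records"),
        }

    log2fc_tables = {
        contrast: compute_log2fc(mfi, contrast[0], contrast[1], meta)
        for contrast in config.contrasts
    }

    report = {
        "qminet_version": __version__,
        "seed": sim.seed if sim is not None else None,
        "parameters": {
            "mfi_threshold": config.mfi_threshold,
            "base_alpha": config.base_alpha,
            "trait_alpha": config.trait_alpha,
            "membership_alpha": config.membership_alpha,
            "min_module_size": config.min_module_size,
            "cut_height_fraction": config.cut_height_fraction,
        },
        "n_samples": len(meta.sample_ids),
        "n_interactions_input": mfi_all.shape[0],
        "n_interactions_tested": mfi.shape[0],
        "removed_low_mfi": removed,
        "soft_power": soft_power,
        "module_sizes": modules.sizes,
        "n_grey": int((modules.labels == "grey").sum()),
        "module_trait": (
            module_trait.to_dict(orient="records") if module_trait is not None else []
        ),
        "module_activity": activity_report,
        "pca_explained_variance": [float(f) for f in pca_frac[:5]],
        "anc": {
            f"{c[0]}:{c[1]}": {
                "alpha_used": res.alpha_used,
                "n_pairs": res.n_comparisons,
                "n_null_comparisons": res.n_null_comparisons,
                "n_hits": len(res.hits),
                "hits": res.hits,
            }
            for c, res in anc_results.items()
        },
        "high_confidence": {
            f"{c[0]}:{c[1]}": {
                "n": len(hcs),
                "modules_of_interest": hcs.modules_of_interest,
                "interactions": hcs.interactions,
            }
            for c, hcs in high_confidence.items()
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mfi_matrix(mfi, out / "mfi.tsv")
        scaled_out = scaled.values.copy()
        scaled_out.index.name = "interaction"
        scaled_out.to_csv(out / "scaled.tsv", sep="\t", float_format=_FLOAT_FORMAT)
        mod_table = pd.DataFrame({"module": modules.labels})
        mod_table.index.name = "interaction"
        mod_table.to_csv(out / "modules.tsv", sep="\t")
        membership.to_csv(out / "membership.tsv", sep="\t", index=False,
                          float_format=_FLOAT_FORMAT)
        if module_trait is not None:
            module_trait.to_csv(out / "module_trait.tsv", sep="\t", index=False,
                                float_format=_FLOAT_FORMAT)
        if modules.module_names:
            ev = modules.eigenvectors.copy()
            ev.index.name = "sample_id"
            ev.to_csv(out / "eigenvectors.tsv", sep="\t", float_format=_FLOAT_FORMAT)
        fit_out = fit_table.reset_index()
        fit_out.to_csv(out / "fit_table.tsv", sep="\t", index=False,
                       float_format=_FLOAT_FORMAT)
        pca_out = pca_scores.copy()
        pca_out.index.name = "sample_id"
        pca_out.to_csv(out / "pca.tsv", sep="\t", float_format=_FLOAT_FORMAT)
        (out / "dendrogram.json").write_text(
            json.dumps(dendro.to_dict(), indent=2, sort_keys=True)
        )
        for contrast, res in anc_results.items():
            tag = f"{contrast[0]}_vs_{contrast[1]}"
            res.to_frame().to_csv(out / f"anc_{tag}.tsv", sep="\t",
                                  float_format=_FLOAT_FORMAT)
            hcs = high_confidence[contrast]
            hits_out = hcs.table.copy()
            hits_out["log2fc_group_means"] = log2fc_tables[contrast].reindex(hits_out.index)
            hits_out.to_csv(out / f"hits_{tag}.tsv", sep="\t", float_format=_FLOAT_FORMAT)
            export_edge_list(hcs, out / f"edges_{tag}.tsv")
        if truth is not None:
            truth.to_json(out / "truth.json")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    return PipelineResult(
        config=config,
        beads=beads,
        meta=meta,
        traits=traits,
        truth=truth,
        mfi=mfi,
        removed_low_mfi=removed,
        corrected=corrected,
        soft_power=soft_power,
        fit_table=fit_table,
        modules=modules,
        module_trait=module_trait,
        membership=membership,
        anc_results=anc_results,
        high_confidence=high_confidence,
        report=report,
    )
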