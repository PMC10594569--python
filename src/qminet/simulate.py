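"""Synthetic QMI experiments with known ground truth.

The generator emulates the structure of a bead-based multiplex
co-immunoprecipitation study: a panel of ``IP_probe`` interactions measured as
bead-level fluorescence distributions (~50-150 reads per interaction per
well), two technical-duplicate wells per sample, matched samples (one per
condition per biological replicate, linked by a pair key), biological
replicates split across batches, and "planted" modules of co-regulated
interactions with per-condition log2 effects.

Generative model, for interaction g in condition c, replicate r, batch b::

    m = mu_g * 2**e_{g,c} * rho_{g,r} * beta_{g,b} * w_well
    bead fluorescence ~ LogNormal(mean=m, CV=bead_cv)

with baseline ``mu_g ~ log-uniform(baseline_mfi_range)``, replicate
multiplier ``rho ~ LogNormal(0, sigma(replicate_cv))`` shared by both matched
samples of a replicate, batch multiplier ``beta ~ LogNormal(0,
batch_sigma * ln 2)``, and one well multiplier ``w ~ LogNormal(0,
sigma(duplicate_cv))`` per well (shared across interactions, emulating
loading/pipetting differences between duplicate wells).  LogNormal noise keeps
fluorescence positive and right-skewed and makes planted log2 effects exact on
the scale of expected values.

Identical config + seed produces bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BeadEventTable, SampleMetadata, TraitTable
from .errors import ParameterError


def _sigma_from_cv(cv: float) -> float:
    """Log-scale s.d. of a LogNormal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass(frozen=True)
class PlantedModule:
    """A set of co-regulated interactions with shared per-condition log2 effects."""

    name: str
    members: tuple[int, ...]  # interaction indices into the simulated panel
    effects: dict[str, float]  # condition -> log2 effect (reference condition: 0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(int(m) for m in self.members))
        if len(set(self.members)) != len(self.members):
            raise ParameterError(f"module {self.name!r} lists a member twice")
        if not all(np.isfinite(list(self.effects.values()))):
            raise ParameterError(f"module {self.name!r} has non-finite effects")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic QMI experiment.

    Defaults mirror the emulated assay: a 384-interaction panel, 50-150 beads
    per interaction per well, baseline MFI log-uniform on 150-20,000 units,
    30% bead-level CV, 10% replicate CV, 5% duplicate-well CV, 8 matched
    biological replicates split evenly over 2 batches with 0.25 log2-s.d.
    batch multipliers.
    """

    n_interactions: int = 384
    conditions: tuple[str, ...] = ("starved", "refed")
    n_biological_replicates: int = 8
    beads_per_well: tuple[int, int] = (50, 150)
    baseline_mfi_range: tuple[float, float] = (150.0, 20000.0)
    bead_cv: float = 0.30
    replicate_cv: float = 0.10
    duplicate_cv: float = 0.05
    n_batches: int = 2
    batch_sigma: float = 0.25  # log2 s.d. of batch multipliers
    planted_modules: tuple[PlantedModule, ...] = ()
    extra_traits: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_interactions < 1:
            raise ParameterError("n_interactions must be >= 1")
        if len(self.conditions) < 2:
            raise ParameterError("need at least two conditions (first = reference)")
        if len(set(self.conditions)) != len(self.conditions):
            raise ParameterError("condition labels must be unique")
        for cv in (self.bead_cv, self.replicate_cv, self.duplicate_cv):
            if cv < 0:
                raise ParameterError("coefficients of variation must be >= 0")
        if self.batch_sigma < 0:
            raise ParameterError("batch_sigma must be >= 0")
        if not (1 <= self.beads_per_well[0] <= self.beads_per_well[1]):
            raise ParameterError("beads_per_well must be an increasing positive range")
        if self.n_batches < 1:
            raise ParameterError("n_batches must be >= 1")
        seen: set[int] = set()
        for mod in self.planted_modules:
            for m in mod.members:
                if not (0 <= m < self.n_interactions):
                    raise ParameterError(
                        f"module {mod.name!r} member index {m} outside panel "
                        f"of {self.n_interactions}"
                    )
                if m in seen:
                    raise ParameterError(f"interaction index {m} planted in two modules")
                seen.add(m)
            unknown = set(mod.effects) - set(self.conditions)
            if unknown:
                raise ParameterError(f"module {mod.name!r} effects name unknown conditions {unknown}")

    @property
    def reference_condition(self) -> str:
        return self.conditions[0]

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        payload = json.loads(Path(path).read_text())
        payload["conditions"] = tuple(payload["conditions"])
        payload["beads_per_well"] = tuple(payload["beads_per_well"])
        payload["baseline_mfi_range"] = tuple(payload["baseline_mfi_range"])
        payload["planted_modules"] = tuple(
            PlantedModule(m["name"], tuple(m["members"]), dict(m["effects"]))
            for m in payload.get("planted_modules", ())
        )
        return cls(**payload)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated experiment, serializable to JSON losslessly."""

    module_of: dict[str, str | None]  # interaction id -> module name (None = unplanted)
    expected_log2_effect: pd.DataFrame  # interactions x conditions
    replicate_multipliers: pd.DataFrame  # interactions x replicate ids
    batch_multipliers: pd.DataFrame  # interactions x batch ids
    well_multipliers: pd.Series  # well id -> multiplier
    baseline_mfi: pd.Series  # interaction id -> mu_g
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_of": self.module_of,
            "expected_log2_effect": self.expected_log2_effect.to_dict(orient="split"),
            "replicate_multipliers": self.replicate_multipliers.to_dict(orient="split"),
            "batch_multipliers": self.batch_multipliers.to_dict(orient="split"),
            "well_multipliers": {
                "index": list(self.well_multipliers.index),
                "data": [float(v) for v in self.well_multipliers],
            },
            "baseline_mfi": {
                "index": list(self.baseline_mfi.index),
                "data": [float(v) for v in self.baseline_mfi],
            },
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())

        def frame(d):
            return pd.DataFrame(d["data"], index=d["index"], columns=d["columns"])

        return cls(
            module_of=payload["module_of"],
            expected_log2_effect=frame(payload["expected_log2_effect"]),
            replicate_multipliers=frame(payload["replicate_multipliers"]),
            batch_multipliers=frame(payload["batch_multipliers"]),
            well_multipliers=pd.Series(
                payload["well_multipliers"]["data"],
                index=payload["well_multipliers"]["index"],
            ),
            baseline_mfi=pd.Series(
                payload["baseline_mfi"]["data"],
                index=payload["baseline_mfi"]["index"],
            ),
            seed=payload["seed"],
        )

    def responsive_interactions(self, condition: str) -> list[str]:
        """Interactions with a non-zero planted effect in ``condition``."""
        eff = self.expected_log2_effect[condition]
        return list(eff.index[eff != 0.0])


def _panel_interaction_ids(n: int) -> list[str]:
    """Ordered IP_probe identifiers over a minimal square protein panel."""
    n_targets = int(np.ceil(np.sqrt(n)))
    width = len(str(n_targets))
    targets = [f"T{i + 1:0{width}d}" for i in range(n_targets)]
    ids = [f"{a}_{b}" for a in targets for b in targets]
    return ids[:n]


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[BeadEventTable, SampleMetadata, TraitTable, SimulationTruth]:
    """Draw a full bead-level experiment from the generative model.

    Returns the bead event table, sample metadata (matched design: one sample
    per condition per biological replicate, duplicated wells), the trait table
    (one 0/1 indicator per non-reference condition plus any configured
    composite/ordinal rows), and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_interactions
    ids = _panel_interaction_ids(G)
    conditions = list(config.conditions)
    R = config.n_biological_replicates

    lo, hi = config.baseline_mfi_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))

    # per-condition log2 effects (reference and unplanted interactions: 0)
    effects = np.zeros((G, len(conditions)))
    module_of: dict[str, str | None] = {i: None for i in ids}
    for mod in config.planted_modules:
        for m in mod.members:
            module_of[ids[m]] = mod.name
            for c, e in mod.effects.items():
                effects[m, conditions.index(c)] = float(e)

    rep_ids = [f"BR{r + 1:02d}" for r in range(R)]
    batch_ids = [f"batch{b + 1}" for b in range(config.n_batches)]
    sigma_rep = _sigma_from_cv(config.replicate_cv)
    sigma_dup = _sigma_from_cv(config.duplicate_cv)
    sigma_bead = _sigma_from_cv(config.bead_cv)
    sigma_batch = config.batch_sigma * np.log(2.0)

    rho = np.exp(rng.normal(0.0, sigma_rep, size=(G, R))) if sigma_rep > 0 else np.ones((G, R))
    beta = (
        np.exp(rng.normal(0.0, sigma_batch, size=(G, config.n_batches)))
        if sigma_batch > 0
        else np.ones((G, config.n_batches))
    )

    # samples: replicate-major, condition order as configured; replicates
    # alternate over batches so no batch is confounded with a condition
    meta_rows = []
    wells: list[tuple[str, str, int, int]] = []  # (sample, well, rep idx, batch idx)
    for r in range(R):
        b = r % config.n_batches
        for c in conditions:
            sid = f"{rep_ids[r]}_{c}"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "biological_replicate_id": rep_ids[r],
                    "condition": c,
                    "batch_id": batch_ids[b],
                    "technical_duplicate_index": 1,
                    "pair_key": rep_ids[r],
                }
            )
            for w in (1, 2):
                wells.append((sid, f"{sid}_w{w}", r, b))
    meta = SampleMetadata(pd.DataFrame(meta_rows))

    well_ids = [w[1] for w in wells]
    wmult = (
        np.exp(rng.normal(0.0, sigma_dup, size=len(wells)))
        if sigma_dup > 0
        else np.ones(len(wells))
    )

    cond_index = {c: k for k, c in enumerate(conditions)}
    cond_of_sample = meta.condition_of()
    frames = []
    for (sid, wid, r, b), wm in zip(wells, wmult):
        c = cond_index[cond_of_sample[sid]]
        m = mu * np.exp2(effects[:, c]) * rho[:, r] * beta[:, b] * wm
        counts = rng.integers(config.beads_per_well[0], config.beads_per_well[1] + 1, size=G)
        total = int(counts.sum())
        log_mean = np.repeat(np.log(m) - 0.5 * sigma_bead**2, counts)
        if sigma_bead > 0:
            fl = np.exp(log_mean + sigma_bead * rng.standard_normal(total))
        else:
            fl = np.exp(log_mean)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "well_id": wid,
                    "batch_id": batch_ids[b],
                    "ip": np.repeat([i.split("_", 1)[0] for i in ids], counts),
                    "probe": np.repeat([i.split("_", 1)[1] for i in ids], counts),
                    "fluorescence": fl,
                }
            )
        )
    beads = BeadEventTable(pd.concat(frames, ignore_index=True))

    sample_ids = meta.sample_ids
    cond_of = meta.condition_of()
    trait_rows: dict[str, list[float]] = {}
    for c in conditions[1:]:
        trait_rows[c] = [1.0 if cond_of[s] == c else 0.0 for s in sample_ids]
    for name, coding in config.extra_traits.items():
        trait_rows[name] = [float(coding[cond_of[s]]) for s in sample_ids]
    traits = TraitTable(pd.DataFrame(trait_rows, index=sample_ids).T)

    truth = SimulationTruth(
        module_of=module_of,
        expected_log2_effect=pd.DataFrame(effects, index=ids, columns=conditions),
        replicate_multipliers=pd.DataFrame(rho, index=ids, columns=rep_ids),
        batch_multipliers=pd.DataFrame(beta, index=ids, columns=batch_ids),
        well_multipliers=pd.Series(wmult, index=well_ids),
        baseline_mfi=pd.Series(mu, index=ids),
        seed=config.seed,
    )
    return beads, meta, traits, truth


def simulate_null(
    config: SimulationConfig,
) -> tuple[BeadEventTable, SampleMetadata, TraitTable, SimulationTruth]:
    """Same generative draw as :func:`simulate_experiment`, with all planted effects zero.

    Module membership labels are kept (truth records zero effects for every
    interaction), so null runs share the panel layout of their matched
    alternative runs.
    """
    null_modules = tuple(
        PlantedModule(m.name, m.members, {c: 0.0 for c in m.effects})
        for m in config.planted_modules
    )
    return simulate_experiment(replace(config, planted_modules=null_modules))
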