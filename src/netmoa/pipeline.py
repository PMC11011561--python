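"""End-to-end orchestration: load -> train -> simulate -> analyze -> export.

One YAML config drives the whole workflow.  Every output is a
deterministic text file (TSV/JSON/DOT): re-running with the same config
and seeds reproduces byte-identical outputs.  The expensive stage — the
simulated-annealing ensemble — is cached in the output directory keyed on
a hash of its inputs, so re-analysis with new thresholds skips
retraining.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping

import yaml

from . import __version__
from .analysis import (
    compare_scenarios,
    ensemble_activity,
    fsignal_distribution,
    heatmap_matrix,
    write_fsignal_table,
    write_heatmap_matrix,
)
from .characterization import (
    SCENARIOS,
    Characterization,
    Stimulus,
    build_scenario,
    load_characterization,
)
from .enrichment import (
    DEFAULT_MAX_HAUSDORFF,
    DEFAULT_MAX_SET_SIZE,
    DEFAULT_MIN_SET_SIZE,
    DEFAULT_Q_THRESHOLD,
    FOREGROUND_THRESHOLD,
    enrichment_network,
    read_gmt,
    run_enrichment,
    select_foreground,
    write_enrichment_network,
    write_enrichment_table,
)
from .interactome import Interactome, read_edge_list
from .moa_paths import (
    DEFAULT_DIFF_THRESHOLD,
    DEFAULT_MIN_FREQUENCY,
    extract_moa_paths,
    paths_to_dot,
    select_moa_effectors,
    write_paths_table,
)
from .propagation import PropagationConfig, write_profile
from .training import (
    DEFAULT_TAU,
    AnnealSchedule,
    Ensemble,
    TrainingRestriction,
    load_ensemble,
    sample_ensemble,
    save_ensemble,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class Thresholds:
    foreground: float = FOREGROUND_THRESHOLD
    heatmap: float = 0.1
    enrichment_q: float = DEFAULT_Q_THRESHOLD
    min_set_size: int = DEFAULT_MIN_SET_SIZE
    max_set_size: int = DEFAULT_MAX_SET_SIZE
    max_hausdorff: float = DEFAULT_MAX_HAUSDORFF
    path_frequency: float = DEFAULT_MIN_FREQUENCY
    effector_diff: float = DEFAULT_DIFF_THRESHOLD
    tau: float = DEFAULT_TAU


@dataclass
class RunConfig:
    network: str
    characterization: str
    training: str
    output_dir: str
    gmt: str | None = None
    scenarios: list = field(default_factory=list)  # names or {name: {protein: sign}}
    reference_scenario: str | None = None
    ensemble_size: int = 250
    base_seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    enrichment: bool = True
    moa: dict | None = None  # source, pathway_scenario, other_scenario, drug_scenario

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p: str | None) -> str | None:
            if p is None:
                return None
            return p if os.path.isabs(p) else os.path.join(base, p)

        kwargs = dict(raw)
        for key in ("network", "characterization", "training", "gmt", "output_dir"):
            if key in kwargs:
                kwargs[key] = resolve(kwargs[key])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "schedule" in kwargs:
            kwargs["schedule"] = AnnealSchedule(**kwargs["schedule"])
        if "propagation" in kwargs:
            kwargs["propagation"] = PropagationConfig(**kwargs["propagation"])
        return cls(**kwargs)

    def validate(self) -> None:
        for key in ("network", "characterization", "training"):
            path = getattr(self, key)
            if not os.path.exists(path):
                raise PipelineError("validate", f"{key} file not found: {path}")
        if self.enrichment and self.gmt is None:
            raise PipelineError("validate", "enrichment enabled but no GMT file given")
        if self.enrichment and not os.path.exists(self.gmt):
            raise PipelineError("validate", f"gmt file not found: {self.gmt}")
        if not self.scenarios:
            raise PipelineError("validate", "no scenarios configured")
        if self.ensemble_size < 1:
            raise PipelineError("validate", "ensemble_size must be >= 1")


def load_training_set(
    path: str, characterization: Characterization
) -> list[TrainingRestriction]:
    """YAML/JSON list of restrictions.

    Each record gives a relation ("therapeutic" or "inductive"), a
    response process name, and either a ``drug`` name (resolved against
    the characterization, all targets applied with their signs) or an
    inline ``stimulus`` mapping {protein: sign}.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError("training set must be a list of restriction records")
    relations = {"therapeutic": -1, "inductive": 1}
    restrictions = []
    for i, rec in enumerate(raw):
        if rec.get("relation") not in relations:
            raise ValueError(f"restriction {i}: relation must be therapeutic or inductive")
        if "drug" in rec:
            drug = rec["drug"]
            if drug not in characterization.drug_targets:
                raise ValueError(f"restriction {i}: unknown drug {drug!r}")
            stim = Stimulus(name=drug, clamps=characterization.drug_targets[drug])
        elif "stimulus" in rec:
            stim = Stimulus(name=f"stimulus{i}", clamps=rec["stimulus"])
        else:
            raise ValueError(f"restriction {i}: needs 'drug' or 'stimulus'")
        restrictions.append(
            TrainingRestriction(
                stimulus=stim,
                response=characterization.effector_set(rec["response"]),
                relation=relations[rec["relation"]],
            )
        )
    return restrictions


def resolve_scenarios(
    entries: list, characterization: Characterization
) -> dict[str, Stimulus]:
    """Scenario entries: a plain string names a drug (all its targets) or
    one of the built-in receptor scenarios; a one-key mapping gives clamps
    inline."""
    scenarios: dict[str, Stimulus] = {}
    all_targets: dict[str, int] = {}
    for targets in characterization.drug_targets.values():
        all_targets.update(targets)
    for entry in entries:
        if isinstance(entry, str):
            if entry in characterization.drug_targets:
                scenarios[entry] = Stimulus(
                    name=entry, clamps=characterization.drug_targets[entry]
                )
            elif entry in SCENARIOS:
                scenarios[entry] = build_scenario(entry, all_targets)
            else:
                raise KeyError(f"unknown scenario {entry!r}")
        elif isinstance(entry, Mapping) and len(entry) == 1:
            name, clamps = next(iter(entry.items()))
            scenarios[str(name)] = Stimulus(name=str(name), clamps=dict(clamps))
        else:
            raise ValueError(f"bad scenario entry: {entry!r}")
    return scenarios


def _file_digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def _ensemble_cache_key(cfg: RunConfig) -> str:
    h = hashlib.sha256()
    for path in (cfg.network, cfg.characterization, cfg.training):
        h.update(_file_digest(path).encode())
    payload = {
        "ensemble_size": cfg.ensemble_size,
        "base_seed": cfg.base_seed,
        "schedule": asdict(cfg.schedule),
        "propagation": asdict(cfg.propagation),
        "tau": cfg.thresholds.tau,
    }
    h.update(json.dumps(payload, sort_keys=True).encode())
    return h.hexdigest()


def ensure_ensemble(
    cfg: RunConfig,
    net: Interactome,
    restrictions: list[TrainingRestriction],
) -> tuple[Ensemble, bool]:
    """Train the SA ensemble or load it from the output-dir cache.

    Returns (ensemble, was_cached).
    """
    cache_dir = os.path.join(cfg.output_dir, "ensemble")
    key = _ensemble_cache_key(cfg)
    key_file = os.path.join(cache_dir, "cache_key.json")
    if os.path.exists(key_file):
        with open(key_file, encoding="utf-8") as fh:
            if json.load(fh).get("cache_key") == key:
                return load_ensemble(cache_dir), True
    ensemble = sample_ensemble(
        net,
        restrictions,
        schedule=cfg.schedule,
        n_solutions=cfg.ensemble_size,
        base_seed=cfg.base_seed,
        cfg=cfg.propagation,
        tau=cfg.thresholds.tau,
    )
    save_ensemble(ensemble, cache_dir)
    with open(key_file, "w", encoding="utf-8") as fh:
        json.dump({"cache_key": key}, fh, sort_keys=True)
        fh.write("\n")
    return ensemble, False


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    cfg.validate()
    os.makedirs(cfg.output_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "base_seed": cfg.base_seed,
        "ensemble_size": cfg.ensemble_size,
        "thresholds": asdict(cfg.thresholds),
        "schedule": asdict(cfg.schedule),
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts

    def output(path: str) -> str:
        manifest["outputs"].append(os.path.relpath(path, cfg.output_dir))
        return path

    def fail(stage: str, exc: Exception) -> PipelineError:
        manifest["failed_stage"] = stage
        _write_manifest(manifest, cfg.output_dir)
        return PipelineError(stage, str(exc))

    # load
    try:
        net = read_edge_list(cfg.network)
        characterization = load_characterization(cfg.characterization)
        restrictions = load_training_set(cfg.training, characterization)
        scenarios = resolve_scenarios(cfg.scenarios, characterization)
        record(
            "load",
            n_nodes=net.n_nodes,
            n_edges=net.n_edges,
            n_restrictions=len(restrictions),
            n_effectors_total=characterization.n_effectors_total,
            n_effectors_unique=characterization.n_effectors_unique,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise fail("load", exc) from exc

    # train
    try:
        ensemble, cached = ensure_ensemble(cfg, net, restrictions)
        record(
            "train",
            n_solutions=ensemble.size,
            mean_accuracy=ensemble.mean_accuracy,
            min_accuracy=ensemble.min_accuracy,
            cached=cached,
        )
    except Exception as exc:
        raise fail("train", exc) from exc

    # simulate scenarios
    try:
        activities = {}
        signal_nodes: set[str] = set()
        for name in sorted(scenarios):
            ea = ensemble_activity(ensemble, net, scenarios[name], cfg.propagation)
            activities[name] = ea
            signal_nodes |= {
                p for p, o in ea.mean_profile.activity.items() if o != 0.0
            }
            write_profile(
                ea.mean_profile,
                output(os.path.join(cfg.output_dir, f"activity_{name}.tsv")),
            )
        record(
            "simulate",
            n_scenarios=len(scenarios),
            n_signal_receiving_proteins=len(signal_nodes),
        )
    except Exception as exc:
        raise fail("simulate", exc) from exc

    # fSignal + comparison + heatmap
    try:
        distributions = {}
        for name, ea in activities.items():
            for effs in characterization.effector_sets:
                distributions[(effs.process, name)] = fsignal_distribution(
                    ea.profiles, effs, name
                )
        reference = cfg.reference_scenario or sorted(scenarios)[0]
        results = (
            compare_scenarios(distributions, reference) if len(scenarios) > 1 else []
        )
        write_fsignal_table(
            distributions,
            results,
            output(os.path.join(cfg.output_dir, "fsignal.tsv")),
            reference,
        )
        mean_profiles = {n: ea.mean_profile for n, ea in activities.items()}
        hm = heatmap_matrix(
            mean_profiles, characterization.effector_sets, cfg.thresholds.heatmap
        )
        write_heatmap_matrix(
            hm, output(os.path.join(cfg.output_dir, "heatmap.tsv"))
        )
        record(
            "analyze",
            n_comparisons=len(results),
            n_flagged=sum(1 for r in results if r.flag),
            n_heatmap_rows=len(hm.matrix),
            reference_scenario=reference,
        )
    except Exception as exc:
        raise fail("analyze", exc) from exc

    # enrichment
    if cfg.enrichment:
        try:
            collection = read_gmt(cfg.gmt, background=net.nodes)
            ref_profile = activities[reference].mean_profile
            foreground = select_foreground(ref_profile, cfg.thresholds.foreground)
            enr = run_enrichment(
                foreground,
                collection,
                min_size=cfg.thresholds.min_set_size,
                max_size=cfg.thresholds.max_set_size,
                q_threshold=cfg.thresholds.enrichment_q,
            )
            write_enrichment_table(
                enr, output(os.path.join(cfg.output_dir, "enrichment.tsv"))
            )
            significant = [r for r in enr if r.significant]
            edges = (
                enrichment_network(
                    significant, net, collection, cfg.thresholds.max_hausdorff
                )
                if len(significant) >= 2
                else []
            )
            write_enrichment_network(
                edges,
                significant,
                output(os.path.join(cfg.output_dir, "enrichment_network.tsv")),
                output(os.path.join(cfg.output_dir, "enrichment_nodes.tsv")),
            )
            record(
                "enrich",
                n_foreground=len(foreground),
                n_tested=len(enr),
                n_significant=len(significant),
                n_network_edges=len(edges),
            )
        except Exception as exc:
            raise fail("enrich", exc) from exc

    # MoA paths
    if cfg.moa:
        try:
            moa = dict(cfg.moa)
            mean_profiles = {n: ea.mean_profile for n, ea in activities.items()}
            effectors = select_moa_effectors(
                mean_profiles,
                characterization.effector_sets,
                diff_threshold=cfg.thresholds.effector_diff,
                pathway_scenario=moa["pathway_scenario"],
                other_scenario=moa["other_scenario"],
                drug_scenario=moa["drug_scenario"],
            )
            stim = scenarios[moa["drug_scenario"]]
            paths = extract_moa_paths(
                ensemble,
                net,
                source=moa["source"],
                effectors=effectors,
                stimulus=stim,
                cfg=cfg.propagation,
                min_frequency=cfg.thresholds.path_frequency,
                max_length=int(moa.get("max_length", 6)),
            )
            write_paths_table(
                paths, output(os.path.join(cfg.output_dir, "moa_paths.tsv"))
            )
            dot = paths_to_dot(paths, mean_profiles[moa["drug_scenario"]])
            dot_path = output(os.path.join(cfg.output_dir, "moa_paths.dot"))
            with open(dot_path, "w", encoding="utf-8") as fh:
                fh.write(dot)
            record(
                "paths",
                n_selected_effectors=len(effectors),
                n_retained_paths=len(paths),
            )
        except Exception as exc:
            raise fail("paths", exc) from exc

    _write_manifest(manifest, cfg.output_dir)
    return manifest


def _write_manifest(manifest: dict, output_dir: str) -> None:
    os.makedirs(output_dir, exist_ok=True)
    with open(os.path.join(output_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
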