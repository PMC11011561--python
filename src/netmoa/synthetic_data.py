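"""Self-contained synthetic worlds for end-to-end testing and calibration.

A world consists of a scale-free signed interactome with planted edge
weights, effector sets with pathological directions, drug target sets,
and a training set of stimulus->response restrictions generated by
forward simulation from the planted weights.  Because the labels are
derived from a known ground-truth model, the whole pipeline — training,
scenario simulation, enrichment, path extraction — can be exercised and
scored against truth without any external data.

Topology: a Barabási–Albert preferential-attachment graph.  Each
attachment edge is oriented from the newer node toward the older one with
probability 0.7 (and the reverse otherwise), so late-added nodes act as
signal sources and the early hubs accumulate heavy-tailed in-degree, the
way drug targets feed signal toward well-connected core proteins.  Drug
targets are sampled from the late ("young") half of the node order;
effectors from the proteins that actually receive signal under at least
one drug stimulus.

(drug, process) pairs whose planted fSignal magnitude falls below
``truth_margin`` are excluded from both the training set and the truth
map: their sign is numerically meaningless and any label on them would be
a coin flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from .analysis import fsignal
from .characterization import EffectorSet, Stimulus
from .enrichment import ProteinSet, ProteinSetCollection
from .interactome import Interactome
from .propagation import MatrixPropagator, PropagationConfig, WeightAssignment
from .training import TrainingRestriction


@dataclass
class GeneratorConfig:
    n_nodes: int = 150
    m: int = 2  # preferential-attachment edges per new node
    p_inh: float = 0.3  # probability an edge is inhibitory
    k_processes: int = 6
    effectors_per_process: int = 5
    n_drugs: int = 12
    targets_per_drug: int = 2
    label_noise: float = 0.0
    seed: int = 0
    weight_low: float = 0.2  # planted weights bounded away from 0 so
    weight_high: float = 1.0  # every truth label has unambiguous sign
    truth_margin: float = 0.1
    p_forward: float = 0.7  # probability an edge points young -> old

    def __post_init__(self) -> None:
        for name in ("n_nodes", "m", "k_processes", "effectors_per_process",
                     "n_drugs", "targets_per_drug"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("p_inh", "label_noise", "p_forward"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.k_processes * self.effectors_per_process > self.n_nodes:
            raise ValueError("more effector slots than nodes")
        if self.n_drugs * self.targets_per_drug > self.n_nodes // 2:
            raise ValueError("too many drug targets for the young half of the graph")


@dataclass
class SyntheticWorld:
    interactome: Interactome
    planted_weights: WeightAssignment
    effector_sets: list[EffectorSet]
    drug_targets: dict[str, Stimulus]
    training_set: list[TrainingRestriction]
    truth: dict[tuple[str, str], float]  # (drug, process) -> planted fSignal
    config: GeneratorConfig


def _node_name(i: int) -> str:
    return f"P{i:04d}"


def _planted_profiles(
    net: Interactome,
    weights: WeightAssignment,
    stimuli: list[Stimulus],
    cfg: PropagationConfig,
) -> tuple[MatrixPropagator, np.ndarray]:
    engine = MatrixPropagator(net)
    engine.load_weights(weights.vector(engine.edge_order))
    values, mask = engine.clamp_arrays(stimuli)
    O, _, _ = engine.relax(values, mask, cfg)
    return engine, O


def generate_world(cfg: GeneratorConfig) -> SyntheticWorld:
    """Generate a fully reproducible synthetic world from the config seed."""
    rng = np.random.default_rng(cfg.seed)
    ba = nx.barabasi_albert_graph(cfg.n_nodes, cfg.m, seed=int(rng.integers(2**31)))
    net = Interactome()
    for i in range(cfg.n_nodes):
        net.add_node(_node_name(i))
    for u, v in sorted(ba.edges()):
        old, young = (u, v) if u < v else (v, u)
        if rng.random() < cfg.p_forward:
            src, tgt = young, old
        else:
            src, tgt = old, young
        sign = -1 if rng.random() < cfg.p_inh else 1
        net.add_edge(_node_name(src), _node_name(tgt), sign)
    weights = WeightAssignment(
        {
            (u, v): float(rng.uniform(cfg.weight_low, cfg.weight_high))
            for u, v, _ in net.sorted_edges()
        }
    )

    # drug targets from the young half: signal sources under the dominant
    # young -> old edge orientation
    young = [_node_name(i) for i in range(cfg.n_nodes // 2, cfg.n_nodes)]
    target_nodes = [
        str(t)
        for t in rng.choice(young, size=cfg.n_drugs * cfg.targets_per_drug, replace=False)
    ]
    drug_targets: dict[str, Stimulus] = {}
    for d in range(cfg.n_drugs):
        targets = target_nodes[d * cfg.targets_per_drug : (d + 1) * cfg.targets_per_drug]
        drug_targets[f"drug{d:02d}"] = Stimulus(
            name=f"drug{d:02d}", clamps={t: -1 for t in targets}
        )

    prop_cfg = PropagationConfig()
    stimuli = [drug_targets[d] for d in sorted(drug_targets)]
    engine, O = _planted_profiles(net, weights, stimuli, prop_cfg)

    # effector pool: non-target proteins receiving clear signal from >= 1 drug
    signal_strength = np.max(np.abs(O), axis=1)
    pool = [
        p
        for p, i in sorted(engine.index.items())
        if signal_strength[i] > cfg.truth_margin and p not in set(target_nodes)
    ]
    if len(pool) < cfg.effectors_per_process:
        raise ValueError(
            f"only {len(pool)} proteins receive signal; cannot draw "
            f"{cfg.effectors_per_process} effectors per process"
        )
    effector_sets = []
    for k in range(cfg.k_processes):
        members = rng.choice(pool, size=cfg.effectors_per_process, replace=False)
        signs = rng.choice([-1, 1], size=cfg.effectors_per_process)
        effector_sets.append(
            EffectorSet(
                process=f"process{k}",
                members={str(p): int(s) for p, s in zip(members, signs)},
            )
        )

    # truth + training restrictions from the planted model
    truth: dict[tuple[str, str], float] = {}
    training_set: list[TrainingRestriction] = []
    for j, drug in enumerate(sorted(drug_targets)):
        profile = {p: float(O[i, j]) for p, i in engine.index.items()}
        for effs in effector_sets:
            fs = fsignal(profile, effs)
            if abs(fs) < cfg.truth_margin:
                continue
            truth[(drug, effs.process)] = fs
            relation = 1 if fs > 0 else -1
            if rng.random() < cfg.label_noise:
                relation = -relation
            training_set.append(
                TrainingRestriction(
                    stimulus=drug_targets[drug], response=effs, relation=relation
                )
            )
    return SyntheticWorld(
        interactome=net,
        planted_weights=weights,
        effector_sets=effector_sets,
        drug_targets=drug_targets,
        training_set=training_set,
        truth=truth,
        config=cfg,
    )


def recovery_score(
    ensemble,
    world: SyntheticWorld,
    cfg: PropagationConfig | None = None,
) -> float:
    """Fraction of truth pairs whose ensemble-mean fSignal sign matches truth.

    A zero ensemble fSignal matches neither sign, so an untrained all-zero
    model scores 0.
    """
    cfg = cfg or PropagationConfig()
    if not world.truth:
        raise ValueError("world has an empty truth map")
    engine = MatrixPropagator(world.interactome)
    stimuli = [world.drug_targets[d] for d in sorted(world.drug_targets)]
    values, mask = engine.clamp_arrays(stimuli)
    mean_O = np.zeros((engine.n_nodes, len(stimuli)))
    for sol in ensemble.solutions:
        engine.load_weights(sol.weights.vector(engine.edge_order))
        O, _, _ = engine.relax(values, mask, cfg)
        mean_O += O
    mean_O /= len(ensemble.solutions)
    col = {d: j for j, d in enumerate(sorted(world.drug_targets))}
    by_process = {e.process: e for e in world.effector_sets}
    hits = 0
    for (drug, process), true_fs in world.truth.items():
        profile = {p: float(mean_O[i, col[drug]]) for p, i in engine.index.items()}
        fs = fsignal(profile, by_process[process])
        if fs != 0.0 and (fs > 0) == (true_fs > 0):
            hits += 1
    return hits / len(world.truth)


def generate_gmt(
    world: SyntheticWorld,
    n_sets: int = 25,
    size_low: int = 10,
    size_high: int = 30,
    seed: int = 0,
    spike_drug: str | None = None,
    spike_threshold: float = 0.3,
) -> ProteinSetCollection:
    """Random protein sets over the world's nodes, plus one "spiked" set.

    The spiked set collects proteins strongly modulated by one drug's
    planted model (|activity| above ``spike_threshold``), giving the
    enrichment stage a known positive control.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(world.interactome.nodes)
    sets: dict[str, ProteinSet] = {}
    for k in range(n_sets):
        size = int(rng.integers(size_low, size_high + 1))
        members = rng.choice(nodes, size=size, replace=False)
        set_id = f"RAND{k:03d}"
        sets[set_id] = ProteinSet(
            set_id=set_id, name=f"random set {k}", members=frozenset(str(p) for p in members)
        )
    drug = spike_drug or sorted(world.drug_targets)[0]
    stim = world.drug_targets[drug]
    engine, O = _planted_profiles(
        world.interactome, world.planted_weights, [stim], PropagationConfig()
    )
    spiked = [p for p, i in sorted(engine.index.items()) if abs(O[i, 0]) > spike_threshold]
    if len(spiked) > size_high:
        spiked = list(rng.choice(spiked, size=size_high, replace=False))
    if len(spiked) >= 2:
        sets["SPIKED"] = ProteinSet(
            set_id="SPIKED",
            name=f"downstream cone of {drug}",
            members=frozenset(str(p) for p in spiked),
        )
    return ProteinSetCollection(sets=sets, background=frozenset(nodes))


# -- dual-cone world --------------------------------------------------------


@dataclass
class TwoConeWorld:
    """Two disjoint receptor cones converging on shared effectors.

    Symmetric by construction (same topology and a single uniform edge
    weight on both sides), so joint inhibition of both receptors provably
    reverses the shared effectors at least as strongly as inhibiting
    either receptor alone, and inhibiting one receptor while activating
    the other cancels to the weakest reversal.
    """

    interactome: Interactome
    weights: WeightAssignment
    effector_set: EffectorSet
    scenarios: dict[str, Stimulus]


def generate_two_cone_world(
    n_layers: int = 2,
    width: int = 3,
    n_effectors: int = 6,
    weight: float = 0.6,
) -> TwoConeWorld:
    net = Interactome()
    effectors = [f"E{i}" for i in range(n_effectors)]
    for receptor in ("R1", "R2"):
        prev = [receptor]
        for layer in range(n_layers):
            current = [f"{receptor}_L{layer}_{i}" for i in range(width)]
            for u in prev:
                for v in current:
                    net.add_edge(u, v, 1)
            prev = current
        for u in prev:
            for e in effectors:
                net.add_edge(u, e, 1)
    weights = WeightAssignment.uniform(net, weight)
    effector_set = EffectorSet(
        process="shared", members={e: 1 for e in effectors}
    )
    scenarios = {
        "JOINT": Stimulus(name="JOINT", clamps={"R1": -1, "R2": -1}),
        "R1-": Stimulus(name="R1-", clamps={"R1": -1}),
        "R2-": Stimulus(name="R2-", clamps={"R2": -1}),
        "MIXED": Stimulus(name="MIXED", clamps={"R2": -1, "R1": +1}),
    }
    return TwoConeWorld(
        interactome=net,
        weights=weights,
        effector_set=effector_set,
        scenarios=scenarios,
    )


# -- world export -----------------------------------------------------------


def write_world(world: SyntheticWorld, directory: str, gmt_seed: int = 0) -> dict[str, str]:
    """Dump a world in the same file formats the pipeline consumes.

    Returns the mapping of logical names to file paths (network,
    characterization, training, gmt).
    """
    import os

    import yaml

    from .enrichment import write_gmt
    from .interactome import write_edge_list

    os.makedirs(directory, exist_ok=True)
    paths = {
        "network": os.path.join(directory, "network.tsv"),
        "characterization": os.path.join(directory, "characterization.yaml"),
        "training": os.path.join(directory, "training.yaml"),
        "gmt": os.path.join(directory, "sets.gmt"),
    }
    write_edge_list(world.interactome, paths["network"])
    characterization = {
        "processes": {
            e.process: {p: int(w) for p, w in sorted(e.members.items())}
            for e in world.effector_sets
        },
        "drugs": {
            d: {p: int(s) for p, s in sorted(stim.clamps.items())}
            for d, stim in sorted(world.drug_targets.items())
        },
    }
    with open(paths["characterization"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(characterization, fh, sort_keys=True)
    training = [
        {
            "drug": r.stimulus.name,
            "response": r.response.process,
            "relation": "inductive" if r.relation == 1 else "therapeutic",
        }
        for r in world.training_set
    ]
    with open(paths["training"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(training, fh, sort_keys=True)
    write_gmt(generate_gmt(world, seed=gmt_seed), paths["gmt"])
    return paths


DEMO_PRESETS: dict[str, GeneratorConfig] = {
    "demo": GeneratorConfig(
        n_nodes=80, m=2, k_processes=4, effectors_per_process=4,
        n_drugs=6, targets_per_drug=2,
    ),
    "default": GeneratorConfig(),
}


def write_demo_project(directory: str, seed: int = 0, preset: str = "demo") -> str:
    """Generate a world and a ready-to-run pipeline config; returns the
    config path.

    The demo scenario set mirrors the receptor case-study structure: the
    first drug's two targets define a joint-inhibition scenario plus the
    two single-target scenarios and a mixed inhibit-one/activate-other
    scenario, so every analysis stage (comparison, heatmap, path mining)
    has something to chew on.
    """
    import os

    import yaml

    cfg = DEMO_PRESETS[preset]
    cfg = GeneratorConfig(**{**vars(cfg), "seed": seed})
    world = generate_world(cfg)
    paths = write_world(world, directory, gmt_seed=seed)
    drug0 = sorted(world.drug_targets)[0]
    targets = sorted(world.drug_targets[drug0].clamps)
    t1, t2 = targets[0], targets[-1]
    scenarios = [
        {"JOINT": {t1: -1, t2: -1}},
        {"T1-": {t1: -1}},
        {"T2-": {t2: -1}},
        {"MIXED": {t1: -1, t2: 1}},
    ]
    run_config = {
        "network": os.path.basename(paths["network"]),
        "characterization": os.path.basename(paths["characterization"]),
        "training": os.path.basename(paths["training"]),
        "gmt": os.path.basename(paths["gmt"]),
        "output_dir": "out",
        "ensemble_size": 10,
        "base_seed": seed,
        "scenarios": scenarios,
        "reference_scenario": "JOINT",
        "moa": {
            "source": t1,
            "pathway_scenario": "T1-",
            "other_scenario": "T2-",
            "drug_scenario": "JOINT",
            "max_length": 5,
        },
    }
    config_path = os.path.join(directory, "config.yaml")
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)
    return config_path
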