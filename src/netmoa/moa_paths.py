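"""Mechanism-of-action path extraction.

After a model ensemble has been analyzed scenario by scenario, the
mechanism of a single pathway (e.g. VEGFR1 inhibition within a
multi-target drug) is summarized as the set of signed directed paths from
a clamped drug target to the selected effectors that are "active" in a
large fraction of ensemble solutions (default at least 75%).

Effector selection mirrors the scenario analysis: an effector is kept
when the single-pathway scenario reverses its pathological direction, the
difference between the two single-pathway scenarios is at least 0.1 in
predicted activity, and the full drug scenario also reverses it.

A path counts as active in one solution when every edge along it carries
non-negligible weight (>= delta, default 0.01) and the terminal
effector's activity sign in that solution equals the sign implied by the
path algebra (source clamp sign times the product of edge signs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .characterization import EffectorSet, Stimulus
from .interactome import Interactome
from .propagation import ActivityProfile, MatrixPropagator, PropagationConfig

DEFAULT_MIN_FREQUENCY = 0.75
DEFAULT_MAX_LENGTH = 6
DEFAULT_MIN_EDGE_WEIGHT = 0.01
DEFAULT_DIFF_THRESHOLD = 0.1


@dataclass(frozen=True)
class MoAPath:
    """A simple signed path from a drug target to an effector."""

    nodes: tuple[str, ...]
    signs: tuple[int, ...]
    frequency: float

    def __post_init__(self) -> None:
        if len(self.signs) != len(self.nodes) - 1:
            raise ValueError("need exactly one sign per edge")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path must be simple (no repeated node)")
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError("frequency must lie in [0, 1]")

    @property
    def net_sign(self) -> int:
        sign = 1
        for s in self.signs:
            sign *= s
        return sign

    @property
    def effector(self) -> str:
        return self.nodes[-1]


def _activity(profile: ActivityProfile | Mapping[str, float]) -> Mapping[str, float]:
    return profile.activity if isinstance(profile, ActivityProfile) else profile


def select_moa_effectors(
    mean_profiles: Mapping[str, ActivityProfile | Mapping[str, float]],
    effector_sets: Sequence[EffectorSet],
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    pathway_scenario: str = "VEGFR1-",
    other_scenario: str = "VEGFR2-",
    drug_scenario: str = "IAI",
) -> set[str]:
    """Effectors reverted by the pathway of interest.

    Kept iff (a) the pathway scenario flips the effector against its
    pathological sign (nonzero activity), (b) the two single-pathway
    scenarios differ by at least ``diff_threshold`` in predicted
    activity, and (c) the full drug scenario also reverts it.
    """
    for scen in (pathway_scenario, other_scenario, drug_scenario):
        if scen not in mean_profiles:
            raise KeyError(f"scenario {scen!r} missing from profiles")
    act_path = _activity(mean_profiles[pathway_scenario])
    act_other = _activity(mean_profiles[other_scenario])
    act_drug = _activity(mean_profiles[drug_scenario])
    selected: set[str] = set()
    for effs in effector_sets:
        for protein, w in effs.members.items():
            o1 = act_path.get(protein, 0.0)
            o2 = act_other.get(protein, 0.0)
            od = act_drug.get(protein, 0.0)
            reverted_pathway = o1 != 0.0 and (o1 > 0) == (w < 0)
            reverted_drug = od != 0.0 and (od > 0) == (w < 0)
            if reverted_pathway and abs(o1 - o2) >= diff_threshold and reverted_drug:
                selected.add(protein)
    return selected


def path_active_in_solution(
    path: MoAPath,
    solution,
    profile: ActivityProfile | Mapping[str, float],
    source_clamp_sign: int,
    min_edge_weight: float = DEFAULT_MIN_EDGE_WEIGHT,
) -> bool:
    """Weight support plus terminal sign consistency in one solution."""
    weights = solution.weights.weights
    for u, v in zip(path.nodes, path.nodes[1:]):
        if weights[(u, v)] < min_edge_weight:
            return False
    terminal = _activity(profile).get(path.effector, 0.0)
    if terminal == 0.0:
        return False
    expected = source_clamp_sign * path.net_sign
    return (terminal > 0) == (expected > 0)


def extract_moa_paths(
    ensemble,
    net: Interactome,
    source: str,
    effectors: set[str],
    stimulus: Stimulus,
    cfg: PropagationConfig | None = None,
    min_frequency: float = DEFAULT_MIN_FREQUENCY,
    max_length: int = DEFAULT_MAX_LENGTH,
    min_edge_weight: float = DEFAULT_MIN_EDGE_WEIGHT,
) -> list[MoAPath]:
    """High-frequency simple paths source -> effector across the ensemble.

    ``max_length`` caps the number of edges per path.  The source must be
    clamped in the stimulus (the pathway under analysis must actually be
    part of the scenario).
    """
    if source not in stimulus.clamps:
        raise ValueError(
            f"source {source!r} is not clamped in scenario {stimulus.name!r}"
        )
    if source not in net:
        raise KeyError(f"source {source!r} not in network")
    clamp_sign = stimulus.clamps[source]
    cfg = cfg or PropagationConfig()
    # one propagation per solution under the scenario stimulus
    engine = MatrixPropagator(net)
    values, mask = engine.clamp_arrays([stimulus])
    profiles: list[dict[str, float]] = []
    for sol in ensemble.solutions:
        engine.load_weights(sol.weights.vector(engine.edge_order))
        O, _, _ = engine.relax(values, mask, cfg)
        profiles.append({p: float(O[i, 0]) for p, i in engine.index.items()})
    g = net.directed_view()
    n_solutions = len(ensemble.solutions)
    out: list[MoAPath] = []
    for effector in sorted(effectors):
        if effector not in net:
            continue
        for nodes in nx.all_simple_paths(g, source, effector, cutoff=max_length):
            signs = tuple(net.sign(u, v) for u, v in zip(nodes, nodes[1:]))
            candidate = MoAPath(nodes=tuple(nodes), signs=signs, frequency=0.0)
            active = sum(
                path_active_in_solution(
                    candidate, sol, prof, clamp_sign, min_edge_weight
                )
                for sol, prof in zip(ensemble.solutions, profiles)
            )
            frequency = active / n_solutions
            if frequency >= min_frequency:
                out.append(
                    MoAPath(nodes=tuple(nodes), signs=signs, frequency=frequency)
                )
    out.sort(key=lambda p: (-p.frequency, len(p.nodes), p.nodes))
    return out


def paths_to_dot(
    paths: Sequence[MoAPath],
    modulation: Mapping[str, float] | ActivityProfile | None = None,
    title: str = "moa",
) -> str:
    """GraphViz DOT rendering of the retained paths.

    Nodes are colored by modulation sign (green activated, red inhibited,
    intensity by magnitude); edges are labeled with their sign and the
    maximum frequency of any retained path using them.
    """
    act = _activity(modulation) if modulation is not None else {}
    nodes: dict[str, float] = {}
    edge_info: dict[tuple[str, str], tuple[int, float]] = {}
    for path in paths:
        for node in path.nodes:
            nodes.setdefault(node, act.get(node, 0.0))
        for (u, v), s in zip(zip(path.nodes, path.nodes[1:]), path.signs):
            prev = edge_info.get((u, v))
            freq = path.frequency if prev is None else max(prev[1], path.frequency)
            edge_info[(u, v)] = (s, freq)
    lines = [f'digraph "{title}" {{', "  rankdir=LR;", "  node [style=filled];"]
    for node in sorted(nodes):
        value = nodes[node]
        intensity = int(round(min(abs(value), 1.0) * 155)) + 100 if value else 0
        if value > 0:
            color = f'"#00{intensity:02x}00"'
        elif value < 0:
            color = f'"#{intensity:02x}0000"'
        else:
            color = '"#c0c0c0"'
        lines.append(
            f'  "{node}" [fillcolor={color}, fontcolor=white, '
            f'tooltip="activity={value:.3f}"];'
        )
    for (u, v) in sorted(edge_info):
        sign, freq = edge_info[(u, v)]
        arrow = "normal" if sign == 1 else "tee"
        lines.append(
            f'  "{u}" -> "{v}" [arrowhead={arrow}, label="{"+" if sign == 1 else "-"} '
            f'{freq:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_paths_table(paths: Sequence[MoAPath], path: str) -> None:
    """Flat TSV of the retained paths."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("path\tsigns\tnet_sign\tfrequency\tlength\n")
        for p in paths:
            fh.write(
                "->".join(p.nodes)
                + "\t"
                + ",".join("+" if s == 1 else "-" for s in p.signs)
                + f"\t{p.net_sign}\t{p.frequency:.10g}\t{len(p.nodes) - 1}\n"
            )
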