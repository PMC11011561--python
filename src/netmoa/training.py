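"""Weight training by simulated annealing and ensemble sampling.

A training restriction pairs a stimulus with a response effector set and a
relation: therapeutic (-1, the stimulus should reverse the set's
pathological pattern, i.e. fSignal < 0) or inductive (+1, the stimulus
should reproduce it, fSignal > 0).  A restriction is satisfied when the
fSignal under the stimulus has the required sign and magnitude at least
tau (default 0.1); fSignal exactly 0 satisfies neither relation.

The energy minimized by the annealer is

    E(w) = (1 - accuracy) + lambda * mean_r |relation_r - fSignal_r| / 2,

where accuracy is the satisfied fraction and the second term is a
continuous tie-breaker scaled by lambda = 0.5/|T| so that it can reorder
weight vectors within an accuracy plateau but never trade away a satisfied
restriction.  Moves perturb one uniformly chosen edge weight by a Gaussian
step clipped to [0, 1]; acceptance is Metropolis with geometric cooling.
The best-seen state, not the final one, is returned.

The weight space is typically underdetermined (far more edges than
restrictions), so independently seeded runs yield distinct, equally valid
solutions; an ensemble of them is the object all downstream analyses
consume.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .analysis import fsignal
from .characterization import EffectorSet, Stimulus
from .interactome import Interactome
from .propagation import (
    ActivityProfile,
    MatrixPropagator,
    PropagationConfig,
    WeightAssignment,
)

DEFAULT_TAU = 0.1
"""Minimum |fSignal| for a restriction to count as satisfied."""


@dataclass(frozen=True)
class TrainingRestriction:
    stimulus: Stimulus
    response: EffectorSet
    relation: int  # -1 therapeutic, +1 inductive

    def __post_init__(self) -> None:
        if self.relation not in (-1, 1):
            raise ValueError(f"relation must be -1 or +1, got {self.relation!r}")


@dataclass
class AnnealSchedule:
    initial_temperature: float = 0.05
    cooling_factor: float = 0.85
    steps_per_temperature: int = 150
    min_temperature: float = 5e-5
    move_scale: float = 0.3
    cycles: int = 3  # cooling cycles; reheating escapes accuracy plateaus

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.initial_temperature <= 0 or self.min_temperature <= 0:
            raise ValueError("temperatures must be positive")
        if not (0 < self.cooling_factor < 1):
            raise ValueError("cooling_factor must lie in (0, 1)")
        if self.steps_per_temperature < 1:
            raise ValueError("steps_per_temperature must be >= 1")
        if self.move_scale <= 0:
            raise ValueError("move_scale must be positive")
        if self.min_temperature > self.initial_temperature:
            raise ValueError("min_temperature exceeds initial_temperature")


@dataclass
class ModelSolution:
    weights: WeightAssignment
    accuracy: float
    seed: int


@dataclass
class Ensemble:
    solutions: list[ModelSolution]

    @property
    def size(self) -> int:
        return len(self.solutions)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([s.accuracy for s in self.solutions])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def min_accuracy(self) -> float:
        return float(self.accuracies.min())


def restriction_satisfied(
    profile: ActivityProfile,
    r: TrainingRestriction,
    tau: float = DEFAULT_TAU,
) -> bool:
    """Sign of fSignal matches the relation and |fSignal| >= tau."""
    fs = fsignal(profile, r.response)
    if fs == 0.0:
        return False
    return (fs > 0) == (r.relation > 0) and abs(fs) >= tau


class RestrictionEvaluator:
    """Precompiled, vectorized evaluation of a restriction set.

    All distinct stimuli become columns of one activity matrix, so a full
    energy evaluation costs a single damped relaxation regardless of the
    number of restrictions.
    """

    def __init__(
        self,
        net: Interactome,
        restrictions: Sequence[TrainingRestriction],
        cfg: PropagationConfig | None = None,
        tau: float = DEFAULT_TAU,
    ) -> None:
        self.cfg = cfg or PropagationConfig()
        # annealing moves are scored at a looser fixed-point tolerance (the
        # search only needs fSignal signs and coarse magnitudes); reported
        # accuracies always come from a strict re-evaluation
        self.train_cfg = PropagationConfig(
            max_iterations=self.cfg.max_iterations,
            tolerance=max(self.cfg.tolerance, 1e-4),
            damping=self.cfg.damping,
        )
        self.tau = tau
        self.engine = MatrixPropagator(net)
        self.restrictions = list(restrictions)
        stimuli: list[Stimulus] = []
        keys: dict[tuple, int] = {}
        self._stim_col: list[int] = []
        for r in self.restrictions:
            key = tuple(sorted(r.stimulus.clamps.items()))
            if key not in keys:
                keys[key] = len(stimuli)
                stimuli.append(r.stimulus)
            self._stim_col.append(keys[key])
        self.stimuli = stimuli
        self._clamp_values, self._clamp_mask = self.engine.clamp_arrays(stimuli)
        self._eff_idx = []
        self._eff_w = []
        for r in self.restrictions:
            missing = [p for p in r.response.members if p not in self.engine.index]
            if missing:
                raise KeyError(
                    f"restriction response {r.response.process!r} names proteins "
                    f"absent from the interactome: {sorted(missing)}"
                )
            proteins = sorted(r.response.members)
            self._eff_idx.append(
                np.array([self.engine.index[p] for p in proteins], dtype=np.intp)
            )
            self._eff_w.append(
                np.array([r.response.members[p] for p in proteins], dtype=float)
            )
        self._relations = np.array([r.relation for r in self.restrictions], dtype=float)
        self.n_edges = len(self.engine.edge_order)

    def fsignals(self, weights: np.ndarray) -> np.ndarray:
        self.engine.load_weights(weights)
        O, _, _ = self.engine.relax(self._clamp_values, self._clamp_mask, self.cfg)
        return self._fsignals_from(O)

    def _fsignals_from(self, O: np.ndarray) -> np.ndarray:
        out = np.empty(len(self.restrictions))
        for i, (col, idx, w) in enumerate(zip(self._stim_col, self._eff_idx, self._eff_w)):
            out[i] = float(w @ O[idx, col]) / len(idx)
        return out

    def accuracy(self, fsignals: np.ndarray) -> float:
        satisfied = (
            (np.sign(fsignals) == self._relations) & (np.abs(fsignals) >= self.tau)
        )
        return float(satisfied.mean())

    def energy(self, weights: np.ndarray) -> tuple[float, float]:
        """(energy, accuracy) for a weight vector at strict tolerance."""
        energy, acc, _ = self.energy_warm(weights, None, strict=True)
        return energy, acc

    def energy_warm(
        self,
        weights: np.ndarray,
        initial: np.ndarray | None,
        strict: bool = False,
    ) -> tuple[float, float, np.ndarray]:
        """Energy with an optional warm start for the fixed-point relaxation.

        Returns (energy, accuracy, converged activity matrix) so callers
        can chain warm starts across single-edge moves.
        """
        self.engine.load_weights(weights)
        O, _, _ = self.engine.relax(
            self._clamp_values,
            self._clamp_mask,
            self.cfg if strict else self.train_cfg,
            initial=initial,
        )
        fs = self._fsignals_from(O)
        acc = self.accuracy(fs)
        secondary = float(np.mean(np.abs(self._relations - fs))) / 2.0
        lam = 0.5 / len(self.restrictions)
        return (1.0 - acc) + lam * secondary, acc, O


def training_accuracy(
    net: Interactome,
    w: WeightAssignment,
    restrictions: Sequence[TrainingRestriction],
    cfg: PropagationConfig | None = None,
    tau: float = DEFAULT_TAU,
) -> float:
    """Fraction of restrictions satisfied by a weight assignment."""
    if not restrictions:
        warnings.warn("empty training set: accuracy is trivially 1.0", UserWarning)
        return 1.0
    ev = RestrictionEvaluator(net, restrictions, cfg, tau)
    w.validate_against(net)
    return ev.accuracy(ev.fsignals(w.vector(ev.engine.edge_order)))


def anneal(
    net: Interactome,
    restrictions: Sequence[TrainingRestriction],
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    cfg: PropagationConfig | None = None,
    tau: float = DEFAULT_TAU,
    _evaluator: RestrictionEvaluator | None = None,
) -> ModelSolution:
    """Simulated-annealing fit of edge weights to the restriction set.

    Fully deterministic given (inputs, seed): the seed fixes the initial
    weights, the move proposals and the acceptance draws.
    """
    schedule = schedule or AnnealSchedule()
    ev = _evaluator or RestrictionEvaluator(net, restrictions, cfg, tau)
    rng = np.random.default_rng(seed)
    # weak-signal start: small initial weights keep the tanh responses out
    # of saturation so early moves see a usable energy gradient
    weights = rng.uniform(0.0, 0.5, size=ev.n_edges)
    energy, acc, state = ev.energy_warm(weights, None)
    best_weights = weights.copy()
    best_energy = energy
    done = False
    for _cycle in range(schedule.cycles):
        temperature = schedule.initial_temperature
        while temperature >= schedule.min_temperature and not done:
            for _ in range(schedule.steps_per_temperature):
                j = int(rng.integers(ev.n_edges))
                old = weights[j]
                proposal = float(
                    np.clip(old + rng.normal(0.0, schedule.move_scale), 0.0, 1.0)
                )
                weights[j] = proposal
                new_energy, new_acc, new_state = ev.energy_warm(weights, state)
                delta = new_energy - energy
                if delta <= 0 or rng.random() < np.exp(-delta / temperature):
                    energy, acc, state = new_energy, new_acc, new_state
                    if energy < best_energy:
                        best_energy = energy
                        best_weights = weights.copy()
                        if acc >= 1.0:
                            # all restrictions satisfied; further cooling can
                            # only polish the tie-break term
                            done = True
                            break
                else:
                    weights[j] = old
            temperature *= schedule.cooling_factor
        if done:
            break
    # report the accuracy of the returned weights from a cold-started,
    # strict-tolerance relaxation, so the stored value is exactly what
    # training_accuracy() recomputes
    _, best_acc, _ = ev.energy_warm(best_weights, None, strict=True)
    assignment = WeightAssignment(
        {e: float(v) for e, v in zip(ev.engine.edge_order, best_weights)}
    )
    return ModelSolution(weights=assignment, accuracy=best_acc, seed=seed)


def sample_ensemble(
    net: Interactome,
    restrictions: Sequence[TrainingRestriction],
    schedule: AnnealSchedule | None = None,
    n_solutions: int = 250,
    base_seed: int = 0,
    cfg: PropagationConfig | None = None,
    tau: float = DEFAULT_TAU,
) -> Ensemble:
    """Anneal with seeds base_seed .. base_seed + n - 1 and pool the solutions."""
    if n_solutions < 1:
        raise ValueError("n_solutions must be >= 1")
    ev = RestrictionEvaluator(net, restrictions, cfg, tau)
    solutions = [
        anneal(net, restrictions, schedule, seed=base_seed + k, cfg=cfg, tau=tau,
               _evaluator=ev)
        for k in range(n_solutions)
    ]
    return Ensemble(solutions=solutions)


# -- ensemble archive ------------------------------------------------------


def save_ensemble(ensemble: Ensemble, directory: str) -> None:
    """Directory of per-solution TSV weight files plus a JSON manifest."""
    os.makedirs(directory, exist_ok=True)
    manifest = []
    for k, sol in enumerate(ensemble.solutions):
        fname = f"solution_{k:04d}.tsv"
        with open(os.path.join(directory, fname), "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\n")
            for (u, v), w in sorted(sol.weights.weights.items()):
                fh.write(f"{u}\t{v}\t{w!r}\n")
        manifest.append({"file": fname, "seed": sol.seed, "accuracy": sol.accuracy})
    with open(os.path.join(directory, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump({"solutions": manifest}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_ensemble(directory: str) -> Ensemble:
    with open(os.path.join(directory, "manifest.json"), encoding="utf-8") as fh:
        manifest = json.load(fh)
    solutions = []
    for rec in manifest["solutions"]:
        weights: dict[tuple[str, str], float] = {}
        with open(os.path.join(directory, rec["file"]), encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                u, v, w = line.rstrip("\n").split("\t")
                weights[(u, v)] = float(w)
        solutions.append(
            ModelSolution(
                weights=WeightAssignment(weights),
                accuracy=float(rec["accuracy"]),
                seed=int(rec["seed"]),
            )
        )
    return Ensemble(solutions=solutions)
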