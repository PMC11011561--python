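"""Signal propagation over the signed interactome.

Every node computes the hyperbolic tangent of the signed, weighted sum of
its incoming signals, mimicking a multilayer-perceptron forward pass laid
over the protein network: for node n with incoming edges (m -> n) carrying
sign s_mn and weight w_mn,

    o_n = tanh( sum_m  o_m * s_mn * w_mn ).

Stimulus nodes are hard-clamped to their stimulus value (+1 activated / -1
inhibited) and ignore incoming signal.  Because the interactome may contain
cycles, the network is relaxed to a fixed point by damped synchronous
iteration from the all-zero state:

    o <- (1 - alpha) * o + alpha * tanh(A o),   clamps reimposed each step,

which on an acyclic graph converges to exactly the layer-by-layer forward
evaluation.  Nodes unreachable from any clamped node stay exactly 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .characterization import Stimulus
from .interactome import Interactome


@dataclass
class PropagationConfig:
    max_iterations: int = 200
    tolerance: float = 1e-6
    damping: float = 0.5

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must lie in (0, 1]")


@dataclass
class WeightAssignment:
    """One weight in [0, 1] per interactome edge (sign lives on the edge)."""

    weights: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for edge, w in self.weights.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"weight for edge {edge} out of [0, 1]: {w}")

    def validate_against(self, net: Interactome) -> None:
        edges = {(u, v) for u, v, _ in net.edges}
        missing = edges - set(self.weights)
        extra = set(self.weights) - edges
        if missing or extra:
            raise ValueError(
                f"weight assignment does not match interactome "
                f"(missing {len(missing)}, extra {len(extra)} edges)"
            )

    def vector(self, edge_order: Sequence[tuple[str, str]]) -> np.ndarray:
        return np.array([self.weights[e] for e in edge_order], dtype=float)

    @classmethod
    def uniform(cls, net: Interactome, value: float) -> "WeightAssignment":
        return cls({(u, v): value for u, v, _ in net.edges})


@dataclass
class ActivityProfile:
    """Predicted protein activity o in [-1, 1] per protein."""

    activity: dict[str, float]
    stimulus: Stimulus
    converged: bool
    iterations: int

    def __getitem__(self, protein: str) -> float:
        return self.activity[protein]

    def __contains__(self, protein: str) -> bool:
        return protein in self.activity

    def as_series(self) -> pd.Series:
        return pd.Series(self.activity, name="activity").sort_index()


class NonConvergenceWarning(UserWarning):
    pass


def node_output(inputs: Iterable[tuple[float, int, float]]) -> float:
    """tanh of the signed weighted input sum; an input-less node outputs 0.

    ``inputs`` is a list of (upstream activity, edge sign, edge weight).
    """
    total = 0.0
    for o, s, w in inputs:
        total += o * s * w
    return math.tanh(total)


class MatrixPropagator:
    """Vectorized fixed-point engine bound to one interactome.

    Node and edge order are the sorted orders, so results are deterministic
    and reproducible across runs.  Reused by the trainer, which evaluates
    many stimuli as columns of a single activity matrix.
    """

    def __init__(self, net: Interactome) -> None:
        self.net = net
        self.nodes: list[str] = net.sorted_nodes()
        self.index: dict[str, int] = {p: i for i, p in enumerate(self.nodes)}
        self.edge_order: list[tuple[str, str]] = [(u, v) for u, v, _ in net.sorted_edges()]
        edges = net.sorted_edges()
        self._src = np.array([self.index[u] for u, _, _ in edges], dtype=np.intp)
        self._tgt = np.array([self.index[v] for _, v, _ in edges], dtype=np.intp)
        self._sign = np.array([s for _, _, s in edges], dtype=float)
        n = len(self.nodes)
        self._A = np.zeros((n, n), dtype=float)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def load_weights(self, w: np.ndarray) -> None:
        """Install an edge-weight vector (in ``edge_order``) into the matrix."""
        self._A[self._tgt, self._src] = self._sign * w

    def update_weight(self, edge_index: int, value: float) -> None:
        self._A[self._tgt[edge_index], self._src[edge_index]] = (
            self._sign[edge_index] * value
        )

    def clamp_arrays(self, stimuli: Sequence[Stimulus]) -> tuple[np.ndarray, np.ndarray]:
        """Per-stimulus clamp value matrix (n x S) and boolean mask."""
        n, S = self.n_nodes, len(stimuli)
        values = np.zeros((n, S), dtype=float)
        mask = np.zeros((n, S), dtype=bool)
        for j, stim in enumerate(stimuli):
            for protein, value in stim.clamps.items():
                if protein not in self.index:
                    raise KeyError(
                        f"stimulus {stim.name!r} clamps unknown protein {protein!r}"
                    )
                i = self.index[protein]
                values[i, j] = value
                mask[i, j] = True
        return values, mask

    def relax(
        self,
        clamp_values: np.ndarray,
        clamp_mask: np.ndarray,
        cfg: PropagationConfig,
        initial: np.ndarray | None = None,
    ) -> tuple[np.ndarray, bool, int]:
        """Damped synchronous iteration to a fixed point from the zero state.

        ``initial`` warm-starts the iteration (used by the trainer, where
        consecutive weight vectors differ in a single edge and the fixed
        point barely moves); the converged result is within tolerance of
        the cold-started one.

        Returns (activity matrix n x S, converged, iterations used).
        """
        alpha = cfg.damping
        if initial is None:
            O = np.where(clamp_mask, clamp_values, 0.0)
        else:
            O = np.where(clamp_mask, clamp_values, initial)
        iterations = 0
        converged = False
        for iterations in range(1, cfg.max_iterations + 1):
            new = (1.0 - alpha) * O + alpha * np.tanh(self._A @ O)
            np.copyto(new, clamp_values, where=clamp_mask)
            delta = np.max(np.abs(new - O)) if O.size else 0.0
            O = new
            if delta < cfg.tolerance:
                converged = True
                break
        return O, converged, iterations


def propagate(
    net: Interactome,
    w: WeightAssignment,
    stim: Stimulus,
    cfg: PropagationConfig | None = None,
) -> ActivityProfile:
    """Propagate a stimulus through the weighted network to a fixed point.

    Non-convergence within ``cfg.max_iterations`` yields a profile with
    ``converged=False`` and a :class:`NonConvergenceWarning`, not an error.
    """
    cfg = cfg or PropagationConfig()
    w.validate_against(net)
    engine = MatrixPropagator(net)
    engine.load_weights(w.vector(engine.edge_order))
    values, mask = engine.clamp_arrays([stim])
    O, converged, iterations = engine.relax(values, mask, cfg)
    if not converged:
        warnings.warn(
            f"propagation of stimulus {stim.name!r} did not converge within "
            f"{cfg.max_iterations} iterations",
            NonConvergenceWarning,
            stacklevel=2,
        )
    activity = {p: float(O[i, 0]) for p, i in engine.index.items()}
    return ActivityProfile(
        activity=activity, stimulus=stim, converged=converged, iterations=iterations
    )


def write_profile(profile: ActivityProfile, path: str) -> None:
    """TSV export: protein, activity, clamped flag."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\tactivity\tclamped\n")
        for protein in sorted(profile.activity):
            clamped = protein in profile.stimulus.clamps
            fh.write(f"{protein}\t{profile.activity[protein]:.10g}\t{int(clamped)}\n")
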