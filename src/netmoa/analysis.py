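"""Ensemble-level activity, the fSignal statistic, scenario comparison and
heatmap matrix construction.

fSignal summarizes the effect of a stimulus on a pathophysiological
process: for a response set of n effectors with pathological directions
w_i and predicted activities o_i,

    fSignal = (1/n) * sum_i w_i * o_i,

so fSignal = +1 means the process is fully driven into its pathological
pattern and fSignal = -1 means complete reversal (therapeutic impact).
Because fSignal is linear in the activities, the mean over ensemble
solutions of per-solution fSignal equals the fSignal of the ensemble-mean
profile; both routes are exposed and cross-checked in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .characterization import EffectorSet, Stimulus
from .interactome import Interactome
from .propagation import (
    ActivityProfile,
    MatrixPropagator,
    PropagationConfig,
    WeightAssignment,
)

FDR_FLAG_THRESHOLD = 0.005  # q-value below which a scenario difference is flagged
MEAN_DIFF_SPLIT = 0.1  # |mean difference| separating "*" from "**"


def fsignal(profile: ActivityProfile | Mapping[str, float], effs: EffectorSet) -> float:
    """Eq.-style mean of w_i * o_i over the effector set.

    Raises ``KeyError`` for effectors absent from the profile — silence
    here would bias the mean toward zero.
    """
    activity = profile.activity if isinstance(profile, ActivityProfile) else profile
    missing = [p for p in effs.members if p not in activity]
    if missing:
        raise KeyError(
            f"effectors of process {effs.process!r} absent from profile: {sorted(missing)}"
        )
    total = sum(w * activity[p] for p, w in effs.members.items())
    return total / len(effs.members)


@dataclass
class EnsembleActivity:
    """Ensemble-mean profile plus the per-solution profiles behind it."""

    mean_profile: ActivityProfile
    profiles: list[ActivityProfile]


def ensemble_activity(
    ensemble,
    net: Interactome,
    stim: Stimulus,
    cfg: PropagationConfig | None = None,
) -> EnsembleActivity:
    """Per-protein arithmetic mean of per-solution propagated activities."""
    cfg = cfg or PropagationConfig()
    solutions = list(ensemble.solutions)
    if not solutions:
        raise ValueError("ensemble is empty")
    engine = MatrixPropagator(net)
    values, mask = engine.clamp_arrays([stim])
    profiles: list[ActivityProfile] = []
    stack = np.zeros((engine.n_nodes, len(solutions)))
    for k, sol in enumerate(solutions):
        engine.load_weights(sol.weights.vector(engine.edge_order))
        O, converged, iterations = engine.relax(values, mask, cfg)
        stack[:, k] = O[:, 0]
        profiles.append(
            ActivityProfile(
                activity={p: float(O[i, 0]) for p, i in engine.index.items()},
                stimulus=stim,
                converged=converged,
                iterations=iterations,
            )
        )
    mean_vec = stack.mean(axis=1)
    mean_profile = ActivityProfile(
        activity={p: float(mean_vec[i]) for p, i in engine.index.items()},
        stimulus=stim,
        converged=all(p.converged for p in profiles),
        iterations=max(p.iterations for p in profiles),
    )
    return EnsembleActivity(mean_profile=mean_profile, profiles=profiles)


@dataclass
class FSignalDistribution:
    """Per-solution fSignal values for one (process, scenario) pair."""

    process: str
    scenario: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("fSignal values must lie in [-1, 1]")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def fsignal_distribution(
    profiles: Sequence[ActivityProfile | Mapping[str, float]],
    effs: EffectorSet,
    scenario: str,
) -> FSignalDistribution:
    return FSignalDistribution(
        process=effs.process,
        scenario=scenario,
        values=np.array([fsignal(p, effs) for p in profiles]),
    )


@dataclass
class ComparisonResult:
    process: str
    scenario: str
    u_statistic: float
    p_value: float
    q_value: float
    mean_difference: float
    flag: str  # "", "*", or "**"


def compare_scenarios(
    distributions: Mapping[tuple[str, str], FSignalDistribution],
    reference_scenario: str,
) -> list[ComparisonResult]:
    """Mann–Whitney U of each (process, scenario) against the reference.

    Two-sided; exact null distribution for ensembles smaller than 20
    solutions, normal approximation with tie correction otherwise.  BH
    correction spans all (process x non-reference scenario) comparisons in
    the batch.  Flags: "*" for q < 0.005 with |mean difference| < 0.1
    against the reference, "**" for q < 0.005 with |mean difference| >= 0.1.
    """
    references = {
        proc: dist
        for (proc, scen), dist in distributions.items()
        if scen == reference_scenario
    }
    if not references:
        raise KeyError(f"reference scenario {reference_scenario!r} not in distributions")
    comparisons = [
        (proc, scen, dist)
        for (proc, scen), dist in sorted(distributions.items())
        if scen != reference_scenario
    ]
    results: list[ComparisonResult] = []
    pvalues: list[float] = []
    for proc, scen, dist in comparisons:
        if proc not in references:
            raise KeyError(f"process {proc!r} missing from reference scenario")
        ref = references[proc]
        if len(dist.values) != len(ref.values):
            raise ValueError("all distributions must have one value per solution")
        if len(dist.values) < 2:
            raise ValueError("ensemble size must be >= 2 for scenario statistics")
        method = "exact" if len(dist.values) < 20 else "asymptotic"
        try:
            stat = mannwhitneyu(dist.values, ref.values, alternative="two-sided", method=method)
        except ValueError:
            # exact method refuses ties; fall back to the tie-corrected normal
            stat = mannwhitneyu(
                dist.values, ref.values, alternative="two-sided", method="asymptotic"
            )
        results.append(
            ComparisonResult(
                process=proc,
                scenario=scen,
                u_statistic=float(stat.statistic),
                p_value=float(stat.pvalue),
                q_value=float("nan"),
                mean_difference=dist.mean - ref.mean,
                flag="",
            )
        )
        pvalues.append(float(stat.pvalue))
    if results:
        _, qvalues, _, _ = multipletests(pvalues, method="fdr_bh")
        for res, q in zip(results, qvalues):
            res.q_value = float(q)
            if q < FDR_FLAG_THRESHOLD:
                res.flag = "**" if abs(res.mean_difference) >= MEAN_DIFF_SPLIT else "*"
    return results


@dataclass
class HeatmapMatrix:
    """Effector-by-scenario mean activity matrix after the 0.1 filter.

    ``matrix`` rows are (process, protein) pairs; ``row_order`` gives the
    hierarchical ordering (Euclidean distance, complete linkage).
    """

    matrix: pd.DataFrame  # index: MultiIndex (process, protein); columns: scenarios
    annotations: pd.DataFrame  # process, protein, pathological_sign
    row_order: list[int]

    @property
    def ordered(self) -> pd.DataFrame:
        return self.matrix.iloc[self.row_order]


def heatmap_matrix(
    mean_profiles: Mapping[str, ActivityProfile | Mapping[str, float]],
    effector_sets: Sequence[EffectorSet],
    threshold: float = 0.1,
) -> HeatmapMatrix:
    """Build the effector-activity heatmap matrix across scenarios.

    Rows with max over scenarios of |activity| < threshold are dropped
    (the |activity| = threshold boundary is kept).
    """
    if not mean_profiles:
        raise ValueError("need at least one scenario profile")
    scenarios = list(mean_profiles)
    rows = []
    for effs in effector_sets:
        for protein, w in sorted(effs.members.items()):
            values = []
            for scen in scenarios:
                prof = mean_profiles[scen]
                activity = prof.activity if isinstance(prof, ActivityProfile) else prof
                if protein not in activity:
                    raise KeyError(f"effector {protein!r} absent from scenario {scen!r}")
                values.append(activity[protein])
            if max(abs(v) for v in values) >= threshold:
                rows.append((effs.process, protein, w, values))
    if not rows:
        warnings.warn("all effectors fell below the activity threshold", UserWarning)
        empty = pd.DataFrame(
            columns=scenarios,
            index=pd.MultiIndex.from_arrays([[], []], names=["process", "protein"]),
        )
        return HeatmapMatrix(
            matrix=empty,
            annotations=pd.DataFrame(columns=["process", "protein", "pathological_sign"]),
            row_order=[],
        )
    index = pd.MultiIndex.from_arrays(
        [[r[0] for r in rows], [r[1] for r in rows]], names=["process", "protein"]
    )
    matrix = pd.DataFrame([r[3] for r in rows], index=index, columns=scenarios)
    annotations = pd.DataFrame(
        {
            "process": [r[0] for r in rows],
            "protein": [r[1] for r in rows],
            "pathological_sign": [r[2] for r in rows],
        }
    )
    if len(rows) > 1:
        Z = linkage(matrix.to_numpy(), method="complete", metric="euclidean")
        row_order = [int(i) for i in leaves_list(Z)]
    else:
        row_order = [0]
    return HeatmapMatrix(matrix=matrix, annotations=annotations, row_order=row_order)


def write_fsignal_table(
    distributions: Mapping[tuple[str, str], FSignalDistribution],
    results: Sequence[ComparisonResult],
    path: str,
    reference_scenario: str,
) -> None:
    """TSV: process, scenario, mean fSignal, q-value, flag."""
    by_key = {(r.process, r.scenario): r for r in results}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("process\tscenario\tmean_fsignal\tq_value\tflag\n")
        for (proc, scen), dist in sorted(distributions.items()):
            res = by_key.get((proc, scen))
            q = "" if res is None else f"{res.q_value:.6g}"
            flag = "" if res is None else res.flag
            fh.write(f"{proc}\t{scen}\t{dist.mean:.10g}\t{q}\t{flag}\n")


def write_heatmap_matrix(hm: HeatmapMatrix, path: str) -> None:
    """TSV export of the ordered heatmap matrix with annotation columns."""
    ordered = hm.ordered
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("process\tprotein\tpathological_sign\t" + "\t".join(ordered.columns) + "\n")
        ann = hm.annotations.iloc[hm.row_order] if len(hm.row_order) else hm.annotations
        for (idx, row), (_, arow) in zip(ordered.iterrows(), ann.iterrows()):
            cells = "\t".join(f"{v:.10g}" for v in row.to_numpy())
            fh.write(f"{idx[0]}\t{idx[1]}\t{arow['pathological_sign']}\t{cells}\n")


def render_heatmap(hm: HeatmapMatrix, path: str) -> None:
    """Optional PNG rendering (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = hm.ordered
    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * len(ordered.columns), 1 + 0.25 * len(ordered))
    )
    im = ax.imshow(ordered.to_numpy(), cmap="RdYlGn", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(ordered)), [f"{p} ({pr})" for pr, p in ordered.index])
    fig.colorbar(im, ax=ax, label="mean predicted activity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
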