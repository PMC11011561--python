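# netmoa

In-silico mechanism-of-action (MoA) modeling on signed protein
interaction networks.

Drugs rarely act through a single linear pathway: a multi-target drug
perturbs several receptors whose signals spread through the protein
interaction network and converge on the effector proteins of a disease.
`netmoa` is a library (plus a thin CLI) for systems biologists who want
to model that spread quantitatively: it propagates target-level stimuli
through a signed, directed interactome, trains the network's edge
weights against known drug–condition relationships, and mines the
resulting model ensemble for the pathways that explain the drug's
therapeutic effect. The bundled case-study fixtures follow the
VEGF-receptor biology of anti-VEGF therapy (targets VEGFA, VEGFB, PGF,
LGALS1, FLT1/VEGFR1, KDR/VEGFR2) in diabetic macular edema, but every
component is generic over any signed interactome and disease
characterization.

## The model

Nodes are proteins with activity o ∈ [−1, 1] (−1 completely inhibited,
+1 completely activated); edges carry a sign s ∈ {−1, +1} and a trained
weight ω ∈ [0, 1]. A node's activity is the perceptron-like update

    o_n = tanh( Σ_m o_m · s_mn · ω_mn ),

iterated (with damping) to a fixed point while drug-target nodes are
clamped at their stimulus value. The impact on a pathophysiological
process with effectors i = 1..n, pathological directions w_i ∈ {−1, +1},
is the mean reversal score

    fSignal = (1/n) Σ_i w_i · o_i   ∈ [−1, 1],

−1 meaning complete reversal of the pathological pattern. Weights are
fitted by simulated annealing so that training restrictions
(stimulus → response relations: therapeutic or inductive) are satisfied;
since many weight assignments fit the data, an ensemble of independently
seeded solutions is the model. Downstream analyses: Mann–Whitney/BH
scenario comparison of fSignal distributions, effector heatmap matrices,
hypergeometric enrichment of strongly modulated proteins with
Hausdorff-distance clustering of the enriched sets on the network, and
extraction of high-frequency signed paths from a target to selected
effectors. See `docs/methods.md` for the full account.

## Worked example

Everything runs on self-contained synthetic worlds — a scale-free signed
interactome with planted edge weights and forward-simulated training
restrictions — so the whole workflow is reproducible offline:

```python
from netmoa import (GeneratorConfig, generate_world, sample_ensemble,
                    recovery_score, ensemble_activity, fsignal)

world = generate_world(GeneratorConfig(
    n_nodes=80, k_processes=4, effectors_per_process=4,
    n_drugs=6, targets_per_drug=2, seed=7))
ens = sample_ensemble(world.interactome, world.training_set,
                      n_solutions=10, base_seed=0)
print(f"ensemble: {ens.size} solutions, mean training accuracy {ens.mean_accuracy:.3f}")
print(f"truth-sign recovery: {recovery_score(ens, world):.2f}")
drug = sorted(world.drug_targets)[0]
ea = ensemble_activity(ens, world.interactome, world.drug_targets[drug])
for effs in world.effector_sets:
    print(f"fSignal[{drug}, {effs.process}] = {fsignal(ea.mean_profile, effs):+.3f}")
```

prints (about ten seconds on one CPU):

```
ensemble: 10 solutions, mean training accuracy 1.000
truth-sign recovery: 1.00
fSignal[drug00, process0] = -0.053
fSignal[drug00, process1] = +0.016
fSignal[drug00, process2] = +0.043
fSignal[drug00, process3] = -0.227
```

The ensemble satisfies every training restriction (accuracy 1.000) and
recovers the planted sign of every held drug–process relationship
(recovery 1.00). The fSignal lines read: inhibiting drug00's two targets
reverses the pathological pattern of process3 markedly (−0.227) and
process0 mildly, while barely touching processes 1–2 — exactly the kind
of per-process impact profile the heatmap and path-mining stages then
dissect.

The same workflow as a shell pipeline:

```sh
netmoa synth --preset demo --out demo --seed 0   # world + config.yaml
netmoa run --config demo/config.yaml             # full pipeline
```

which writes per-scenario activity TSVs, the fSignal table with
comparison flags, the heatmap matrix, enrichment tables and network, the
MoA path table with a GraphViz DOT rendering, and a `manifest.json`
recording seeds, thresholds and per-stage counts. Re-running with the
same config is byte-identical.

## Layout

| module | contents |
| --- | --- |
| `netmoa.interactome` | signed digraph container, TSV/SIF I/O, subnetworks, hop distances |
| `netmoa.characterization` | effector sets, stimuli, the four receptor scenarios |
| `netmoa.propagation` | tanh fixed-point engine, activity profiles |
| `netmoa.training` | restrictions, simulated annealing, ensembles |
| `netmoa.analysis` | fSignal, scenario statistics, heatmap matrices |
| `netmoa.enrichment` | GMT sets, hypergeometric tests, Hausdorff networks |
| `netmoa.moa_paths` | effector selection, path frequency mining, DOT export |
| `netmoa.synthetic_data` | world generator, recovery scoring, dual-cone world |
| `netmoa.pipeline` / `netmoa.cli` | end-to-end orchestration, `netmoa` command |
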