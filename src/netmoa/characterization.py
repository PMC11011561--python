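"""Disease and drug characterizations, and the four simulation scenarios.

A characterization names pathophysiological processes, each with a set of
effector proteins carrying a pathological direction w_i (+1 the protein is
hyperactivated in disease, -1 hypoactivated), and drugs, each with a set of
target proteins carrying a stimulus sign (-1 inhibited, +1 activated).

The bundled demo characterization (``netmoa/data/dme_demo.yaml``) is a
small illustrative diabetic-macular-edema-like fixture; it is not a full
disease characterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml


@dataclass(frozen=True)
class EffectorSet:
    """Process-labeled response proteins with pathological direction w_i."""

    process: str
    members: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"effector set {self.process!r} is empty")
        for protein, w in self.members.items():
            if w not in (-1, 1):
                raise ValueError(
                    f"pathological sign for {protein!r} in {self.process!r} "
                    f"must be -1 or +1, got {w!r}"
                )
        object.__setattr__(self, "members", dict(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Stimulus:
    """Clamped activity values on drug-target nodes (-1 inhibited, +1 activated)."""

    name: str
    clamps: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.clamps:
            raise ValueError(f"stimulus {self.name!r} has no clamped proteins")
        for protein, value in self.clamps.items():
            if value not in (-1, 1):
                raise ValueError(
                    f"clamp for {protein!r} in stimulus {self.name!r} "
                    f"must be -1 or +1, got {value!r}"
                )
        object.__setattr__(self, "clamps", dict(self.clamps))


@dataclass
class Characterization:
    """Validated disease + drug characterization."""

    effector_sets: list[EffectorSet]
    drug_targets: dict[str, dict[str, int]]
    aliases: dict[str, str] = field(default_factory=dict)

    @property
    def n_effectors_total(self) -> int:
        """Effector count summed over processes (a protein may recur)."""
        return sum(len(s) for s in self.effector_sets)

    @property
    def n_effectors_unique(self) -> int:
        return len({p for s in self.effector_sets for p in s.members})

    def effector_set(self, process: str) -> EffectorSet:
        for s in self.effector_sets:
            if s.process == process:
                return s
        raise KeyError(f"unknown process {process!r}")


def _parse_members(process: str, raw: object) -> dict[str, int]:
    """Accept either a mapping {protein: sign} or a list of {protein, sign}."""
    members: dict[str, int] = {}
    if isinstance(raw, Mapping):
        items = list(raw.items())
    elif isinstance(raw, list):
        items = []
        for rec in raw:
            if not isinstance(rec, Mapping) or "protein" not in rec or "sign" not in rec:
                raise ValueError(f"process {process!r}: list entries need 'protein' and 'sign'")
            items.append((rec["protein"], rec["sign"]))
    else:
        raise ValueError(f"process {process!r}: members must be a mapping or a list")
    for protein, sign in items:
        if sign not in (-1, 1):
            raise ValueError(f"process {process!r}: sign for {protein!r} must be -1 or +1")
        if protein in members and members[protein] != sign:
            raise ValueError(
                f"process {process!r}: protein {protein!r} listed twice with conflicting signs"
            )
        members[str(protein)] = int(sign)
    return members


def load_characterization(path: str) -> Characterization:
    """Load a YAML/JSON characterization file.

    Expected structure::

        processes:
          inflammation: {TNF: 1, TJP1: -1}
        drugs:
          aflibercept: {VEGFA: -1, KDR: -1}
        aliases:          # optional, applied to protein keys everywhere
          VEGFR2: KDR

    Raises ``ValueError`` on empty processes, non-±1 signs, or a protein
    listed twice within one process with conflicting signs.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return parse_characterization(raw)


def parse_characterization(raw: Mapping) -> Characterization:
    if not isinstance(raw, Mapping) or "processes" not in raw:
        raise ValueError("characterization must contain a 'processes' section")
    aliases = {str(k): str(v) for k, v in (raw.get("aliases") or {}).items()}

    def resolve(name: str) -> str:
        return aliases.get(name, name)

    effector_sets = []
    for process, members_raw in raw["processes"].items():
        members = _parse_members(process, members_raw)
        effector_sets.append(
            EffectorSet(process=str(process), members={resolve(p): w for p, w in members.items()})
        )
    drugs: dict[str, dict[str, int]] = {}
    for drug, targets_raw in (raw.get("drugs") or {}).items():
        targets = _parse_members(f"drug {drug}", targets_raw)
        drugs[str(drug)] = {resolve(p): s for p, s in targets.items()}
    return Characterization(effector_sets=effector_sets, drug_targets=drugs, aliases=aliases)


def load_demo_characterization() -> Characterization:
    """The bundled illustrative DME-like characterization."""
    text = resources.files("netmoa.data").joinpath("dme_demo.yaml").read_text(encoding="utf-8")
    return parse_characterization(yaml.safe_load(text))


# Scenario clamp patterns for the VEGF-receptor case study.  The two receptor
# pathways are: VEGFR1 (FLT1) with its ligands PGF and VEGFB, and VEGFR2 (KDR)
# with its ligands VEGFA and LGALS1.  IAI inhibits everything; VEGFR2-(DME)
# inhibits the VEGFR2 pathway while holding the VEGFR1 pathway activated.
VEGFR1_PATHWAY = ("FLT1", "PGF", "VEGFB")
VEGFR2_PATHWAY = ("KDR", "VEGFA", "LGALS1")

SCENARIOS: dict[str, dict[str, int]] = {
    "IAI": {p: -1 for p in VEGFR1_PATHWAY + VEGFR2_PATHWAY},
    "VEGFR1-": {p: -1 for p in VEGFR1_PATHWAY},
    "VEGFR2-": {p: -1 for p in VEGFR2_PATHWAY},
    "VEGFR2-(DME)": {
        **{p: -1 for p in VEGFR2_PATHWAY},
        **{p: +1 for p in VEGFR1_PATHWAY},
    },
}


def build_scenario(name: str, target_map: Mapping[str, int]) -> Stimulus:
    """Construct one of the four receptor-modulation scenarios.

    ``target_map`` is the drug characterization (targets with stimulus
    signs); every protein the scenario clamps must be present in it.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}")
    clamps = SCENARIOS[name]
    missing = sorted(set(clamps) - set(target_map))
    if missing:
        raise KeyError(f"scenario {name!r} references proteins absent from target map: {missing}")
    return Stimulus(name=name, clamps=dict(clamps))
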