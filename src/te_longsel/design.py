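"""Study designs: populations, breeding regimes, diets and demographies.

A *study* is one experimental-evolution data set: replicate populations
bred either early in life (control regime ``C``) or only at old age
(longevity-selected regime ``S``), each pool-sequenced once.  Some designs
additionally cross the regimes with larval diets.  The demographic fields
(effective population sizes and generations per regime) parameterize the
drift null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import yaml

REGIMES = ("C", "S")

#: Diet value for designs without a diet treatment.
NO_DIET = "none"


@dataclass(frozen=True)
class PopulationSample:
    """One pool-sequenced replicate population."""

    study: str
    regime: str
    replicate_id: str
    diet: str = NO_DIET
    pool_size: int = 100

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.pool_size <= 0:
            raise ValueError("pool_size must be > 0")

    @property
    def name(self) -> str:
        """Unique column-safe sample identifier."""
        base = f"{self.study}_{self.regime}{self.replicate_id}"
        return base if self.diet == NO_DIET else f"{base}_{self.diet}"


@dataclass
class StudyDesign:
    """All populations of one study plus its demographic parameters.

    ``ne_control``/``ne_selected`` are consensus effective population sizes;
    ``gen_control``/``gen_selected`` the numbers of generations each regime
    spent in the laboratory at sequencing time.
    ``breeding_fraction_selected`` scales the selected-regime Ne to reflect
    that only a fraction of flies may still breed at old age.
    """

    name: str
    samples: Sequence[PopulationSample]
    ne_control: int = 1000
    ne_selected: int = 1000
    gen_control: int = 0
    gen_selected: int = 0
    breeding_fraction_selected: float = 1.0

    def __post_init__(self) -> None:
        keys = [(s.study, s.regime, s.replicate_id, s.diet) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError(f"study {self.name}: duplicate population keys")
        for regime in REGIMES:
            if not any(s.regime == regime for s in self.samples):
                raise ValueError(f"study {self.name}: no {regime} population")
        if not 0 < self.breeding_fraction_selected <= 1:
            raise ValueError("breeding_fraction_selected must be in (0, 1]")
        if min(self.ne_control, self.ne_selected) <= 0:
            raise ValueError("effective population sizes must be > 0")
        if min(self.gen_control, self.gen_selected) < 0:
            raise ValueError("generation counts must be >= 0")
        diets = {s.diet for s in self.samples}
        if NO_DIET in diets and len(diets) > 1:
            raise ValueError(
                f"study {self.name}: mixes diet and no-diet populations"
            )

    @property
    def has_diets(self) -> bool:
        return any(s.diet != NO_DIET for s in self.samples)

    @property
    def diets(self) -> list[str]:
        return sorted({s.diet for s in self.samples if s.diet != NO_DIET})

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def samples_for(self, regime: str | None = None,
                    diet: str | None = None) -> list[PopulationSample]:
        out = list(self.samples)
        if regime is not None:
            out = [s for s in out if s.regime == regime]
        if diet is not None:
            out = [s for s in out if s.diet == diet]
        return out

    def regime_of(self) -> Mapping[str, str]:
        """Map sample name -> regime."""
        return {s.name: s.regime for s in self.samples}


def make_design(name: str, n_control: int, n_selected: int,
                diets: Iterable[str] = (), pool_size: int = 100,
                **demography) -> StudyDesign:
    """Construct a balanced design with ``n_control``/``n_selected``
    replicates per regime (per diet, if diets are given)."""
    samples = []
    diet_list = list(diets) or [NO_DIET]
    for diet in diet_list:
        for regime, n in (("C", n_control), ("S", n_selected)):
            for i in range(1, n + 1):
                samples.append(PopulationSample(
                    study=name, regime=regime, replicate_id=f"r{i}",
                    diet=diet, pool_size=pool_size))
    return StudyDesign(name=name, samples=samples, **demography)


def load_study_designs(path) -> dict[str, StudyDesign]:
    """Load study designs from a YAML config file.

    Schema (per study)::

        studies:
          - name: StudyA
            ne: {C: 300, S: 300}
            generations: {C: 100, S: 58}
            breeding_fraction_selected: 1.0
            populations:
              - {regime: S, replicate: r1, diet: none, pool_size: 125}
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "studies" not in cfg:
        raise ValueError(f"{path}: config must contain a 'studies' list")
    designs: dict[str, StudyDesign] = {}
    for study in cfg["studies"]:
        name = study["name"]
        samples = [
            PopulationSample(
                study=name,
                regime=p["regime"],
                replicate_id=str(p["replicate"]),
                diet=str(p.get("diet", NO_DIET)),
                pool_size=int(p.get("pool_size", 100)),
            )
            for p in study["populations"]
        ]
        designs[name] = StudyDesign(
            name=name,
            samples=samples,
            ne_control=int(study.get("ne", {}).get("C", 1000)),
            ne_selected=int(study.get("ne", {}).get("S", 1000)),
            gen_control=int(study.get("generations", {}).get("C", 0)),
            gen_selected=int(study.get("generations", {}).get("S", 0)),
            breeding_fraction_selected=float(
                study.get("breeding_fraction_selected", 1.0)),
        )
    return designs
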