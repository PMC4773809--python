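"""Population panel: sample -> population -> super-group assignments.

Every per-population statistic in the package is driven by a
:class:`PanelMap`, mirroring the sample panels that accompany multi-sample
variant call sets (e.g. the continental super-groups AFR/EUR/EAS/AMR used
in large cohort studies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class PanelMap:
    """Immutable sample/population/super-group mapping.

    Parameters
    ----------
    population_of:
        sample id -> population code. Every sample maps to exactly one
        population.
    super_group_of:
        population code -> super-group label. Every population maps to
        exactly one super-group.
    """

    population_of: dict[str, str]
    super_group_of: dict[str, str]
    _pop_order: tuple[str, ...] = field(init=False, repr=False, default=())

    def __post_init__(self) -> None:
        for pop in set(self.population_of.values()):
            if pop not in self.super_group_of:
                raise ValueError(f"population {pop!r} has no super-group assignment")
        # population order = first-appearance order over samples
        seen: list[str] = []
        for pop in self.population_of.values():
            if pop not in seen:
                seen.append(pop)
        object.__setattr__(self, "_pop_order", tuple(seen))

    @property
    def samples(self) -> list[str]:
        return list(self.population_of)

    @property
    def populations(self) -> list[str]:
        return list(self._pop_order)

    @property
    def super_groups(self) -> list[str]:
        seen: list[str] = []
        for pop in self.populations:
            g = self.super_group_of[pop]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.population_of.items() if p == population]

    def populations_in(self, super_group: str) -> list[str]:
        return [p for p in self.populations if self.super_group_of[p] == super_group]

    def sample_indices_by_population(self, samples: list[str]) -> dict[str, list[int]]:
        """Indices of ``samples`` grouped by population (panel population order)."""
        out: dict[str, list[int]] = {p: [] for p in self.populations}
        for i, s in enumerate(samples):
            if s not in self.population_of:
                raise KeyError(f"sample {s!r} absent from panel")
            out[self.population_of[s]].append(i)
        return out

    # -- TSV round trip ---------------------------------------------------

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PanelMap":
        """Read a 3-column TSV: sample_id <TAB> population <TAB> super_group."""
        population_of: dict[str, str] = {}
        super_group_of: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
                sample, pop, group = parts
                if sample in population_of:
                    raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
                if pop in super_group_of and super_group_of[pop] != group:
                    raise ValueError(
                        f"{path}:{lineno}: population {pop!r} mapped to two super-groups"
                    )
                population_of[sample] = pop
                super_group_of[pop] = group
        return cls(population_of, super_group_of)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sample, pop in self.population_of.items():
                fh.write(f"{sample}\t{pop}\t{self.super_group_of[pop]}\n")
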