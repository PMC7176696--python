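"""Individual -> population label table with derived pair counts."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["PopulationTable"]


@dataclass
class PopulationTable:
    """Mapping of individual identifiers to population labels.

    Every individual carries exactly one label; ``sizes`` gives the n_i and
    ``n_individuals`` the total N, so that sum(n_i) == N by construction.
    """

    labels: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PopulationTable":
        labels: dict[str, str] = {}
        dupes = []
        for ind, pop in pairs:
            if ind in labels:
                dupes.append(ind)
            labels[str(ind)] = str(pop)
        if dupes:
            raise ValueError(f"duplicated individual identifiers: {sorted(set(dupes))}")
        return cls(labels)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "PopulationTable":
        return cls(dict(mapping))

    def __contains__(self, individual: str) -> bool:
        return individual in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, individual: str) -> str:
        return self.labels[individual]

    def get(self, individual: str, default: str | None = None) -> str | None:
        return self.labels.get(individual, default)

    @property
    def individuals(self) -> list[str]:
        return list(self.labels)

    @property
    def populations(self) -> list[str]:
        """Population names in first-appearance order."""
        seen: dict[str, None] = {}
        for pop in self.labels.values():
            seen.setdefault(pop, None)
        return list(seen)

    @property
    def sizes(self) -> Counter:
        return Counter(self.labels.values())

    @property
    def n_individuals(self) -> int:
        return len(self.labels)

    def members(self, population: str) -> list[str]:
        return [ind for ind, pop in self.labels.items() if pop == population]
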