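"""Pore-network containers: pores (spheres) and throats (cylinders).

A pore sits at a local maximum of the maximal-ball radius field; a throat
is the constriction (saddle) between two adjacent pores.  Pore centers are
stored as 0-based (z, y, x) voxel indices; radii, lengths and volumes are
physical (um, um^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Pore", "Throat", "PoreNetwork"]


@dataclass
class Pore:
    id: int
    center: tuple[int, int, int]  # (z, y, x) voxel index of defining maximum
    radius_um: float
    volume_um3: float  # assigned-voxel volume
    coordination: int = 0


@dataclass
class Throat:
    id: int
    pore_a: int
    pore_b: int
    radius_um: float  # saddle maximal-ball radius on the interface
    length_um: float
    volume_um3: float  # cylinder model: pi r^2 L


@dataclass
class PoreNetwork:
    pores: list[Pore]
    throats: list[Throat]
    voxel_size_um: float
    void_voxel_count: int
    extraction_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def pore_count(self) -> int:
        return len(self.pores)

    @property
    def throat_count(self) -> int:
        return len(self.throats)

    def pore_by_id(self, pore_id: int) -> Pore:
        try:
            return self._index[pore_id]
        except (AttributeError, KeyError):
            self._index = {p.id: p for p in self.pores}
            return self._index[pore_id]

    def validate(self) -> None:
        """Check referential integrity and the degree identity."""
        ids = [p.id for p in self.pores]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pore ids")
        id_set = set(ids)
        incident: dict[int, int] = dict.fromkeys(ids, 0)
        tids = set()
        for t in self.throats:
            if t.id in tids:
                raise ValueError(f"duplicate throat id {t.id}")
            tids.add(t.id)
            if t.pore_a == t.pore_b:
                raise ValueError(f"throat {t.id} is a self-loop on pore {t.pore_a}")
            for pid in (t.pore_a, t.pore_b):
                if pid not in id_set:
                    raise ValueError(f"throat {t.id} references unknown pore id {pid}")
                incident[pid] += 1
        for p in self.pores:
            if p.coordination != incident[p.id]:
                raise ValueError(
                    f"pore {p.id}: coordination {p.coordination} != incident "
                    f"throat count {incident[p.id]}"
                )
        # degree identity: sum of coordinations = 2 * number of throats
        assert sum(incident.values()) == 2 * len(self.throats)

    def pore_center_um(self, pore: Pore) -> tuple[float, float, float]:
        """Physical (z, y, x) position of a pore center (voxel-center rule)."""
        return tuple((c + 0.5) * self.voxel_size_um for c in pore.center)  # type: ignore[return-value]
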