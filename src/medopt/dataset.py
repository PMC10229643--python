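"""In-memory container pairing medium combinations with replicate A450 readings."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from .design import DesignSpace, MediumCombination

__all__ = ["CultureObservation", "Dataset"]


@dataclass
class CultureObservation:
    """Replicate A450 readings for one medium at each sampled timepoint.

    ``raw`` holds plate-reader values, ``blanked`` the blank-subtracted
    values (raw minus the mean medium-only A450; may be slightly negative
    under noise), and ``mean`` the arithmetic mean of the blank-subtracted
    replicates — the quantity the surrogate is trained on.
    """

    combination_id: str
    raw: Dict[float, np.ndarray]
    blanked: Dict[float, np.ndarray]
    mean: Dict[float, float]
    n_replicates: int

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.raw)

    def validate(self) -> None:
        for t in self.raw:
            if len(self.raw[t]) != self.n_replicates or len(self.blanked[t]) != self.n_replicates:
                raise ValueError(f"{self.combination_id}: replicate count mismatch at {t} h")
            if not np.isclose(self.mean[t], float(np.mean(self.blanked[t]))):
                raise ValueError(f"{self.combination_id}: mean is not the replicate mean at {t} h")


@dataclass
class _Record:
    combo: MediumCombination
    obs: CultureObservation
    round_label: str
    mode: str


class Dataset:
    """Ordered collection of (medium, observation) records, tagged by round and mode.

    Component order follows the owning :class:`DesignSpace`; per-combination
    mean blank-subtracted A450 at a chosen timepoint is the learning target.
    """

    def __init__(self, space: DesignSpace):
        self.space = space
        self._records: dict[str, _Record] = {}

    # -- construction -----------------------------------------------------
    def add(
        self,
        combo: MediumCombination,
        obs: CultureObservation,
        round_label: str = "initial",
        mode: str = "regular",
    ) -> None:
        if combo.id is None:
            raise ValueError("combination must carry an id before entering a dataset")
        if combo.id in self._records:
            raise ValueError(f"duplicate combination id {combo.id!r}")
        if len(combo.folds) != self.space.n_components:
            raise ValueError(f"{combo.id}: fold vector length mismatch")
        self._records[combo.id] = _Record(combo, obs, round_label, mode)

    def extend(self, other: "Dataset") -> None:
        for rec in other._records.values():
            self.add(rec.combo, rec.obs, rec.round_label, rec.mode)

    def copy(self) -> "Dataset":
        out = Dataset(self.space)
        out._records = dict(self._records)
        return out

    # -- access ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, combo) -> bool:
        if isinstance(combo, MediumCombination):
            return combo.key() in {r.combo.key() for r in self._records.values()}
        return combo in self._records

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def combination(self, id: str) -> MediumCombination:
        return self._records[id].combo

    def observation(self, id: str) -> CultureObservation:
        return self._records[id].obs

    def round_label(self, id: str) -> str:
        return self._records[id].round_label

    def mode(self, id: str) -> str:
        return self._records[id].mode

    @property
    def round_labels(self) -> list[str]:
        seen: list[str] = []
        for rec in self._records.values():
            if rec.round_label not in seen:
                seen.append(rec.round_label)
        return seen

    def ids_in_round(self, round_label: str) -> list[str]:
        return [i for i, rec in self._records.items() if rec.round_label == round_label]

    def combos(self) -> list[MediumCombination]:
        return [rec.combo for rec in self._records.values()]

    def keys(self) -> set[tuple[float, ...]]:
        return {rec.combo.key() for rec in self._records.values()}

    @property
    def timepoints(self) -> list[float]:
        ts: set[float] = set()
        for rec in self._records.values():
            ts.update(rec.obs.raw)
        return sorted(ts)

    # -- learning views ----------------------------------------------------
    def features(self, ids: Optional[Iterable[str]] = None) -> np.ndarray:
        ids = list(ids) if ids is not None else self.ids
        return np.array([self._records[i].combo.folds for i in ids], dtype=float)

    def mean_a450(self, timepoint: float, ids: Optional[Iterable[str]] = None) -> pd.Series:
        ids = list(ids) if ids is not None else self.ids
        vals = []
        for i in ids:
            obs = self._records[i].obs
            if timepoint not in obs.mean:
                raise KeyError(f"combination {i!r} has no observation at {timepoint} h")
            vals.append(obs.mean[timepoint])
        return pd.Series(vals, index=ids, name=f"a450_{timepoint:g}h")

    def best(self, timepoint: float, ids: Optional[Iterable[str]] = None) -> tuple[str, float]:
        s = self.mean_a450(timepoint, ids)
        i = s.idxmax()
        return i, float(s.loc[i])
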