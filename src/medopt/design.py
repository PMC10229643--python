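"""Medium composition space: components, level schedules, OFAT design, candidate grid.

Concentrations are handled internally as dimensionless *fold-of-baseline*
values (concentration divided by the component's level in the basal medium),
so a medium is a vector of folds in a fixed component order.  The basal
medium itself is the all-ones vector.  Fold vectors are the feature vectors
seen by the surrogate model, which keeps feature scales comparable across
components whose absolute concentrations span five orders of magnitude.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ComponentSpec",
    "DesignSpace",
    "MediumCombination",
    "build_design_space",
    "default_component_table",
    "generate_initial_design",
    "sample_candidates",
    "validate_combination",
    "canonical_fold",
]

#: significant digits that define combination identity (dedup / exclusion)
FOLD_SIG_DIGITS = 12


def canonical_fold(x: float) -> float:
    """Round a fold value to the canonical 12 significant digits."""
    if x == 0:
        return 0.0
    return float(f"{float(x):.{FOLD_SIG_DIGITS}g}")


def derive_seed(base: int, *parts) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a base seed and labels."""
    h = zlib.crc32(repr(tuple(parts)).encode())
    return (int(base) ^ h) & 0x7FFFFFFF


@dataclass(frozen=True)
class ComponentSpec:
    """One medium component and its allowed concentration levels.

    Parameters
    ----------
    name : str
        Component identifier (e.g. ``"NaCl"``).
    baseline : float
        Concentration in the basal medium, in ``unit`` (must be positive).
    unit : str
        Unit tag for the baseline, e.g. ``"mM"`` or ``"%v/v"``.
    levels : tuple of float
        Ordered fold-of-baseline levels available to the designs.  Must be
        sorted ascending, non-negative and duplicate-free, and must contain
        1.0 for tunable components.
    fixed : bool
        Fixed components (phenol red, penicillin-streptomycin) are held at
        baseline in every medium; their level list is exactly ``(1.0,)``.
    role : str
        Free-text role tag (amino acid, vitamin, salt, serum, carbon, other).
    """

    name: str
    baseline: float
    unit: str
    levels: tuple[float, ...]
    fixed: bool = False
    role: str = "other"

    def __post_init__(self):
        if not self.name:
            raise ValueError("component name must be non-empty")
        if not self.baseline > 0:
            raise ValueError(f"{self.name}: baseline_concentration must be > 0")
        lv = tuple(float(x) for x in self.levels)
        if len(lv) == 0:
            raise ValueError(f"{self.name}: level list is empty")
        if any(x < 0 for x in lv):
            raise ValueError(f"{self.name}: negative level")
        if list(lv) != sorted(set(lv)):
            raise ValueError(f"{self.name}: levels must be sorted ascending with no duplicates")
        if self.fixed:
            if lv != (1.0,):
                raise ValueError(f"{self.name}: fixed components must have levels == [1.0]")
        elif 1.0 not in lv:
            raise ValueError(f"{self.name}: tunable component must include fold 1.0")
        object.__setattr__(self, "levels", lv)

    def absolute(self, fold: float) -> float:
        """Concentration (in ``unit``) corresponding to a fold value."""
        return self.baseline * fold


@dataclass(frozen=True)
class DesignSpace:
    """Ordered collection of :class:`ComponentSpec`.

    The component order is the canonical feature order used everywhere
    downstream (designs, datasets, surrogate features, importances).
    """

    components: tuple[ComponentSpec, ...]

    def __post_init__(self):
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate component names: {dupes}")
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def tunable(self) -> list[ComponentSpec]:
        return [c for c in self.components if not c.fixed]

    @property
    def tunable_count(self) -> int:
        return sum(1 for c in self.components if not c.fixed)

    @property
    def grid_size(self) -> int:
        """Number of points in the full level grid (fixed components contribute 1)."""
        n = 1
        for c in self.components:
            n *= len(c.levels)
        return n

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown component {name!r}") from None

    def baseline_combination(self, id: str = "baseline") -> "MediumCombination":
        return MediumCombination(folds=(1.0,) * self.n_components, id=id)


@dataclass(frozen=True, eq=False)
class MediumCombination:
    """One medium as a vector of fold-of-baseline values in space order.

    Identity (equality, hashing, dedup, exclusion) is defined by the fold
    vector rounded to 12 significant digits; the ``id`` label is metadata.
    """

    folds: tuple[float, ...]
    id: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "folds", tuple(float(x) for x in self.folds))

    def key(self) -> tuple[float, ...]:
        return tuple(canonical_fold(x) for x in self.folds)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MediumCombination):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def with_id(self, id: str) -> "MediumCombination":
        return MediumCombination(folds=self.folds, id=id)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.folds, dtype=float)


# ---------------------------------------------------------------------------
# Built-in EMEM-based component table
# ---------------------------------------------------------------------------

#: Default level schedules: five log-spaced folds for most components,
#: four for the osmotically dominant ones, three for serum (0.1-10 %v/v).
_FIVE = "0;0.1;1;10;100"
_FOUR = "0;0.1;1;10"
_FBS = "0.01;0.1;1"

_DEFAULT_TABLE_CSV = f"""name,baseline,unit,levels,fixed,role
L-arginine hydrochloride,0.6,mM,{_FIVE},false,amino acid
L-cystine,0.1,mM,{_FIVE},false,amino acid
L-glutamine,2.0,mM,{_FIVE},false,amino acid
L-histidine hydrochloride,0.2,mM,{_FIVE},false,amino acid
L-isoleucine,0.4,mM,{_FIVE},false,amino acid
L-leucine,0.4,mM,{_FIVE},false,amino acid
L-lysine hydrochloride,0.4,mM,{_FIVE},false,amino acid
L-methionine,0.1,mM,{_FIVE},false,amino acid
L-phenylalanine,0.2,mM,{_FIVE},false,amino acid
L-threonine,0.4,mM,{_FIVE},false,amino acid
L-tryptophan,0.05,mM,{_FIVE},false,amino acid
L-tyrosine,0.2,mM,{_FIVE},false,amino acid
L-valine,0.4,mM,{_FIVE},false,amino acid
choline chloride,0.007,mM,{_FIVE},false,vitamin
folic acid,0.0023,mM,{_FIVE},false,vitamin
myo-inositol,0.011,mM,{_FIVE},false,vitamin
nicotinamide,0.0082,mM,{_FIVE},false,vitamin
D-pantothenic acid,0.0021,mM,{_FIVE},false,vitamin
pyridoxal hydrochloride,0.0049,mM,{_FIVE},false,vitamin
riboflavin,0.00027,mM,{_FIVE},false,vitamin
thiamine hydrochloride,0.003,mM,{_FIVE},false,vitamin
NaCl,116.0,mM,{_FOUR},false,salt
KCl,5.3,mM,{_FIVE},false,salt
CaCl2,1.8,mM,{_FIVE},false,salt
MgSO4,0.8,mM,{_FIVE},false,salt
NaH2PO4,1.0,mM,{_FIVE},false,salt
NaHCO3,26.0,mM,{_FOUR},false,salt
D-glucose,5.5,mM,{_FOUR},false,carbon
FBS,10.0,%v/v,{_FBS},false,serum
phenol red,0.03,mM,1,true,indicator
penicillin-streptomycin,1.0,%v/v,1,true,antibiotic
"""


def default_component_table() -> pd.DataFrame:
    """Built-in 31-component EMEM-based table (29 tunable, 2 fixed).

    Baselines follow the standard EMEM formulation; serum (FBS) spans the
    0.1-10 %v/v range as folds {0.01, 0.1, 1} of the 10 %v/v convention,
    and the remaining tunables span zero- to 10- or 100-fold on a log scale.
    """
    return pd.read_csv(StringIO(_DEFAULT_TABLE_CSV))


def _parse_levels(value) -> tuple[float, ...]:
    if isinstance(value, (list, tuple, np.ndarray)):
        return tuple(float(x) for x in value)
    return tuple(float(x) for x in str(value).split(";") if str(x).strip() != "")


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"true", "1", "yes", "t"}


def build_design_space(component_table: Optional[pd.DataFrame] = None) -> DesignSpace:
    """Build and validate a :class:`DesignSpace` from a component table.

    Parameters
    ----------
    component_table : pandas.DataFrame, optional
        One row per component with columns ``name``, ``baseline``, ``unit``,
        ``levels`` (semicolon-separated fold values), ``fixed`` and ``role``.
        Defaults to the built-in EMEM table (29 tunable components).
    """
    table = default_component_table() if component_table is None else component_table
    required = {"name", "baseline", "levels"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"component table missing columns: {sorted(missing)}")
    comps = []
    for _, row in table.iterrows():
        comps.append(
            ComponentSpec(
                name=str(row["name"]),
                baseline=float(row["baseline"]),
                unit=str(row.get("unit", "")),
                levels=_parse_levels(row["levels"]),
                fixed=_parse_bool(row.get("fixed", False)),
                role=str(row.get("role", "other")),
            )
        )
    return DesignSpace(components=tuple(comps))


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

def generate_initial_design(
    space: DesignSpace, include_baseline: bool = True
) -> list[MediumCombination]:
    """One-factor-at-a-time initial design.

    One combination per (tunable component, non-baseline level) pair, each
    differing from the all-baseline medium in exactly that coordinate, in
    deterministic order (component order, then level order); the all-baseline
    medium is prepended when ``include_baseline`` is set.
    """
    out: list[MediumCombination] = []
    if include_baseline:
        out.append(space.baseline_combination())
    base = [1.0] * space.n_components
    for i, comp in enumerate(space.components):
        if comp.fixed:
            continue
        for level in comp.levels:
            if level == 1.0:
                continue
            folds = list(base)
            folds[i] = level
            out.append(
                MediumCombination(folds=tuple(folds), id=f"ofat_{comp.name}_{level:g}x")
            )
    return out


def _enumerate_grid(space: DesignSpace) -> Iterable[tuple[float, ...]]:
    """Cartesian product of per-component level lists, deterministic order."""
    return itertools.product(*(c.levels for c in space.components))


def _bounded_pool_counts(weights: list[int], k_max: int) -> np.ndarray:
    """N_k = number of grid points altering exactly k tunable components.

    ``weights[i]`` is the number of non-baseline levels of component i;
    N_k is the elementary symmetric aggregate sum_{|S|=k} prod_{i in S} w_i.
    """
    counts = np.zeros(k_max + 1)
    counts[0] = 1.0
    for w in weights:
        counts[1:] = counts[1:] + w * counts[:-1]
    return counts


def _esp_suffix_table(weights: list[float], k_max: int) -> np.ndarray:
    """e[j, i] = elementary symmetric polynomial e_j over weights[i:]."""
    n = len(weights)
    e = np.zeros((k_max + 1, n + 1))
    e[0, :] = 1.0
    for i in range(n - 1, -1, -1):
        for j in range(1, k_max + 1):
            e[j, i] = e[j, i + 1] + weights[i] * e[j - 1, i + 1]
    return e


def sample_candidates(
    space: DesignSpace,
    n_max: int,
    rng_seed: int,
    exclude: Iterable[MediumCombination] = (),
    draw_budget_factor: int = 64,
    max_changes: Optional[int] = None,
) -> list[MediumCombination]:
    """Candidate pool over the level grid.

    If the full (or Hamming-bounded, see below) grid has at most ``n_max``
    points it is enumerated exactly (minus exclusions, deterministic order).
    Otherwise candidates are drawn uniformly — by independent per-component
    level sampling when ``max_changes`` is None — de-duplicated and filtered
    against ``exclude``, until ``n_max`` distinct candidates are found or
    ``draw_budget_factor * n_max`` draws are spent.  Reproducible under a
    fixed seed.

    ``max_changes`` bounds the number of components altered from baseline
    per candidate.  A 29-component space with four to five levels has about
    ten million media within four alterations, whereas the unrestricted grid
    has ~1e20; the bounded pool concentrates the search near the region the
    one-factor-at-a-time data can inform.  Sampling is exactly uniform over
    the bounded pool (number of alterations drawn proportional to the pool
    stratum size, the altered subset by weighted sequential inclusion).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    excl = {c.key() for c in exclude}

    if max_changes is None and space.grid_size <= n_max:
        pool = [
            MediumCombination(folds=folds)
            for folds in _enumerate_grid(space)
            if tuple(canonical_fold(x) for x in folds) not in excl
        ]
        if not pool:
            raise ValueError("candidate pool empty: all grid points excluded")
        return pool

    rng = np.random.default_rng(rng_seed)
    seen: set[tuple[float, ...]] = set()
    pool: list[MediumCombination] = []
    budget = draw_budget_factor * n_max

    if max_changes is None:
        level_arrays = [np.asarray(c.levels) for c in space.components]
        n_levels = np.array([len(lv) for lv in level_arrays])
        batch = max(256, min(n_max, 65536))
        drawn = 0
        while len(pool) < n_max and drawn < budget:
            m = min(batch, budget - drawn)
            drawn += m
            idx = rng.integers(0, n_levels[None, :], size=(m, space.n_components))
            folds_mat = np.column_stack(
                [level_arrays[j][idx[:, j]] for j in range(space.n_components)]
            )
            for row in folds_mat:
                key = tuple(canonical_fold(x) for x in row)
                if key in seen or key in excl:
                    continue
                seen.add(key)
                pool.append(MediumCombination(folds=tuple(row)))
                if len(pool) == n_max:
                    break
    else:
        if max_changes < 1:
            raise ValueError("max_changes must be >= 1")
        alt_levels = [
            [l for l in c.levels if l != 1.0] if not c.fixed else []
            for c in space.components
        ]
        weights = [len(lv) for lv in alt_levels]
        k_max = min(max_changes, sum(1 for w in weights if w > 0))
        counts = _bounded_pool_counts(weights, k_max)
        esp = _esp_suffix_table([float(w) for w in weights], k_max)
        k_probs = counts[1:] / counts[1:].sum()  # k = 0 is the (tested) baseline
        for _ in range(budget):
            k = int(rng.choice(np.arange(1, k_max + 1), p=k_probs))
            folds = [1.0] * space.n_components
            j = k
            for i, w in enumerate(weights):
                if j == 0:
                    break
                if w == 0:
                    continue
                p_in = w * esp[j - 1, i + 1] / esp[j, i]
                if rng.random() < p_in:
                    folds[i] = alt_levels[i][int(rng.integers(len(alt_levels[i])))]
                    j -= 1
            key = tuple(canonical_fold(x) for x in folds)
            if key in seen or key in excl:
                continue
            seen.add(key)
            pool.append(MediumCombination(folds=tuple(folds)))
            if len(pool) == n_max:
                break
    if not pool:
        raise ValueError("candidate pool empty: draw budget exhausted before any candidate found")
    return pool


def sample_training_media(
    space: DesignSpace, n: int, rng_seed: int, max_changes: Optional[int] = 4
) -> list[MediumCombination]:
    """Media mix representative of a growing campaign dataset.

    A fixed 30/70 mixture of OFAT-design media (what a campaign starts
    from) and Hamming-bounded grid candidates (what greedy rounds
    contribute), at any requested size, so learning-curve experiments that
    compare surrogate accuracy across training-set sizes draw both sizes
    from the same distribution.
    """
    rng = np.random.default_rng(rng_seed)
    design = generate_initial_design(space)
    n_ofat = min(round(0.3 * n), len(design))
    order = rng.permutation(len(design))
    media = [design[i] for i in order[:n_ofat]]
    if n > n_ofat:
        media += sample_candidates(
            space,
            n - n_ofat,
            rng_seed=derive_seed(rng_seed, "training-extra"),
            exclude=design,
            max_changes=max_changes,
        )
    return [c.with_id(f"tm{i:04d}") for i, c in enumerate(media)]


def validate_combination(
    space: DesignSpace, combo: MediumCombination, grid_constrained: bool = True
) -> list[str]:
    """Report violations of a combination against a space (empty list = valid)."""
    violations: list[str] = []
    if len(combo.folds) != space.n_components:
        violations.append(
            f"length mismatch: {len(combo.folds)} folds for {space.n_components} components"
        )
        return violations
    for comp, fold in zip(space.components, combo.folds):
        if fold < 0:
            violations.append(f"{comp.name}: negative fold {fold}")
        if comp.fixed and canonical_fold(fold) != 1.0:
            violations.append(f"{comp.name}: fixed component altered (fold {fold})")
        elif grid_constrained and not comp.fixed:
            if canonical_fold(fold) not in {canonical_fold(l) for l in comp.levels}:
                violations.append(f"{comp.name}: off-grid fold {fold}")
    return violations
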