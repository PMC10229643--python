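"""Synthetic culture oracle: medium composition -> replicate A450 timecourses.

The oracle is the ground truth the closed loop is benchmarked against.  It
composes three layers:

1. **Dose responses.**  Each tunable component multiplies the baseline
   growth rate ``r0`` and carrying capacity ``K0`` through a per-component
   effect function of its fold value (inert, log-quadratic, saturating, or
   window), normalized so the all-baseline medium reproduces ``(r0, K0)``
   exactly.  Salt excess additionally feeds an osmotic penalty on the rate
   (hyper-osmotic media arrest growth), and designated vitamins modulate the
   NAD(P)H content per cell — which moves the colorimetric readout without
   moving the cell count.
2. **Growth kinetics.**  Logistic growth from an initial density ``n0``
   (default 1e4 cells/ml), with defaults tuned so the baseline culture sits
   near saturation by the last sampling time (168 h).
3. **Assay model.**  A450 = ``assay_scale`` x NAD(P)H factor x cell density
   plus a medium blank, with multiplicative lognormal and additive Gaussian
   replicate noise; blank subtraction removes the noise-free blank mean, so
   blank-subtracted values can dip slightly below zero, as in real plates.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

from .dataset import CultureObservation, Dataset
from .design import DesignSpace, MediumCombination

__all__ = [
    "ComponentEffect",
    "OracleParams",
    "make_default_oracle",
    "growth_response",
    "logistic_cells",
    "simulate_measurement",
    "build_dataset",
]

_EFFECT_TYPES = ("inert", "log_quadratic", "saturating", "window")


@dataclass(frozen=True)
class ComponentEffect:
    """Dose-response of one component, as a multiplier on growth rate.

    All profiles are normalized to 1.0 at fold 1 (the basal concentration)
    and clipped to ``(floor, cap]``; the value at fold 0 is the
    ``essentiality`` parameter directly (log profiles are undefined there).

    effect_type:
        ``inert``           multiplier 1 everywhere.
        ``log_quadratic``   Gaussian in log10(fold) peaking at ``optimum_fold``
                            with sd ``width`` (log10-fold units); gentle tails.
        ``window``          same shape, but tails fall to a near-zero floor —
                            both excess and deficiency are harmful.
        ``saturating``      Michaelis-Menten benefit ``1 + max_benefit *
                            fold / (fold + half_sat_fold)``.
    essentiality:
        multiplier at fold 0 (0 = strictly required, 1 = dispensable).
    r_exponent, k_exponent:
        the growth-rate and carrying-capacity multipliers are the base
        profile raised to these exponents.  Rate-limiting components
        (serum growth factors) have large ``r_exponent``; density-limiting
        nutrients (carbon/nitrogen sources) have large ``k_exponent``.
        Decoupling the two is what makes early-timepoint readouts (pure
        exponential phase, rate-driven) imperfect rank predictors of the
        saturated endpoint (capacity-driven).
    """

    effect_type: str = "inert"
    optimum_fold: float = 1.0
    width: float = 0.5
    essentiality: float = 1.0
    max_benefit: float = 0.5
    half_sat_fold: float = 2.0
    r_exponent: float = 1.0
    k_exponent: float = 0.5

    def __post_init__(self):
        if self.effect_type not in _EFFECT_TYPES:
            raise ValueError(f"unknown effect_type {self.effect_type!r}")
        if self.effect_type in ("log_quadratic", "window") and not self.optimum_fold > 0:
            raise ValueError("optimum_fold must be positive")
        if not self.width > 0:
            raise ValueError("width must be positive")
        if not 0.0 <= self.essentiality <= 1.0:
            raise ValueError("essentiality must lie in [0, 1]")
        if self.effect_type == "saturating" and not self.max_benefit > 0:
            raise ValueError("max_benefit must be positive")

    def _raw(self, fold: float) -> float:
        if self.effect_type == "inert":
            return 1.0
        if self.effect_type == "saturating":
            return 1.0 + self.max_benefit * fold / (fold + self.half_sat_fold)
        d = math.log10(fold) - math.log10(self.optimum_fold)
        return math.exp(-0.5 * (d / self.width) ** 2)

    def multiplier(self, fold: float, cap: float = 2.0) -> float:
        """Rate multiplier at a fold value, in (0, cap] (0 allowed at fold 0)."""
        if self.effect_type == "inert":
            return 1.0
        if fold <= 0.0:
            return float(self.essentiality)
        floor = 0.02 if self.effect_type == "window" else 0.2
        m = self._raw(fold) / self._raw(1.0)
        return float(min(cap, max(floor, m)))


@dataclass
class OracleParams:
    """Ground-truth synthetic response surface for a design space.

    The parameters of the default instance are free, clearly synthetic
    choices; only the qualitative structure (serum optimum an order of
    magnitude below convention, salt windows, osmotic arrest, vitamin-driven
    NAD(P)H shifts, 48/96/144/168 h sampling, n0 = 1e4 cells/ml) is anchored
    to observed cell-culture behaviour.
    """

    space: DesignSpace
    effects: Dict[str, ComponentEffect] = field(default_factory=dict)
    r0: float = 0.0405  # 1/h; baseline culture ~90% of K0 by 168 h
    K0: float = 1.0e6  # cells/ml
    n0: float = 1.0e4  # cells/ml
    osmo_weights: Dict[str, float] = field(default_factory=dict)
    osmo_threshold: float = 0.5  # weighted excess-fold units
    osmo_alpha: float = 0.6
    nadph_modifiers: Dict[str, float] = field(default_factory=dict)  # slope per log10 fold
    assay_scale: float = 1.0e-6  # A450 per (cells/ml x NADPH factor)
    blank_a450: float = 0.08
    noise_sd_mult: float = 0.05  # lognormal sigma
    noise_sd_add: float = 0.02  # comparable to the 48 h signal, as in real plates
    timepoints: tuple[float, ...] = (48.0, 96.0, 144.0, 168.0)
    multiplier_cap: float = 2.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.blank_a450 < 0 or self.noise_sd_mult < 0 or self.noise_sd_add < 0:
            raise ValueError("blank and noise parameters must be non-negative")
        unknown = set(self.effects) - set(self.space.names)
        if unknown:
            raise ValueError(f"effects reference unknown components: {sorted(unknown)}")

    @property
    def active_components(self) -> list[str]:
        """Components that influence the readout (growth effects or NAD(P)H)."""
        active = [n for n, e in self.effects.items() if e.effect_type != "inert"]
        active += [n for n in self.nadph_modifiers if n not in active]
        return [n for n in self.space.names if n in active]

    def effect_for(self, name: str) -> ComponentEffect:
        return self.effects.get(name, ComponentEffect())

    def nadph_modifier(self, name: str, fold: float) -> float:
        slope = self.nadph_modifiers.get(name, 0.0)
        if slope == 0.0:
            return 1.0
        f = max(fold, 0.01)  # a depleted vitamin pins the factor at its low end
        return float(np.clip(1.0 + slope * math.log10(f), 0.2, 2.0))


def make_default_oracle(
    space: DesignSpace,
    rng_seed: int = 0,
    n_active: int = 10,
    noise_sd_mult: float = 0.05,
    noise_sd_add: float = 0.02,
) -> OracleParams:
    """Default synthetic oracle for a design space.

    ``n_active`` components carry non-trivial dose responses (the rest are
    inert).  When the space contains the named EMEM components, the anchors
    are assigned first: FBS peaks near fold 0.1 (an order of magnitude below
    the 10 %v/v convention), NaCl and CaCl2 get window profiles, glucose and
    glutamine saturate, and two vitamins modulate NAD(P)H per cell.  Any
    remaining active slots are filled reproducibly from the seed with
    log-quadratic profiles whose optima sit off baseline.
    """
    rng = np.random.default_rng(rng_seed)
    names = [c.name for c in space.tunable]
    effects: Dict[str, ComponentEffect] = {}
    nadph: Dict[str, float] = {}

    anchors = {
        # serum growth factors are rate-limiting
        "FBS": ComponentEffect("log_quadratic", optimum_fold=0.1, width=0.55,
                               essentiality=0.3, r_exponent=1.0, k_exponent=0.2),
        "NaCl": ComponentEffect("window", optimum_fold=1.0, width=0.45,
                                essentiality=0.05, r_exponent=1.0, k_exponent=0.5),
        "CaCl2": ComponentEffect("window", optimum_fold=1.0, width=0.7,
                                 essentiality=0.1, r_exponent=1.0, k_exponent=0.5),
        # carbon/nitrogen sources limit the attainable density
        "D-glucose": ComponentEffect("saturating", max_benefit=0.6, half_sat_fold=2.0,
                                     essentiality=0.2, r_exponent=0.3, k_exponent=1.0),
        "L-glutamine": ComponentEffect("saturating", max_benefit=0.4, half_sat_fold=1.5,
                                       essentiality=0.3, r_exponent=0.3, k_exponent=1.0),
    }
    nadph_anchors = {"nicotinamide": 0.25, "riboflavin": 0.2}

    if n_active > 0:
        for name, eff in anchors.items():
            if name in names and len(effects) < n_active:
                effects[name] = eff
        for name, slope in nadph_anchors.items():
            if name in names and len(effects) + len(nadph) < n_active:
                nadph[name] = slope

    remaining = [n for n in names if n not in effects and n not in nadph]
    n_extra = max(0, n_active - len(effects) - len(nadph))
    if n_extra > 0 and remaining:
        chosen = [str(x) for x in rng.choice(remaining, size=min(n_extra, len(remaining)),
                                             replace=False)]
        for name in chosen:
            optimum = float(rng.choice([0.1, 10.0]))
            r_exp = float(rng.uniform(0.2, 1.0))
            effects[name] = ComponentEffect(
                "log_quadratic",
                optimum_fold=optimum,
                width=float(rng.uniform(0.5, 0.9)),
                essentiality=float(rng.uniform(0.3, 0.7)),
                r_exponent=r_exp,
                k_exponent=round(1.1 - r_exp, 6),
            )

    osmo = {
        "NaCl": 0.70, "NaHCO3": 0.20, "KCl": 0.05,
        "CaCl2": 0.02, "MgSO4": 0.02, "NaH2PO4": 0.01,
    }
    osmo_weights = {k: v for k, v in osmo.items() if k in names}

    return OracleParams(
        space=space,
        effects=effects,
        osmo_weights=osmo_weights,
        nadph_modifiers=nadph,
        noise_sd_mult=noise_sd_mult,
        noise_sd_add=noise_sd_add,
        rng_seed=rng_seed,
    )


def growth_response(
    oracle: OracleParams, combo: MediumCombination
) -> tuple[float, float, float]:
    """(growth rate r, carrying capacity K, NAD(P)H-per-cell factor) of a medium."""
    if len(combo.folds) != oracle.space.n_components:
        raise ValueError("fold vector length does not match the design space")
    r = oracle.r0
    K = oracle.K0
    nadph = 1.0
    osmo_excess = 0.0
    for comp, fold in zip(oracle.space.components, combo.folds):
        eff = oracle.effect_for(comp.name)
        m = eff.multiplier(fold, cap=oracle.multiplier_cap)
        r *= m ** eff.r_exponent
        # capacity stays positive so that r = 0 yields a standing (not
        # vanishing) culture at n0
        K *= max(m, 1e-9) ** eff.k_exponent
        nadph *= oracle.nadph_modifier(comp.name, fold)
        w = oracle.osmo_weights.get(comp.name, 0.0)
        if w:
            osmo_excess += w * max(0.0, fold - 1.0)
    r *= math.exp(-oracle.osmo_alpha * max(0.0, osmo_excess - oracle.osmo_threshold))
    return float(r), float(K), float(nadph)


def logistic_cells(t: float, r: float, K: float, n0: float) -> float:
    """Logistic timecourse n(t) = K n0 e^{rt} / (K + n0 (e^{rt} - 1))."""
    if K <= 0:
        return 0.0
    ert = math.exp(r * t)
    return K * n0 * ert / (K + n0 * (ert - 1.0))


def simulate_measurement(
    oracle: OracleParams,
    combo: MediumCombination,
    n_replicates: int = 3,
    rng_seed: int = 0,
) -> CultureObservation:
    """Simulate replicate A450 readings of one medium at every oracle timepoint."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    r, K, nadph = growth_response(oracle, combo)
    rng = np.random.default_rng(rng_seed)
    raw: Dict[float, np.ndarray] = {}
    blanked: Dict[float, np.ndarray] = {}
    mean: Dict[float, float] = {}
    for t in oracle.timepoints:
        signal = oracle.assay_scale * nadph * logistic_cells(t, r, K, oracle.n0)
        mult = (
            np.exp(rng.normal(0.0, oracle.noise_sd_mult, size=n_replicates))
            if oracle.noise_sd_mult > 0
            else np.ones(n_replicates)
        )
        add = (
            rng.normal(0.0, oracle.noise_sd_add, size=n_replicates)
            if oracle.noise_sd_add > 0
            else np.zeros(n_replicates)
        )
        raw_t = signal * mult + oracle.blank_a450 + add
        raw[t] = raw_t
        blanked[t] = raw_t - oracle.blank_a450  # noise-free blank mean
        mean[t] = float(np.mean(blanked[t]))
    cid = combo.id if combo.id is not None else "medium"
    return CultureObservation(
        combination_id=cid, raw=raw, blanked=blanked, mean=mean, n_replicates=n_replicates
    )


def _combo_seed(rng_seed: int, combo_id: str) -> int:
    return (int(rng_seed) + zlib.crc32(combo_id.encode())) % (2**31)


def build_dataset(
    oracle: OracleParams,
    combos: Sequence[MediumCombination],
    n_replicates: int = 3,
    rng_seed: int = 0,
    round_label: str = "initial",
    mode: str = "regular",
) -> Dataset:
    """Measure a list of media into a :class:`Dataset`.

    Per-combination seeds are derived from ``rng_seed`` plus a stable hash of
    the combination id, so a combination's replicates do not depend on its
    position in the list.
    """
    if len(combos) == 0:
        raise ValueError("combo list must be non-empty")
    ids = [c.id for c in combos]
    if any(i is None for i in ids):
        raise ValueError("all combinations must carry ids")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate combination ids")
    ds = Dataset(oracle.space)
    for combo in combos:
        obs = simulate_measurement(
            oracle, combo, n_replicates=n_replicates, rng_seed=_combo_seed(rng_seed, combo.id)
        )
        ds.add(combo, obs, round_label=round_label, mode=mode)
    return ds
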