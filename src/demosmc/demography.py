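"""Demographic models, parameter vectors, priors, and the interval→event
time convention.

Five competing models of the out-of-Africa (OOA) settlement of Sahul are
supported, labelled ``A``, ``O``, ``M``, ``AX`` and ``OX``:

* ``A``  — PNG is a sister group of East Asians: ``(EUR,(ASN,PNG))``.
* ``O``  — PNG is an outgroup of Europeans and East Asians:
  ``(PNG,(EUR,ASN))``.
* ``M``  — topology of ``A`` plus an admixture pulse into PNG from an
  unsampled ("ghost") outgroup of Europeans + East Asians.
* ``AX`` — topology of ``A`` plus a pulse from a ghost lineage that left
  Africa before the main OOA event.
* ``OX`` — topology of ``O`` plus the early-OOA ghost pulse.

All models share: an African size change from the ancestral size, an OOA
bottleneck, a Neanderthal pulse into the common OOA branch, a Denisovan
pulse into PNG, exponential growth of EUR/ASN/PNG from their own split
times, and two sequenced archaic genomes whose introgressing relatives
split off deeper in time.

Times are parameterized as *intervals* (thousand years) that chain into
absolute event times; see :func:`resolve_events`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Sequence, Tuple

import msprime
import numpy as np

__all__ = [
    "MODERN_POPULATIONS",
    "ARCHAIC_POPULATIONS",
    "POPULATION_ORDER",
    "SIZE_PARAMS",
    "INTERVAL_PARAMS",
    "FRACTION_PARAMS",
    "GHOST_PARAMS",
    "MODEL_A_BEST_FIT",
    "SimulationConstants",
    "ParameterVector",
    "EventSchedule",
    "PriorBox",
    "ModelSpec",
    "MinimalModelSpec",
    "SampleConfig",
    "resolve_events",
    "build_demography",
    "build_minimal_demography",
    "default_priors",
    "sample_prior",
]

MODERN_POPULATIONS: Tuple[str, ...] = ("AFR", "EUR", "ASN", "PNG")
ARCHAIC_POPULATIONS: Tuple[str, ...] = ("NEA", "DEN")
#: Canonical population order used throughout the cSFS machinery.
POPULATION_ORDER: Tuple[str, ...] = MODERN_POPULATIONS + ARCHAIC_POPULATIONS

SIZE_PARAMS: Tuple[str, ...] = (
    "N_A", "N_AF", "N_EU", "N_AS", "N_PA", "N_NE", "N_DE",
    "N_EU0", "N_AS0", "N_PA0", "N_B", "N_ND",
)
#: Interval parameters in chain order, thousand years.
INTERVAL_PARAMS: Tuple[str, ...] = (
    "T_DPM", "T_AS_PA", "T_EU_AS", "T_NOM", "T_B", "T_AF",
    "T_NI_NS", "T_DI_DS", "T_N_D", "T_H_A",
)
FRACTION_PARAMS: Tuple[str, ...] = ("NEA_m_OOA", "DEN_m_PAP")
#: Extra parameters for the ghost-admixture models (M, AX, OX).
GHOST_PARAMS: Tuple[str, ...] = ("ghost_m", "ghost_split_frac")

GHOST_MODELS = frozenset({"M", "AX", "OX"})
MODEL_IDS: Tuple[str, ...] = ("A", "O", "M", "AX", "OX")
MIGRATION_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("AFR", "EUR"), ("AFR", "ASN"), ("AFR", "PNG"),
    ("EUR", "ASN"), ("EUR", "PNG"), ("ASN", "PNG"),
)

#: Published best-fit parameter values for model A (admixture fractions
#: stored as proportions, not percent).
MODEL_A_BEST_FIT: Dict[str, float] = {
    "N_A": 19_308.0,
    "N_AF": 43_477.0,
    "N_EU": 71_931.0,
    "N_AS": 94_703.0,
    "N_PA": 32_085.0,
    "N_NE": 2_360.0,
    "N_DE": 2_535.0,
    "N_EU0": 3_512.0,
    "N_AS0": 1_771.0,
    "N_PA0": 674.0,
    "N_B": 726.0,
    "N_ND": 15_324.0,
    "T_DPM": 31.3,
    "T_AS_PA": 14.9,
    "T_EU_AS": 5.0,
    "T_NOM": 0.9,
    "T_B": 10.3,
    "T_AF": 43.2,
    "T_NI_NS": 200.6,
    "T_DI_DS": 276.0,
    "T_N_D": 14.3,
    "T_H_A": 269.8,
    "NEA_m_OOA": 0.0404,
    "DEN_m_PAP": 0.0323,
}


@dataclass(frozen=True)
class SimulationConstants:
    """Fixed per-generation rates and the year↔generation conversion."""

    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1e-8
    generation_time: float = 29.0

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "recombination_rate", "generation_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def ky_to_generations(self, t_ky: float) -> float:
        return t_ky * 1000.0 / self.generation_time

    def years_to_generations(self, t_years: float) -> float:
        return t_years / self.generation_time


def parameter_names(model_id: str, migration_variant: str = "none") -> Tuple[str, ...]:
    """Ordered parameter names for a model: 24 for A/O, 26 for M/AX/OX,
    plus six pairwise migration rates when a migration variant is enabled.
    """
    names: Tuple[str, ...] = SIZE_PARAMS + INTERVAL_PARAMS + FRACTION_PARAMS
    if model_id in GHOST_MODELS:
        names = names + GHOST_PARAMS
    if migration_variant != "none":
        names = names + tuple(f"m_{a}_{b}" for a, b in MIGRATION_PAIRS)
    return names


class ParameterVector(Mapping[str, float]):
    """An ordered mapping of demographic parameters for one model.

    Sizes are diploid effective sizes, ``T_*`` entries are time intervals
    in thousand years (see :func:`resolve_events`) and admixture entries
    are proportions in [0, 1].
    """

    def __init__(self, model_id: str, values: Mapping[str, float],
                 migration_variant: str = "none"):
        if model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {model_id!r}")
        self.model_id = model_id
        self.migration_variant = migration_variant
        self.names = parameter_names(model_id, migration_variant)
        missing = [n for n in self.names if n not in values]
        if missing:
            raise ValueError(f"missing parameters for model {model_id}: {missing}")
        self._values = {n: float(values[n]) for n in self.names}
        self.validate()

    def validate(self) -> None:
        for n in SIZE_PARAMS:
            if self._values[n] <= 0:
                raise ValueError(f"population size {n} must be > 0")
        for n in INTERVAL_PARAMS:
            if self._values[n] < 0:
                raise ValueError(f"time interval {n} must be >= 0")
        frac_names = list(FRACTION_PARAMS)
        if self.model_id in GHOST_MODELS:
            frac_names += list(GHOST_PARAMS)
        for n in frac_names:
            if not 0.0 <= self._values[n] <= 1.0:
                raise ValueError(f"fraction {n} must lie in [0, 1]")

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def to_array(self) -> np.ndarray:
        return np.array([self._values[n] for n in self.names], dtype=float)

    @classmethod
    def from_array(cls, model_id: str, values: Sequence[float],
                   migration_variant: str = "none") -> "ParameterVector":
        names = parameter_names(model_id, migration_variant)
        if len(values) != len(names):
            raise ValueError(
                f"expected {len(names)} values for model {model_id}, got {len(values)}"
            )
        return cls(model_id, dict(zip(names, values)), migration_variant)

    def replace(self, **updates: float) -> "ParameterVector":
        vals = dict(self._values)
        vals.update(updates)
        return ParameterVector(self.model_id, vals, self.migration_variant)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ParameterVector(model={self.model_id}, {self._values})"


@dataclass(frozen=True)
class EventSchedule:
    """Absolute event times (thousand years ago) for each interval parameter."""

    events: Dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.events[key]


@dataclass(frozen=True)
class ModelSpec:
    """Which model topology to build and how.

    ``migration_variant`` adds symmetric migration between modern-human
    pairs after their separation, with per-generation rate bounded by
    5e-5 (``low``) or 5e-4 (``high``).  Archaic sampling ages are in
    years before present.
    """

    model_id: str
    migration_variant: str = "none"
    nea_sample_age: float = 120_000.0
    den_sample_age: float = 60_000.0
    #: Width (ky) of the window before the OOA split in which the AX/OX
    #: ghost lineage diverges from Africans.
    ghost_window_ky: float = 60.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if self.migration_variant not in ("none", "low", "high"):
            raise ValueError(f"unknown migration variant {self.migration_variant!r}")

    @property
    def has_ghost(self) -> bool:
        return self.model_id in GHOST_MODELS

    @property
    def migration_rate_bound(self) -> float:
        return {"none": 0.0, "low": 5e-5, "high": 5e-4}[self.migration_variant]

    def parameter_names(self) -> Tuple[str, ...]:
        return parameter_names(self.model_id, self.migration_variant)


@dataclass(frozen=True)
class MinimalModelSpec:
    """Three-population (AFR, EUR, PNG) model used to probe how bottleneck
    size and growth rate move cross-coalescence-rate curves.

    The ancestral and African sizes are fixed at 10,000 diploids; EUR
    grows at 0.2% per generation from the EUR/PNG split.
    """

    african_split_kya: float = 80.0
    png_bottleneck_size: float = 10_000.0
    png_growth_rate: float = 0.0
    eur_png_split_kya: float = 50.0
    ancestral_size: float = 10_000.0
    eur_growth_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.african_split_kya not in (80.0, 300.0):
            raise ValueError("african_split_kya must be 80 or 300")
        if not 500.0 <= self.png_bottleneck_size <= 10_000.0:
            raise ValueError("png_bottleneck_size must lie in [500, 10000]")
        if not 0.0 <= self.png_growth_rate <= 0.002:
            raise ValueError("png_growth_rate must lie in [0, 0.002]")


@dataclass(frozen=True)
class SampleConfig:
    """Diploid sample counts (and sampling ages in years) per population."""

    counts: Dict[str, int]
    ages: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative sample count for {pop}")

    @classmethod
    def canonical_csfs(cls, spec: ModelSpec | None = None) -> "SampleConfig":
        """5 diploids per modern population, 1 per archaic genome."""
        ages = {}
        if spec is not None:
            ages = {"NEA": spec.nea_sample_age, "DEN": spec.den_sample_age}
        counts = {p: 5 for p in MODERN_POPULATIONS}
        counts.update({p: 1 for p in ARCHAIC_POPULATIONS})
        return cls(counts=counts, ages=ages)

    @classmethod
    def rccr(cls, n: int = 40) -> "SampleConfig":
        return cls(counts={p: n for p in MODERN_POPULATIONS})

    @property
    def populations(self) -> List[str]:
        return [p for p in self.counts if self.counts[p] > 0]

    @property
    def total_diploids(self) -> int:
        return sum(self.counts.values())

    def haplotype_counts(self) -> Dict[str, int]:
        return {p: 2 * n for p, n in self.counts.items()}


def resolve_events(params: ParameterVector, spec: ModelSpec) -> EventSchedule:
    """Convert interval parameters to absolute event times (kya).

    Chains, most recent first:

    * modern chain: ``T_DPM → T_AS_PA → T_EU_AS → T_NOM → T_B → T_AF``
      (each event = previous event + interval);
    * Neanderthal split: ``event(T_NI_NS) = event(T_NOM) + T_NI_NS``;
    * Denisovan split: ``event(T_DI_DS) = event(T_DPM) + T_DI_DS``;
    * archaic chain: ``event(T_N_D) = event(T_DI_DS) + T_N_D`` and
      ``event(T_H_A) = event(T_N_D) + T_H_A``.
    """
    for name in INTERVAL_PARAMS:
        if params[name] < 0:
            raise ValueError(f"negative interval {name}")
    ev: Dict[str, float] = {}
    ev["T_DPM"] = params["T_DPM"]
    ev["T_AS_PA"] = ev["T_DPM"] + params["T_AS_PA"]
    ev["T_EU_AS"] = ev["T_AS_PA"] + params["T_EU_AS"]
    ev["T_NOM"] = ev["T_EU_AS"] + params["T_NOM"]
    ev["T_B"] = ev["T_NOM"] + params["T_B"]
    ev["T_AF"] = ev["T_B"] + params["T_AF"]
    ev["T_NI_NS"] = ev["T_NOM"] + params["T_NI_NS"]
    ev["T_DI_DS"] = ev["T_DPM"] + params["T_DI_DS"]
    ev["T_N_D"] = ev["T_DI_DS"] + params["T_N_D"]
    ev["T_H_A"] = ev["T_N_D"] + params["T_H_A"]
    return EventSchedule(events=ev)


def _growth_rate(n_modern: float, n_start: float, duration_gen: float) -> float:
    if duration_gen <= 0:
        return 0.0
    return float(np.log(n_modern / n_start) / duration_gen)


def build_demography(
    spec: ModelSpec,
    params: ParameterVector,
    constants: SimulationConstants = SimulationConstants(),
) -> msprime.Demography:
    """Compile a model + parameter vector into an ``msprime.Demography``.

    Population labels: the four modern populations, the two sequenced
    archaic genomes (``NEA``, ``DEN``), their introgressing relatives
    (``NEAI``, ``DENI``, sharing the sequenced sizes), and ``GHO`` for the
    ghost lineage of models M/AX/OX.  Internal ancestral branches:
    ``XPH`` (the younger inner modern split), ``OOA`` (bottlenecked
    out-of-Africa branch, size ``N_B``), ``ARC`` (Neanderthal+Denisova
    ancestor) and ``ANC`` (root).
    """
    ev = resolve_events(params, spec)
    gen = constants.ky_to_generations
    t_dpm = gen(ev["T_DPM"])
    t_inner = gen(ev["T_AS_PA"])   # younger modern split
    t_outer = gen(ev["T_EU_AS"])   # older modern split
    t_nom = gen(ev["T_NOM"])
    t_b = gen(ev["T_B"])
    t_af = gen(ev["T_AF"])
    t_nins = gen(ev["T_NI_NS"])
    t_dids = gen(ev["T_DI_DS"])
    t_nd = gen(ev["T_N_D"])
    t_ha = gen(ev["T_H_A"])
    # reject draws whose event ordering is inconsistent (zero-length
    # intervals are tolerated except for the Denisovan pulse, which must
    # strictly predate the inner modern split)
    if t_dpm >= t_inner:
        raise ValueError("Denisovan pulse must be more recent than the inner split")
    if t_nins >= t_nd:
        raise ValueError(
            "Neanderthal introgressing-lineage split must predate the "
            "Neanderthal/Denisovan common-ancestor event"
        )
    if t_af >= t_ha:
        raise ValueError(
            "African size change must predate the human/archaic split"
        )
    if spec.nea_sample_age / constants.generation_time >= t_nins:
        raise ValueError("Neanderthal sampled older than its population split")
    if spec.den_sample_age / constants.generation_time >= t_dids:
        raise ValueError("Denisovan sampled older than its population split")

    outgroup = "PNG" if spec.model_id in ("O", "OX") else "EUR"
    inner = [p for p in ("EUR", "ASN", "PNG") if p != outgroup]
    # growth starts at each terminal population's own founding split
    split_time = {outgroup: t_outer, inner[0]: t_inner, inner[1]: t_inner}
    start_size = {"EUR": params["N_EU0"], "ASN": params["N_AS0"], "PNG": params["N_PA0"]}
    modern_size = {"EUR": params["N_EU"], "ASN": params["N_AS"], "PNG": params["N_PA"]}

    dem = msprime.Demography()
    # AFR / NEA / DEN are ancestral ends of splits but hold samples, so
    # they must be active from the start
    dem.add_population(name="AFR", initial_size=params["N_AF"], initially_active=True)
    for pop in ("EUR", "ASN", "PNG"):
        dem.add_population(
            name=pop,
            initial_size=modern_size[pop],
            growth_rate=_growth_rate(modern_size[pop], start_size[pop], split_time[pop]),
        )
    dem.add_population(name="NEA", initial_size=params["N_NE"], initially_active=True)
    dem.add_population(name="DEN", initial_size=params["N_DE"], initially_active=True)
    dem.add_population(name="NEAI", initial_size=params["N_NE"])
    dem.add_population(name="DENI", initial_size=params["N_DE"])
    dem.add_population(name="XPH", initial_size=params["N_B"])
    dem.add_population(name="OOA", initial_size=params["N_B"])
    dem.add_population(name="ARC", initial_size=params["N_ND"])
    dem.add_population(name="ANC", initial_size=params["N_A"])

    t_ghost = None
    if spec.has_ghost:
        dem.add_population(name="GHO", initial_size=params["N_B"])
        frac = float(np.clip(params["ghost_split_frac"], 1e-6, 1.0 - 1e-6))
        if spec.model_id == "M":
            # ghost splits from the OOA branch between the outer modern
            # split and the OOA bottleneck
            t_ghost = t_outer + frac * (t_b - t_outer)
        else:  # AX / OX: ghost splits from Africans before the OOA event
            t_ghost = t_b + frac * gen(spec.ghost_window_ky)

    # ---- events, most recent first -----------------------------------
    dem.add_mass_migration(time=t_dpm, source="PNG", dest="DENI",
                           proportion=params["DEN_m_PAP"])
    if spec.has_ghost:
        dem.add_mass_migration(time=t_dpm, source="PNG", dest="GHO",
                               proportion=params["ghost_m"])
    dem.add_population_split(time=t_inner, derived=inner, ancestral="XPH")
    dem.add_population_split(time=t_outer, derived=[outgroup, "XPH"], ancestral="OOA")
    dem.add_mass_migration(time=t_nom, source="OOA", dest="NEAI",
                           proportion=params["NEA_m_OOA"])
    if spec.has_ghost and spec.model_id == "M":
        dem.add_population_split(time=t_ghost, derived=["GHO"], ancestral="OOA")
    dem.add_population_split(time=t_b, derived=["OOA"], ancestral="AFR")
    if spec.has_ghost and spec.model_id in ("AX", "OX"):
        dem.add_population_split(time=t_ghost, derived=["GHO"], ancestral="AFR")
    dem.add_population_parameters_change(time=t_af, population="AFR",
                                         initial_size=params["N_A"])
    dem.add_population_split(time=t_nins, derived=["NEAI"], ancestral="NEA")
    dem.add_population_split(time=t_dids, derived=["DENI"], ancestral="DEN")
    dem.add_population_split(time=t_nd, derived=["NEA", "DEN"], ancestral="ARC")
    dem.add_population_split(time=t_ha, derived=["AFR", "ARC"], ancestral="ANC")

    if spec.migration_variant != "none":
        for a, b in MIGRATION_PAIRS:
            rate = params[f"m_{a}_{b}"]
            if rate > 0:
                dem.set_symmetric_migration_rate([a, b], rate)

    dem.sort_events()
    return dem


def build_minimal_demography(
    spec: MinimalModelSpec,
    constants: SimulationConstants = SimulationConstants(),
) -> msprime.Demography:
    """Compile the three-population minimal OOA model."""
    gen = constants.ky_to_generations
    t_split = gen(spec.eur_png_split_kya)
    t_afr = gen(spec.african_split_kya)
    n0 = spec.ancestral_size
    eur_modern = n0 * np.exp(spec.eur_growth_rate * t_split)
    png_modern = spec.png_bottleneck_size * np.exp(spec.png_growth_rate * t_split)

    dem = msprime.Demography()
    dem.add_population(name="AFR", initial_size=n0)
    dem.add_population(name="EUR", initial_size=eur_modern,
                       growth_rate=spec.eur_growth_rate)
    dem.add_population(name="PNG", initial_size=png_modern,
                       growth_rate=spec.png_growth_rate)
    dem.add_population(name="OOA", initial_size=n0)
    dem.add_population(name="ANC", initial_size=n0)
    dem.add_population_split(time=t_split, derived=["EUR", "PNG"], ancestral="OOA")
    dem.add_population_split(time=t_afr, derived=["AFR", "OOA"], ancestral="ANC")
    dem.sort_events()
    return dem


@dataclass(frozen=True)
class PriorBox:
    """Independent-uniform prior bounds, one (lower, upper) pair per
    parameter, in the same units as :class:`ParameterVector`."""

    names: Tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if not (len(self.names) == lower.size == upper.size):
            raise ValueError("names/lower/upper length mismatch")
        if np.any(lower > upper):
            bad = [self.names[i] for i in np.nonzero(lower > upper)[0]]
            raise ValueError(f"empty prior box for {bad}")

    def bounds(self, name: str) -> Tuple[float, float]:
        i = self.names.index(name)
        return float(self.lower[i]), float(self.upper[i])

    def contains(self, values: np.ndarray) -> bool:
        v = np.asarray(values, dtype=float)
        return bool(np.all(v >= self.lower - 1e-12) and np.all(v <= self.upper + 1e-12))

    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def scale(self, values: np.ndarray) -> np.ndarray:
        """Map parameter values into [0, 1] per dimension (degenerate
        dimensions map to 0)."""
        w = self.width()
        safe = np.where(w > 0, w, 1.0)
        return (np.asarray(values, dtype=float) - self.lower) / safe

    def unscale(self, unit_values: np.ndarray) -> np.ndarray:
        return self.lower + np.asarray(unit_values, dtype=float) * self.width()

    def replace_bounds(self, lower: np.ndarray, upper: np.ndarray) -> "PriorBox":
        return PriorBox(self.names, np.asarray(lower), np.asarray(upper))

    def with_overrides(self, overrides: Mapping[str, Tuple[float, float]]) -> "PriorBox":
        lower = self.lower.copy()
        upper = self.upper.copy()
        for name, (lo, hi) in overrides.items():
            i = self.names.index(name)
            lower[i], upper[i] = lo, hi
        return PriorBox(self.names, lower, upper)


_DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "N_A": (5_000.0, 60_000.0),
    "N_AF": (10_000.0, 60_000.0),
    "N_EU": (10_000.0, 150_000.0),
    "N_AS": (10_000.0, 150_000.0),
    "N_PA": (10_000.0, 50_000.0),
    "N_NE": (500.0, 30_000.0),
    "N_DE": (500.0, 30_000.0),
    "N_EU0": (100.0, 5_000.0),
    "N_AS0": (100.0, 5_000.0),
    "N_PA0": (100.0, 5_000.0),
    "N_B": (100.0, 5_000.0),
    "N_ND": (500.0, 30_000.0),
    "T_DPM": (10.0, 100.0),
    "T_AS_PA": (0.5, 50.0),
    "T_EU_AS": (0.5, 50.0),
    "T_NOM": (0.5, 50.0),
    "T_B": (0.5, 50.0),
    "T_AF": (0.5, 50.0),
    "T_NI_NS": (50.0, 400.0),
    "T_DI_DS": (50.0, 400.0),
    "T_N_D": (0.5, 100.0),
    "T_H_A": (100.0, 400.0),
    "NEA_m_OOA": (0.01, 0.05),
    "DEN_m_PAP": (0.01, 0.05),
    "ghost_m": (0.01, 0.99),
    "ghost_split_frac": (0.0, 1.0),
}


def default_priors(spec: ModelSpec) -> PriorBox:
    """Default prior box for a model.

    Bounds for modern sizes, ``T_DPM``, the chained modern intervals, and
    the admixture fractions follow the published design; bottleneck sizes,
    archaic split intervals, and ghost parameters use documented defaults
    wide enough to contain the best-fit values.  Migration rates, when a
    variant is enabled, are uniform on [0, bound].
    """
    names = spec.parameter_names()
    lower, upper = [], []
    for n in names:
        if n.startswith("m_"):
            lo, hi = 0.0, spec.migration_rate_bound
        else:
            lo, hi = _DEFAULT_BOUNDS[n]
        lower.append(lo)
        upper.append(hi)
    return PriorBox(tuple(names), np.array(lower), np.array(upper))


def sample_prior(box: PriorBox, n: int, seed: int) -> List[np.ndarray]:
    """Draw ``n`` independent uniform vectors from the box (reproducible)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(box.lower, box.upper, size=(n, box.lower.size))
    return [draws[i] for i in range(n)]


def sample_prior_vectors(
    box: PriorBox, spec: ModelSpec, n: int, seed: int
) -> List[ParameterVector]:
    """As :func:`sample_prior` but wrapping each draw in a ParameterVector."""
    return [
        ParameterVector.from_array(spec.model_id, v, spec.migration_variant)
        for v in sample_prior(box, n, seed)
    ]
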