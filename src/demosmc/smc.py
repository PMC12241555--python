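"""Sequential Monte Carlo refinement: simulate → train regressor → ABC,
with the posterior range becoming the next cycle's prior range and the
simulated sequence length growing along a schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from demosmc.demography import (
    ModelSpec,
    ParameterVector,
    PriorBox,
    SampleConfig,
    SimulationConstants,
    build_demography,
)
from demosmc.inference import (
    NetSpec,
    ParamPosterior,
    ReferenceTable,
    abc_parameters,
    train_network,
)
from demosmc.sfs import csfs, joint_sfs
from demosmc.simulate import SimulationPlan, simulate_genomes

__all__ = [
    "LengthSchedule",
    "SMCState",
    "simulate_reference",
    "smc_cycle",
    "run_smc",
]

#: Canonical per-sample sequence lengths (bases) for successive SMC stages.
CANONICAL_LENGTHS = (100e6, 500e6, 1.5e9, 3e9)


@dataclass(frozen=True)
class LengthSchedule:
    """Strictly increasing sequence lengths, optionally desk-scaled."""

    lengths: Tuple[float, ...] = CANONICAL_LENGTHS
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("schedule must be nonempty")
        if np.any(np.diff(self.lengths) <= 0):
            raise ValueError("schedule lengths must strictly increase")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def scaled(self) -> Tuple[float, ...]:
        return tuple(l * self.scale for l in self.lengths)


@dataclass
class SMCState:
    """Mutable record of the SMC iteration."""

    cycle: int
    box: PriorBox
    sequence_length: float
    shrinkage: List[np.ndarray] = field(default_factory=list)
    estimates: List[np.ndarray] = field(default_factory=list)
    posterior: Optional[ParamPosterior] = None

    def geometric_shrinkage(self) -> float:
        """Geometric mean of the last cycle's posterior/prior width ratios."""
        if not self.shrinkage:
            return 1.0
        r = self.shrinkage[-1]
        r = r[r > 0]
        return float(np.exp(np.mean(np.log(r)))) if r.size else 0.0


def simulate_reference(
    spec: ModelSpec,
    box: PriorBox,
    samples: SampleConfig,
    n_sims: int,
    sequence_length: float,
    seed: int,
    constants: SimulationConstants = SimulationConstants(),
    pop_order: Optional[Sequence[str]] = None,
    chunk_length: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw ``n_sims`` parameter vectors from the box, simulate each, and
    return (cSFS feature matrix, true parameter matrix)."""
    if pop_order is None:
        pop_order = samples.populations
    features = []
    params = []
    chunk = chunk_length or max(sequence_length, 1.0)
    rng = np.random.default_rng(seed)
    attempts = 0
    max_attempts = 100 * max(n_sims, 1)
    i = 0
    while i < n_sims:
        if attempts >= max_attempts:
            raise RuntimeError("too many invalid prior draws rejected")
        attempts += 1
        values = rng.uniform(box.lower, box.upper)
        pv = ParameterVector.from_array(spec.model_id, values, spec.migration_variant)
        try:
            dem = build_demography(spec, pv, constants)
        except ValueError:
            continue  # event ordering violated: reject the draw
        plan = SimulationPlan(sequence_length, chunk, base_seed=seed + 1000 * (i + 1))
        chunks = simulate_genomes(dem, samples, plan, constants)
        joint = joint_sfs(chunks, samples, pop_order=pop_order)
        features.append(csfs(joint))
        params.append(values)
        i += 1
    return np.vstack(features), np.vstack(params)


def smc_cycle(
    state: SMCState,
    observed: np.ndarray,
    spec: ModelSpec,
    samples: SampleConfig,
    n_sims: int,
    net: NetSpec,
    seed: int,
    tolerance: float = 0.05,
    train_fraction: float = 0.5,
    constants: SimulationConstants = SimulationConstants(),
    pop_order: Optional[Sequence[str]] = None,
    interval_quantiles: Tuple[float, float] = (2.5, 97.5),
    observed_length: Optional[float] = None,
    reference_factory: Optional[Callable[..., Tuple[np.ndarray, np.ndarray]]] = None,
) -> SMCState:
    """Run one cycle and return the refined state.

    The next prior box is the accepted draws' 2.5–97.5 percentile range
    intersected with the current box (outlier-resistant refinement).
    ``reference_factory(box, n_sims, sequence_length, seed)`` may replace
    the coalescent simulator (used by identity-map experiments).
    """
    if n_sims < 20:
        raise ValueError("n_sims too small for a train/validation split")
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    if observed_length is not None and observed_length > 0:
        # bring observed counts onto the reference-table length scale
        observed = observed * (state.sequence_length / observed_length)
    if reference_factory is not None:
        features, params = reference_factory(
            state.box, n_sims, state.sequence_length, seed)
    else:
        features, params = simulate_reference(
            spec, state.box, samples, n_sims, state.sequence_length, seed,
            constants=constants, pop_order=pop_order,
        )
    n_train = max(10, int(round(train_fraction * n_sims)))
    table = ReferenceTable(
        features=features,
        labels=params,
        n_train=n_train,
        prior_box=state.box,
    )
    predictor = train_network(table, net, seed=seed + 7)
    x_val, y_val = table.validation_split()
    val_pred = predictor.predict(x_val)
    obs_pred = predictor.predict(np.atleast_2d(observed))
    posterior = abc_parameters(
        predictions=val_pred,
        true_parameters=y_val,
        observed=obs_pred,
        names=state.box.names,
        tolerance=tolerance,
    )
    q_lo, q_hi = interval_quantiles
    lo = np.percentile(posterior.accepted, q_lo, axis=0)
    hi = np.percentile(posterior.accepted, q_hi, axis=0)
    new_lower = np.maximum(state.box.lower, lo)
    new_upper = np.minimum(state.box.upper, hi)
    # guard: keep the box from collapsing to a point
    degenerate = new_upper <= new_lower
    if np.all(degenerate):
        raise RuntimeError("posterior box degenerate in every dimension")
    new_upper = np.where(degenerate, state.box.upper, new_upper)
    new_lower = np.where(degenerate, state.box.lower, new_lower)
    new_box = state.box.replace_bounds(new_lower, new_upper)

    old_width = state.box.width()
    ratios = np.where(old_width > 0, new_box.width() / np.maximum(old_width, 1e-300), 1.0)
    new_state = SMCState(
        cycle=state.cycle + 1,
        box=new_box,
        sequence_length=state.sequence_length,
        shrinkage=state.shrinkage + [ratios],
        estimates=state.estimates + [posterior.point_estimate],
        posterior=posterior,
    )
    return new_state


def run_smc(
    initial_box: PriorBox,
    observed: np.ndarray,
    spec: ModelSpec,
    samples: SampleConfig,
    schedule: LengthSchedule,
    net: NetSpec,
    n_sims: int | Sequence[int],
    seed: int,
    tolerance: float = 0.05,
    convergence_threshold: float = 0.95,
    convergence_cycles: int = 2,
    max_cycles_per_length: int = 10,
    constants: SimulationConstants = SimulationConstants(),
    pop_order: Optional[Sequence[str]] = None,
    observed_length: Optional[float] = None,
    reference_factory: Optional[Callable[..., Tuple[np.ndarray, np.ndarray]]] = None,
) -> Tuple[ParamPosterior, List[SMCState]]:
    """Iterate cycles at each schedule length until the geometric-mean
    shrinkage exceeds ``convergence_threshold`` for ``convergence_cycles``
    consecutive cycles, then advance to the next length."""
    lengths = schedule.scaled()
    if np.isscalar(n_sims):
        n_sims_per_length = [int(n_sims)] * len(lengths)
    else:
        if len(n_sims) != len(lengths):
            raise ValueError("n_sims sequence must match the schedule length")
        n_sims_per_length = [int(n) for n in n_sims]
    state = SMCState(cycle=0, box=initial_box, sequence_length=lengths[0])
    trace: List[SMCState] = [state]
    cycle_seed = seed
    for length, length_n_sims in zip(lengths, n_sims_per_length):
        state = SMCState(
            cycle=state.cycle, box=state.box, sequence_length=length,
            shrinkage=state.shrinkage, estimates=state.estimates,
            posterior=state.posterior,
        )
        # a threshold of 1 (or more) declares convergence immediately:
        # the box can never widen, so one cycle per length suffices
        trivial = convergence_threshold >= 1.0
        needed = 1 if trivial else convergence_cycles
        flat_cycles = 0
        for _ in range(max_cycles_per_length):
            cycle_seed += 10_000
            state = smc_cycle(
                state, observed, spec, samples, length_n_sims, net, cycle_seed,
                tolerance=tolerance, constants=constants, pop_order=pop_order,
                observed_length=observed_length,
                reference_factory=reference_factory,
            )
            trace.append(state)
            if trivial or state.geometric_shrinkage() >= convergence_threshold:
                flat_cycles += 1
            else:
                flat_cycles = 0
            if flat_cycles >= needed:
                break
        else:
            warnings.warn(
                f"max cycles reached at length {length:g} without convergence",
                stacklevel=2,
            )
    if state.posterior is None:
        raise RuntimeError("SMC produced no posterior")
    return state.posterior, trace
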