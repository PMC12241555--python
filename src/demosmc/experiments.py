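"""Canned end-to-end experiments: best-fit parameter recovery on
pseudo-observed data and the classifier ghost-admixture confusion sweep.

Both are deterministic given their seeds and scale down cleanly; the
acceptance checks and the command-line reports run these drivers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from demosmc.demography import (
    MODEL_A_BEST_FIT,
    POPULATION_ORDER,
    ModelSpec,
    ParameterVector,
    SampleConfig,
    default_priors,
    resolve_events,
)
from demosmc.inference import (
    NetSpec,
    ParamPosterior,
    ReferenceTable,
    abc_model_choice,
    train_network,
)
from demosmc.smc import LengthSchedule, SMCState, run_smc, simulate_reference
from demosmc.synthetic_data import PseudoObserved, make_pseudo_observed

__all__ = ["RecoveryResult", "recover_best_fit", "confusion_sweep"]

MODEL_IDS = ("A", "O", "M", "AX", "OX")


@dataclass
class RecoveryResult:
    """Outcome of a Model-A best-fit recovery run."""

    pseudo: PseudoObserved
    posterior: ParamPosterior
    trace: List[SMCState]
    #: point estimates / intervals in reporting units: admixtures in
    #: percent, sizes in diploids, event times in kya
    report: Dict[str, Dict[str, float]]


def _event_time(values: np.ndarray, names: Sequence[str], interval: str) -> float:
    pv = ParameterVector.from_array("A", values)
    return resolve_events(pv, ModelSpec("A"))[interval]


def recover_best_fit(
    seed: int,
    observed_length: float = 30e6,
    stage_lengths: Sequence[float] = (2e6, 6e6),
    n_sims: int | Sequence[int] = 300,
    net: Optional[NetSpec] = None,
    tolerance: float = 0.1,
) -> RecoveryResult:
    """Simulate pseudo-observed cSFS under the published best-fit Model A
    parameters and run reduced-budget SMC recovery against them.

    The report includes the recovered Neanderthal and Denisovan admixture
    percentages, the PNG pre-growth size, and the African/OOA and
    East-Asian/PNG divergence event times (kya, via interval chaining).
    """
    if net is None:
        net = NetSpec(max_epochs=400, early_stop_patience=80)
    spec = ModelSpec("A")
    truth = ParameterVector("A", MODEL_A_BEST_FIT)
    pseudo = make_pseudo_observed(
        "A", truth, observed_length, seed=seed, chunk_length=10e6)
    box = default_priors(spec)
    samples = SampleConfig.canonical_csfs(spec)
    posterior, trace = run_smc(
        box, pseudo.replicates, spec, samples,
        LengthSchedule(tuple(stage_lengths)), net,
        n_sims=n_sims, seed=seed + 1, tolerance=tolerance,
        convergence_threshold=1.0, pop_order=list(POPULATION_ORDER),
        observed_length=observed_length,
    )
    names = list(posterior.names)
    est = posterior.point_estimate
    lo, hi = posterior.interval_low, posterior.interval_high

    def entry(value, low, high, truth_val):
        return {
            "estimate": float(value),
            "low": float(low),
            "high": float(high),
            "truth": float(truth_val),
            "relative_error": float(abs(value - truth_val) / abs(truth_val)),
            "in_interval": bool(low - 1e-12 <= truth_val <= high + 1e-12),
        }

    i_nea = names.index("NEA_m_OOA")
    i_den = names.index("DEN_m_PAP")
    i_pa0 = names.index("N_PA0")
    report = {
        "NEA_m_OOA_pct": entry(100 * est[i_nea], 100 * lo[i_nea],
                               100 * hi[i_nea], 100 * truth["NEA_m_OOA"]),
        "DEN_m_PAP_pct": entry(100 * est[i_den], 100 * lo[i_den],
                               100 * hi[i_den], 100 * truth["DEN_m_PAP"]),
        "N_PA0": entry(est[i_pa0], lo[i_pa0], hi[i_pa0], truth["N_PA0"]),
    }
    # event times via chained accumulation: point estimate from the
    # recovered intervals; interval bounds from the accepted draws
    truth_events = resolve_events(truth, spec)
    for interval, key in (("T_B", "event_T_B_kya"),
                          ("T_AS_PA", "event_T_AS_PA_kya")):
        accepted_events = np.array([
            _event_time(row, names, interval) for row in posterior.accepted
        ])
        report[key] = entry(
            _event_time(est, names, interval),
            np.percentile(accepted_events, 2.5),
            np.percentile(accepted_events, 97.5),
            truth_events[interval],
        )
    return RecoveryResult(pseudo=pseudo, posterior=posterior, trace=trace,
                          report=report)


def confusion_sweep(
    seed: int,
    ghost_fractions: Sequence[float] = (0.02, 0.04),
    n_per_model: int = 60,
    reference_length: float = 1e6,
    observed_length: float = 5e6,
    observed_seeds: Sequence[int] = (1, 2, 3),
    net: Optional[NetSpec] = None,
    tolerance: float = 0.2,
) -> Dict[str, List[Dict[str, float]]]:
    """Train the 5-model classifier and classify pseudo-observed AX / OX
    data across a low ghost-admixture sweep.

    Returns, per case label like ``"AX@0.02"``, one posterior dict per
    observed seed.
    """
    if net is None:
        net = NetSpec(max_epochs=300, early_stop_patience=60)
    feats, labels = [], []
    for mi, mid in enumerate(MODEL_IDS):
        spec = ModelSpec(mid)
        f, _ = simulate_reference(
            spec, default_priors(spec), SampleConfig.canonical_csfs(spec),
            n_per_model, reference_length, seed=seed + 1000 * mi,
            pop_order=list(POPULATION_ORDER))
        feats.append(f)
        labels.append(np.full(n_per_model, mi))
    x = np.vstack(feats)
    y = np.concatenate(labels)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    x, y = x[order], y[order]
    n_train = int(0.7 * len(y))
    table = ReferenceTable(x, y, n_train=n_train, model_ids=MODEL_IDS)
    predictor = train_network(table, net, seed=seed + 7)
    val_pred = predictor.predict(x[n_train:])
    val_y = y[n_train:]

    results: Dict[str, List[Dict[str, float]]] = {}
    for ci, (mid, frac) in enumerate(
            (m, f) for m in ("AX", "OX") for f in ghost_fractions):
        case = f"{mid}@{frac:g}"
        results[case] = []
        for obs_seed in observed_seeds:
            vals = dict(MODEL_A_BEST_FIT,
                        ghost_m=frac, ghost_split_frac=0.5)
            pv = ParameterVector(mid, vals)
            pseudo = make_pseudo_observed(
                mid, pv, observed_length,
                seed=seed + 99 * obs_seed + 13 * ci)
            obs = pseudo.replicates * (reference_length / observed_length)
            post = abc_model_choice(
                val_pred, val_y, predictor.predict(obs), MODEL_IDS,
                tolerance=tolerance)
            results[case].append(
                dict(zip(MODEL_IDS, post.probabilities.tolist())))
    return results
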