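"""Deterministic fixtures: pseudo-observed cSFS replicates under known
truth, toy VCFs with known ground-truth SFS, and labelled sweeps for
classifier-confusion experiments.

Pseudo-observed data mimic the empirical design: one simulation with 15
diploids per modern population plus the two archaic genomes, summarized
three times from disjoint 5-diploid subsets (archaic samples shared).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from demosmc.demography import (
    ARCHAIC_POPULATIONS,
    MODERN_POPULATIONS,
    POPULATION_ORDER,
    ModelSpec,
    ParameterVector,
    SampleConfig,
    SimulationConstants,
    build_demography,
)
from demosmc.inference import ParamPosterior
from demosmc.sfs import JointSFS, csfs, joint_sfs_from_counts
from demosmc.simulate import GenomeChunk, SimulationPlan, simulate_genomes

__all__ = [
    "PseudoObserved",
    "make_pseudo_observed",
    "make_toy_vcf",
    "make_confusion_suite",
    "score_recovery",
]

_SUBSET_SIZE = 5
_POOL_SIZE = 15


@dataclass
class PseudoObserved:
    """Three cSFS replicates plus the generating truth for scoring."""

    model_id: str
    truth: ParameterVector
    replicates: np.ndarray  # (3 × csfs_length)
    sequence_length: float
    seed: int

    def __post_init__(self) -> None:
        if self.replicates.shape[0] != 3:
            raise ValueError("exactly 3 pseudo-observed replicates expected")


def make_pseudo_observed(
    model_id: str,
    params: ParameterVector,
    sequence_length: float,
    seed: int,
    constants: SimulationConstants = SimulationConstants(),
    chunk_length: Optional[float] = None,
    spec: Optional[ModelSpec] = None,
) -> PseudoObserved:
    """Simulate once with 15 diploids per modern population + 2 archaics
    and derive three 5-per-population cSFS vectors from disjoint subsets."""
    if spec is None:
        spec = ModelSpec(model_id)
    dem = build_demography(spec, params, constants)
    counts = {p: _POOL_SIZE for p in MODERN_POPULATIONS}
    counts.update({p: 1 for p in ARCHAIC_POPULATIONS})
    pool = SampleConfig(
        counts=counts,
        ages={"NEA": spec.nea_sample_age, "DEN": spec.den_sample_age},
    )
    plan = SimulationPlan(
        sequence_length, chunk_length or sequence_length, base_seed=seed
    )
    chunks = list(simulate_genomes(dem, pool, plan, constants))

    replicates = []
    for r in range(3):
        vec = _subset_csfs(chunks, pool, subset_index=r)
        replicates.append(vec)
    return PseudoObserved(
        model_id=model_id,
        truth=params,
        replicates=np.vstack(replicates),
        sequence_length=sequence_length,
        seed=seed,
    )


def _subset_csfs(
    chunks: Sequence[GenomeChunk], pool: SampleConfig, subset_index: int
) -> np.ndarray:
    """cSFS from diploids [5r, 5r+5) of each modern population plus the
    shared archaic samples."""
    lo = subset_index * _SUBSET_SIZE
    hi = lo + _SUBSET_SIZE
    pop_order = list(POPULATION_ORDER)
    haplotypes = [2 * _SUBSET_SIZE] * 4 + [2, 2]
    rows = []
    total_length = 0.0
    n_variant = 0
    for chunk in chunks:
        total_length += chunk.length
        if chunk.n_sites == 0:
            continue
        idx = chunk.haplotype_indices()
        cols = []
        for p in pop_order:
            hap = idx[p]
            if p in MODERN_POPULATIONS:
                hap = hap[2 * lo: 2 * hi]
            cols.append(chunk.genotypes[:, hap].sum(axis=1))
        per_pop = np.stack(cols, axis=1)
        # drop sites monomorphic within the subset
        seg = per_pop.sum(axis=1) > 0
        rows.append(per_pop[seg])
        n_variant += int(seg.sum())
    counts = np.vstack(rows) if rows else np.zeros((0, 6), dtype=np.int64)
    joint = joint_sfs_from_counts(counts, pop_order, haplotypes, total_length)
    return csfs(joint)


def make_toy_vcf(
    n_clean: int,
    n_multiallelic: int,
    n_missing: int,
    pops: Mapping[str, int],
    seed: int,
    out_dir: str | Path,
) -> Tuple[Path, Path, JointSFS]:
    """Write a small VCF with a known mix of clean / multiallelic /
    missing-genotype sites and return the ground-truth joint SFS counting
    clean sites only."""
    if min(n_clean, n_multiallelic, n_missing) < 0:
        raise ValueError("site counts must be nonnegative")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / "toy.vcf"
    popmap_path = out_dir / "toy.popmap.txt"

    pop_order = list(pops)
    sample_names = []
    sample_pops = []
    for pop, n in pops.items():
        for k in range(n):
            sample_names.append(f"{pop}_{k}")
            sample_pops.append(pop)
    n_dip = len(sample_names)
    haplotypes = [2 * pops[p] for p in pop_order]
    length = 10_000

    kinds = (["clean"] * n_clean + ["multi"] * n_multiallelic
             + ["missing"] * n_missing)
    rng.shuffle(kinds)
    positions = np.sort(rng.choice(np.arange(1, length), size=len(kinds),
                                   replace=False))
    clean_counts = []
    lines = []
    for pos, kind in zip(positions, kinds):
        gt = rng.integers(0, 2, size=(n_dip, 2))
        if kind == "clean" and gt.sum() == 0:
            gt[rng.integers(n_dip), 0] = 1  # keep clean sites polymorphic
        if kind == "multi":
            alt, info = "T,G", "AA=A"
            gt[rng.integers(n_dip), 0] = 2
        elif kind == "missing":
            alt, info = "T", "AA=A"
        else:
            alt, info = "T", "AA=A"
        alleles = {0: "0", 1: "1", 2: "2"}
        cols = []
        miss_at = rng.integers(n_dip) if kind == "missing" else -1
        for d in range(n_dip):
            if d == miss_at:
                cols.append(".|.")
            else:
                cols.append(f"{alleles[int(gt[d,0])]}|{alleles[int(gt[d,1])]}")
        lines.append(
            f"toy\t{pos}\t.\tA\t{alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(cols)
        )
        if kind == "clean":
            per_pop = np.zeros(len(pop_order), dtype=np.int64)
            for d in range(n_dip):
                per_pop[pop_order.index(sample_pops[d])] += int(gt[d].sum())
            clean_counts.append(per_pop)

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID=toy,length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        for line in lines:
            fh.write(line + "\n")
    with open(popmap_path, "w") as fh:
        for name, pop in zip(sample_names, sample_pops):
            fh.write(f"{name}\t{pop}\n")

    counts = (np.vstack(clean_counts) if clean_counts
              else np.zeros((0, len(pop_order)), dtype=np.int64))
    truth = joint_sfs_from_counts(counts, pop_order, haplotypes, float(length))
    return vcf_path, popmap_path, truth


def make_confusion_suite(
    ghost_fractions: Sequence[float],
    base_params: Mapping[str, float],
    sequence_length: float,
    seed: int,
    model_ids: Sequence[str] = ("A", "M", "AX", "OX"),
    constants: SimulationConstants = SimulationConstants(),
) -> List[PseudoObserved]:
    """Pseudo-observed sets spanning a ghost-admixture sweep.

    Model ``A`` (no ghost) is generated once per call; ghost models get
    one entry per admixture fraction.
    """
    for f in ghost_fractions:
        if not 0.01 <= f <= 0.99:
            raise ValueError("ghost fractions must lie in [0.01, 0.99]")
    suite: List[PseudoObserved] = []
    k = 0
    for model_id in model_ids:
        spec = ModelSpec(model_id)
        if not spec.has_ghost:
            pv = ParameterVector(model_id, dict(base_params))
            suite.append(make_pseudo_observed(
                model_id, pv, sequence_length, seed + 31 * k, constants))
            k += 1
            continue
        for frac in ghost_fractions:
            vals = dict(base_params)
            vals.update(ghost_m=frac, ghost_split_frac=0.5)
            pv = ParameterVector(model_id, vals)
            suite.append(make_pseudo_observed(
                model_id, pv, sequence_length, seed + 31 * k, constants))
            k += 1
    return suite


def score_recovery(
    pseudo: PseudoObserved, posterior: ParamPosterior
) -> Dict[str, Dict[str, float]]:
    """Per-parameter relative error and truth-in-95%-interval coverage."""
    out: Dict[str, Dict[str, float]] = {}
    for i, name in enumerate(posterior.names):
        truth = pseudo.truth[name]
        est = float(posterior.point_estimate[i])
        denom = abs(truth) if truth != 0 else 1.0
        out[name] = {
            "truth": truth,
            "estimate": est,
            "relative_error": abs(est - truth) / denom,
            "in_interval": float(
                posterior.interval_low[i] - 1e-12 <= truth
                <= posterior.interval_high[i] + 1e-12
            ),
        }
    return out
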