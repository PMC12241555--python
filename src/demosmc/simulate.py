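"""Chunked coalescent simulation and VCF export.

Genomes are simulated in independent chunks (deterministic per-chunk
seeds derived from a base seed) so that arbitrarily long sequences never
hold more than one chunk's tree sequence in memory.  Only biallelic
derived mutations are retained; multi-hit sites are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Tuple

import msprime
import numpy as np
import tskit

from demosmc.demography import SampleConfig, SimulationConstants

__all__ = ["SimulationPlan", "GenomeChunk", "simulate_genomes", "export_vcf"]

# offset separating ancestry seeds from mutation seeds
_MUTATION_SEED_OFFSET = 777_000_000


@dataclass(frozen=True)
class SimulationPlan:
    """Total sequence length split into equal chunks, plus the base seed."""

    total_length: float
    chunk_length: float = 10_000_000.0
    base_seed: int = 1

    def __post_init__(self) -> None:
        if self.chunk_length <= 0:
            raise ValueError("chunk length must be > 0")
        if self.total_length <= 0:
            raise ValueError("total length must be > 0")

    @property
    def n_chunks(self) -> int:
        return int(np.ceil(self.total_length / self.chunk_length))

    def chunk_lengths(self) -> List[float]:
        full = int(self.total_length // self.chunk_length)
        lengths = [self.chunk_length] * full
        rest = self.total_length - full * self.chunk_length
        if rest > 0:
            lengths.append(rest)
        return lengths


@dataclass
class GenomeChunk:
    """One simulated chunk: genealogies plus the filtered genotype matrix.

    ``genotypes`` is (sites × haplotypes) with values 0 (ancestral) / 1
    (derived); ``pop_of_haplotype`` labels every haplotype column.
    ``n_dropped_sites`` counts multi-allelic / multi-hit sites removed
    under the infinite-sites approximation.
    """

    length: float
    ts: tskit.TreeSequence
    pop_of_haplotype: List[str]
    genotypes: np.ndarray
    positions: np.ndarray
    n_dropped_sites: int = 0

    @property
    def n_sites(self) -> int:
        return int(self.genotypes.shape[0])

    def haplotype_indices(self) -> Dict[str, np.ndarray]:
        pops = np.asarray(self.pop_of_haplotype)
        return {p: np.nonzero(pops == p)[0] for p in dict.fromkeys(self.pop_of_haplotype)}


def _sample_sets(samples: SampleConfig, constants: SimulationConstants):
    sets = []
    for pop, n in samples.counts.items():
        if n == 0:
            continue
        age_years = samples.ages.get(pop, 0.0)
        sets.append(
            msprime.SampleSet(
                n, population=pop,
                time=constants.years_to_generations(age_years),
            )
        )
    return sets


def _filter_biallelic(ts: tskit.TreeSequence) -> Tuple[np.ndarray, np.ndarray, int]:
    """Return (genotypes 0/1, positions, n_dropped) keeping biallelic
    derived sites only."""
    if ts.num_sites == 0:
        return (np.zeros((0, ts.num_samples), dtype=np.int8),
                np.zeros(0, dtype=np.float64), 0)
    g = ts.genotype_matrix()
    positions = ts.tables.sites.position
    multi = (g > 1).any(axis=1)
    n_dropped = int(multi.sum())
    if n_dropped:
        g = g[~multi]
        positions = positions[~multi]
    return g.astype(np.int8, copy=False), positions, n_dropped


def simulate_chunk(
    demography: msprime.Demography,
    samples: SampleConfig,
    length: float,
    seed: int,
    constants: SimulationConstants = SimulationConstants(),
    mutations: bool = True,
) -> GenomeChunk:
    """Simulate a single chunk of sequence."""
    length = max(1, int(round(length)))  # discrete genome needs integer bases
    ts = msprime.sim_ancestry(
        samples=_sample_sets(samples, constants),
        demography=demography,
        sequence_length=length,
        recombination_rate=constants.recombination_rate,
        random_seed=seed,
    )
    if mutations:
        ts = msprime.sim_mutations(
            ts, rate=constants.mutation_rate,
            random_seed=seed + _MUTATION_SEED_OFFSET,
        )
    pop_labels: List[str] = []
    pop_names = {p.id: p.metadata["name"] for p in ts.populations()}
    for ind in ts.individuals():
        node = ts.node(ind.nodes[0])
        pop_labels.extend([pop_names[node.population]] * len(ind.nodes))
    genotypes, positions, n_dropped = _filter_biallelic(ts)
    return GenomeChunk(
        length=length,
        ts=ts,
        pop_of_haplotype=pop_labels,
        genotypes=genotypes,
        positions=positions,
        n_dropped_sites=n_dropped,
    )


def simulate_genomes(
    demography: msprime.Demography,
    samples: SampleConfig,
    plan: SimulationPlan,
    constants: SimulationConstants = SimulationConstants(),
    mutations: bool = True,
) -> Iterator[GenomeChunk]:
    """Yield independent chunks; chunk ``i`` uses seed ``base_seed + i``."""
    demography.validate()
    for i, length in enumerate(plan.chunk_lengths()):
        yield simulate_chunk(
            demography, samples, length, plan.base_seed + i + 1,
            constants=constants, mutations=mutations,
        )


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=demosmc
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def export_vcf(
    chunks: Iterable[GenomeChunk],
    samples: SampleConfig,
    path: str | Path,
    popmap_path: str | Path | None = None,
) -> Tuple[Path, Path]:
    """Write chunks to a single uncompressed VCF (one contig per chunk)
    plus a two-column sample→population map.

    Ancestral alleles are encoded as REF with an ``AA`` INFO tag, so
    genotype allele 1 is always the derived allele.
    """
    path = Path(path)
    if popmap_path is None:
        popmap_path = path.with_suffix(".popmap.txt")
    popmap_path = Path(popmap_path)

    chunks = list(chunks)
    if not chunks:
        raise ValueError("no chunks to export")

    sample_names: List[str] = []
    sample_pops: List[str] = []
    for pop, n in samples.counts.items():
        for k in range(n):
            sample_names.append(f"{pop}_{k}")
            sample_pops.append(pop)

    try:
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for ci, chunk in enumerate(chunks):
                fh.write(f"##contig=<ID=chunk{ci + 1},length={int(chunk.length)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(sample_names) + "\n")
            for ci, chunk in enumerate(chunks):
                contig = f"chunk{ci + 1}"
                g = chunk.genotypes
                for si in range(chunk.n_sites):
                    pos = int(chunk.positions[si]) + 1
                    row = g[si]
                    gts = "\t".join(
                        f"{row[2 * d]}|{row[2 * d + 1]}"
                        for d in range(len(sample_names))
                    )
                    fh.write(
                        f"{contig}\t{pos}\t.\tA\tT\t.\tPASS\tAA=A\tGT\t{gts}\n"
                    )
        with open(popmap_path, "w") as fh:
            for name, pop in zip(sample_names, sample_pops):
                fh.write(f"{name}\t{pop}\n")
    except OSError as err:  # pragma: no cover - hard to trigger portably
        raise OSError(f"failed writing VCF artefacts at {path}: {err}") from err
    return path, popmap_path
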