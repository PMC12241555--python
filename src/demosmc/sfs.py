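"""Joint, pairwise, and concatenated cross-population site frequency
spectra (cSFS).

The joint SFS is an integer array with one axis per population in the
canonical order (AFR, EUR, ASN, PNG, NEA, DEN for the full model); axis
``i`` has length ``2 n_i + 1`` for ``n_i`` diploids, the extra cell
holding the monomorphic ("no mutation") count.  The cSFS is the
row-major flattening of every pairwise 2-D marginal, pairs enumerated in
lexicographic order of (i, j) with i < j, concatenated into a single
vector: 6×121 + 8×33 + 9 = 999 entries in the canonical configuration.
The pair order and flattening are part of the public contract — trained
networks depend on the index map in :func:`csfs_index`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from demosmc.demography import SampleConfig
from demosmc.simulate import GenomeChunk

__all__ = [
    "JointSFS",
    "ExclusionReport",
    "derived_counts",
    "joint_sfs",
    "joint_sfs_from_counts",
    "marginalize",
    "csfs",
    "csfs_length",
    "csfs_index",
    "vcf_to_csfs",
]


@dataclass
class JointSFS:
    """Multidimensional derived-allele-count spectrum.

    ``array[c1, ..., ck]`` counts sites whose per-population derived
    counts are exactly ``(c1, ..., ck)``; the all-zero cell carries the
    monomorphic remainder so that the total equals ``callable_length``.
    """

    populations: Tuple[str, ...]
    haplotypes: Tuple[int, ...]
    array: np.ndarray
    callable_length: float = 0.0

    def __post_init__(self) -> None:
        expected = tuple(h + 1 for h in self.haplotypes)
        if self.array.shape != expected:
            raise ValueError(
                f"SFS shape {self.array.shape} != expected {expected}"
            )

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.array.shape

    def total(self) -> float:
        return float(self.array.sum())

    def flatten(self) -> np.ndarray:
        return self.array.ravel(order="C")


@dataclass
class ExclusionReport:
    """Per-reason counts of sites excluded while building an SFS."""

    multiallelic: int = 0
    missing_genotype: int = 0
    ancestral_unknown: int = 0
    counted: int = 0

    @property
    def excluded(self) -> int:
        return self.multiallelic + self.missing_genotype + self.ancestral_unknown


def derived_counts(
    genotypes: Sequence[Sequence[int]],
    populations: Sequence[str],
    pop_order: Sequence[str],
) -> np.ndarray:
    """Per-population derived-allele counts at one biallelic site.

    ``genotypes`` holds one (a, b) allele pair per diploid, coded
    0 = ancestral / 1 = derived; negative codes mean missing.  Raises
    ``ValueError`` on missing genotypes (callers count exclusions).
    """
    counts = {p: 0 for p in pop_order}
    for gt, pop in zip(genotypes, populations):
        for allele in gt:
            if allele < 0:
                raise ValueError("missing genotype")
            if allele > 1:
                raise ValueError("site not biallelic")
            counts[pop] += int(allele)
    return np.array([counts[p] for p in pop_order], dtype=np.int64)


def _empty_array(haplotypes: Sequence[int]) -> np.ndarray:
    return np.zeros(tuple(h + 1 for h in haplotypes), dtype=np.int64)


def joint_sfs_from_counts(
    counts: np.ndarray,
    populations: Sequence[str],
    haplotypes: Sequence[int],
    callable_length: float,
) -> JointSFS:
    """Accumulate per-site derived-count vectors (sites × pops) into a
    joint SFS, putting the monomorphic remainder in the zero cell."""
    arr = _empty_array(haplotypes)
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size:
        if counts.shape[1] != len(populations):
            raise ValueError("count matrix does not match population list")
        if np.any(counts < 0) or np.any(counts > np.asarray(haplotypes)):
            raise ValueError("derived count outside [0, 2n] for some population")
        flat = np.ravel_multi_index(tuple(counts.T), arr.shape)
        np.add.at(arr.ravel(), flat, 1)
    n_variant = int(counts.shape[0]) if counts.size else 0
    mono = callable_length - n_variant
    if mono < 0:
        raise ValueError("more variant sites than callable length")
    arr[(0,) * arr.ndim] += int(round(mono))
    return JointSFS(
        populations=tuple(populations),
        haplotypes=tuple(haplotypes),
        array=arr,
        callable_length=callable_length,
    )


def joint_sfs(
    chunks: Iterable[GenomeChunk],
    samples: SampleConfig,
    pop_order: Optional[Sequence[str]] = None,
) -> JointSFS:
    """Joint SFS over simulated chunks.

    The callable length is the summed chunk length; dropped (multi-hit)
    sites are treated as monomorphic, matching the published filters
    which discard non-biallelic positions.
    """
    if pop_order is None:
        pop_order = [p for p in samples.counts if samples.counts[p] > 0]
    haplotypes = [2 * samples.counts[p] for p in pop_order]
    arr = _empty_array(haplotypes)
    total_length = 0.0
    n_variant = 0
    for chunk in chunks:
        total_length += chunk.length
        if chunk.n_sites == 0:
            continue
        idx = chunk.haplotype_indices()
        for p in pop_order:
            if p not in idx or idx[p].size != 2 * samples.counts[p]:
                raise ValueError(
                    f"sample config mismatch for population {p!r} in chunk"
                )
        per_pop = np.stack(
            [chunk.genotypes[:, idx[p]].sum(axis=1) for p in pop_order], axis=1
        )
        flat = np.ravel_multi_index(tuple(per_pop.T), arr.shape)
        np.add.at(arr.ravel(), flat, 1)
        n_variant += chunk.n_sites
    mono = total_length - n_variant
    if mono < 0:
        raise ValueError("more variant sites than callable length")
    arr[(0,) * arr.ndim] += int(round(mono))
    return JointSFS(
        populations=tuple(pop_order),
        haplotypes=tuple(haplotypes),
        array=arr,
        callable_length=total_length,
    )


def marginalize(joint: JointSFS, pair: Tuple[str, str]) -> np.ndarray:
    """Sum the joint SFS down to the 2-D spectrum of one population pair."""
    a, b = pair
    if a == b:
        raise ValueError("pair must name two distinct populations")
    ia = joint.populations.index(a)
    ib = joint.populations.index(b)
    other = tuple(k for k in range(len(joint.populations)) if k not in (ia, ib))
    marg = joint.array.sum(axis=other)
    if ia > ib:
        marg = marg.T
    return marg


def population_pairs(populations: Sequence[str]) -> List[Tuple[str, str]]:
    """Unordered pairs in lexicographic (i, j), i < j order over the
    positions of ``populations``."""
    pops = list(populations)
    return [
        (pops[i], pops[j])
        for i in range(len(pops))
        for j in range(i + 1, len(pops))
    ]


def csfs_length(haplotypes: Sequence[int]) -> int:
    """Length of the concatenated pairwise cSFS vector."""
    sizes = [h + 1 for h in haplotypes]
    return sum(
        sizes[i] * sizes[j]
        for i in range(len(sizes))
        for j in range(i + 1, len(sizes))
    )


def csfs_index(
    haplotypes: Sequence[int], pair_index: int, ci: int, cj: int
) -> int:
    """Position in the cSFS vector of cell (ci, cj) of pair number
    ``pair_index`` (pairs in canonical order, row-major flattening)."""
    sizes = [h + 1 for h in haplotypes]
    pairs = [
        (i, j) for i in range(len(sizes)) for j in range(i + 1, len(sizes))
    ]
    offset = sum(sizes[i] * sizes[j] for i, j in pairs[:pair_index])
    i, j = pairs[pair_index]
    return offset + ci * sizes[j] + cj


def csfs(joint: JointSFS) -> np.ndarray:
    """Concatenated flattened pairwise SFS in the canonical order."""
    parts = [
        marginalize(joint, pair).ravel(order="C").astype(float)
        for pair in population_pairs(joint.populations)
    ]
    return np.concatenate(parts) if parts else np.zeros(0)


# ---------------------------------------------------------------------------
# VCF path
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path) -> Dict[str, str]:
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            mapping[sample] = pop
    return mapping


def vcf_to_csfs(
    vcf_path: str | Path,
    popmap: str | Path | Mapping[str, str],
    pop_order: Sequence[str],
    callable_length: float,
    sample_selection: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, ExclusionReport, JointSFS]:
    """Build a cSFS vector from an ancestral-annotated VCF.

    Sites are excluded (and counted) when not biallelic, when any
    selected sample has a missing genotype, or when the AA tag is absent
    or matches neither allele.  ``callable_length`` supplies the
    monomorphic remainder (genome masks are upstream of this package).
    """
    from cyvcf2 import VCF

    mapping = popmap if isinstance(popmap, Mapping) else read_popmap(popmap)
    vcf = VCF(str(vcf_path), gts012=False)
    names = list(vcf.samples)
    if sample_selection is not None:
        selection = list(sample_selection)
        unknown = [s for s in selection if s not in names]
        if unknown:
            raise ValueError(f"samples not in VCF: {unknown}")
    else:
        selection = [s for s in names if s in mapping]
    unknown = [s for s in selection if s not in mapping]
    if unknown:
        raise ValueError(f"samples missing from population map: {unknown}")
    sel_idx = np.array([names.index(s) for s in selection])
    sel_pops = [mapping[s] for s in selection]
    for p in sel_pops:
        if p not in pop_order:
            raise ValueError(f"population {p!r} not in requested order")
    pop_slot = np.array([list(pop_order).index(p) for p in sel_pops])
    n_pops = len(pop_order)
    haplotypes = [2 * sum(1 for p in sel_pops if p == q) for q in pop_order]

    report = ExclusionReport()
    rows: List[np.ndarray] = []
    saw_aa = False
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] in (".", ""):
            report.multiallelic += 1
            continue
        aa = var.INFO.get("AA")
        if aa is not None:
            saw_aa = True
        gt = np.array(var.genotypes)[sel_idx]  # (n, 3): a, b, phased
        alleles = gt[:, :2]
        if np.any(alleles < 0):
            report.missing_genotype += 1
            continue
        if aa is None:
            report.ancestral_unknown += 1
            continue
        aa = aa.upper()
        if aa == var.REF.upper():
            derived = alleles
        elif aa == var.ALT[0].upper():
            derived = 1 - alleles
        else:
            report.ancestral_unknown += 1
            continue
        per_pop = np.zeros(n_pops, dtype=np.int64)
        np.add.at(per_pop, pop_slot, derived.sum(axis=1))
        rows.append(per_pop)
        report.counted += 1
    if not saw_aa and (report.counted or report.ancestral_unknown):
        raise ValueError(f"VCF {vcf_path} carries no AA (ancestral allele) INFO tag")
    counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, n_pops), np.int64)
    joint = joint_sfs_from_counts(counts, pop_order, haplotypes, callable_length)
    return csfs(joint), report, joint
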