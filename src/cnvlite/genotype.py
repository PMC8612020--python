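"""Region genotyping, call filtering, multi-sample merging and offline
gene annotation.

Copy number of a region is ``2 * mean(region RD) / mean(autosomal RD)``
with the first and last bin weighted by their overlap fraction with the
region.  The BAF p-value is a boundary-corrected likelihood-ratio test of
allelic balance (H0: p = 0.5) against the pooled region likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .baf import BinLikelihood, _argmax_prefer_high
from .genome import BASE_BIN, GapSet, GenomeAssembly, NO_GAP_DISTANCE, distance_to_gap
from .rd import BinnedTrack, CnvCall, RdStats, _gaussian_tail_pvalue, _region_q0, region_n_fraction


@dataclass
class GenotypeResult:
    chrom: str
    start: int
    end: int
    copy_number: float
    e_value: float = float("nan")
    q0: float = float("nan")
    pN: float = float("nan")
    baf_level: float = float("nan")
    n_het: int = 0
    n_hom: int = 0
    baf_pvalue: float = float("nan")

    @property
    def region(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _region_bin_weights(start: int, end: int, bin_size: int, chrom_len: int) -> tuple[int, np.ndarray]:
    """First bin index and per-bin overlap-fraction weights for a 1-based
    inclusive region."""
    r0, r1 = start - 1, end
    b0, b1 = r0 // bin_size, (r1 - 1) // bin_size
    weights = np.ones(b1 - b0 + 1)
    for i, b in enumerate(range(b0, b1 + 1)):
        bs = b * bin_size
        be = min(bs + bin_size, chrom_len)
        ov = min(be, r1) - max(bs, r0)
        weights[i] = ov / (be - bs)
    return b0, weights


def genotype_region(
    chrom: str,
    start: int,
    end: int,
    rd: BinnedTrack,
    rd_stats: RdStats,
    assembly: GenomeAssembly,
    *,
    q0_100: BinnedTrack | None = None,
    rd_100: BinnedTrack | None = None,
    likelihood: BinLikelihood | None = None,
    gaps: GapSet | None = None,
) -> GenotypeResult:
    """Estimate copy number (and optional statistics) for a region.

    CN = 2 * overlap-weighted mean RD / autosomal mean RD.  When a
    :class:`BinLikelihood` is supplied, the ML BAF level, het/hom counts
    and BAF p-value are attached; RD statistics are returned regardless.
    """
    chrom = assembly.resolve(chrom)
    if end - start + 1 < BASE_BIN:
        raise ValueError(f"region {chrom}:{start}-{end} is smaller than one 100-bp bin")
    if end > assembly.lengths[chrom]:
        raise ValueError(f"region end {end} beyond {chrom} length {assembly.lengths[chrom]}")
    vals = rd.values[chrom]
    b0, w = _region_bin_weights(start, end, rd.bin_size, assembly.lengths[chrom])
    region = vals[b0 : b0 + len(w)].astype(np.float64)
    finite = np.isfinite(region)
    wsum = (w * finite).sum()
    mean_rd = float((region[finite] * w[finite]).sum() / wsum) if wsum > 0 else float("nan")
    cn = 2.0 * mean_rd / rd_stats.mean if rd_stats.mean > 0 else float("nan")
    genome_bins = rd_stats.n_bins_used or sum(len(v) for v in rd.values.values())
    e_value = _gaussian_tail_pvalue(
        mean_rd, max(int(round(w.sum())), 1), rd_stats.mean, rd_stats.sd, genome_bins
    )
    result = GenotypeResult(
        chrom=chrom,
        start=start,
        end=end,
        copy_number=cn,
        e_value=e_value,
        q0=_region_q0(chrom, start, end, rd_100, q0_100),
        pN=region_n_fraction(assembly, chrom, start, end),
    )
    if gaps is not None:
        pass  # dG not part of the genotype record; callers use distance_to_gap
    if likelihood is not None and chrom in likelihood.likelihood:
        lb0 = (start - 1) // likelihood.bin_size
        lb1 = (end - 1) // likelihood.bin_size
        result.n_het = int(likelihood.het_count[chrom][lb0 : lb1 + 1].sum())
        result.n_hom = int(likelihood.hom_count[chrom][lb0 : lb1 + 1].sum())
        pooled = _pooled_log_likelihood(likelihood, chrom, lb0, lb1)
        if pooled is not None:
            idx = _argmax_prefer_high(pooled)
            result.baf_level = float(likelihood.grid[idx])
            result.baf_pvalue = _lrt_pvalue(pooled, likelihood.grid, idx)
    return result


def _pooled_log_likelihood(
    likelihood: BinLikelihood, chrom: str, b0: int, b1: int
) -> np.ndarray | None:
    lk = likelihood.likelihood[chrom][b0 : b1 + 1]
    nonempty = lk.max(axis=1) > 0
    if not nonempty.any():
        return None
    with np.errstate(divide="ignore"):
        logs = np.log(lk[nonempty])
    return logs.sum(axis=0)


def _lrt_pvalue(pooled_log: np.ndarray, grid: np.ndarray, idx_hat: int) -> float:
    """Chi-square(1) LRT of p=0.5 vs the grid ML, halved at the boundary."""
    idx_null = len(grid) - 1  # grid endpoint 0.5
    if idx_hat == idx_null:
        return 1.0
    stat = 2.0 * (pooled_log[idx_hat] - pooled_log[idx_null])
    if not np.isfinite(stat) or stat <= 0:
        return 1.0
    return float(0.5 * sps.chi2.sf(stat, df=1))


def baf_pvalue_region(likelihood: BinLikelihood, chrom: str, b0: int, b1: int) -> float:
    """Standalone BAF balance p-value over bins [b0, b1] (inclusive)."""
    pooled = _pooled_log_likelihood(likelihood, chrom, b0, b1)
    if pooled is None:
        return float("nan")
    idx = _argmax_prefer_high(pooled)
    return _lrt_pvalue(pooled, likelihood.grid, idx)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_calls(
    calls: Sequence[CnvCall],
    *,
    size_range: tuple[float, float] | None = None,
    max_e_val1: float | None = None,
    max_q0: float | None = None,
    max_pN: float | None = None,
    min_dG: float | None = None,
) -> tuple[list[CnvCall], dict[str, int]]:
    """Conjunction of the five optional filters; order preserved.

    Returns surviving calls plus counts of removals by reason (a call
    failing several filters is attributed to the first in the order
    size, e_val1, q0, pN, dG).
    """
    removed = {"size": 0, "e_val1": 0, "q0": 0, "pN": 0, "dG": 0}
    kept = []
    for call in calls:
        if size_range is not None and not (size_range[0] <= call.size <= size_range[1]):
            removed["size"] += 1
            continue
        if max_e_val1 is not None and not (call.e_val1 <= max_e_val1):
            removed["e_val1"] += 1
            continue
        if max_q0 is not None and call.q0 > max_q0:
            removed["q0"] += 1
            continue
        if max_pN is not None and call.pN > max_pN:
            removed["pN"] += 1
            continue
        if min_dG is not None and call.dG < min_dG:
            removed["dG"] += 1
            continue
        kept.append(call)
    return kept, removed


# ---------------------------------------------------------------------------
# Merging across samples
# ---------------------------------------------------------------------------

@dataclass
class SampleContext:
    """Everything needed to genotype one sample's regions."""

    rd: BinnedTrack
    rd_stats: RdStats
    assembly: GenomeAssembly
    q0_100: BinnedTrack | None = None
    rd_100: BinnedTrack | None = None
    likelihood: BinLikelihood | None = None


@dataclass
class MergedCall:
    chrom: str
    start: int  # intersection, 1-based inclusive
    end: int
    source_calls: list[CnvCall]
    genotypes: dict[str, GenotypeResult] = field(default_factory=dict)
    annotation: str = ""

    @property
    def region(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / a.size, ov / b.size)


def merge_calls(
    calls_by_sample: dict[str, Sequence[CnvCall]],
    contexts: dict[str, SampleContext] | None = None,
    *,
    chrom_order: Sequence[str] | None = None,
    min_reciprocal_overlap: float = 0.5,
    filter_kwargs: dict | None = None,
) -> list[MergedCall]:
    """Group calls across samples by strict reciprocal overlap and genotype
    each sample over the intersection.

    Procedure: filter each sample's calls, sort all calls by start, then
    repeatedly take the first unprocessed call, attach calls from other
    samples whose reciprocal overlap strictly exceeds the threshold, and
    genotype every contributing sample over the intersection region.
    """
    pool: list[CnvCall] = []
    for sample, calls in calls_by_sample.items():
        if filter_kwargs:
            calls, _ = filter_calls(calls, **filter_kwargs)
        for call in calls:
            if not call.sample:
                call.sample = sample
            pool.append(call)
    order = {c: i for i, c in enumerate(chrom_order)} if chrom_order else None

    def sort_key(c: CnvCall):
        ck = order.get(c.chrom, len(order)) if order is not None else c.chrom
        return (ck, c.start, c.end, c.sample)

    pool.sort(key=sort_key)
    processed = [False] * len(pool)
    merged: list[MergedCall] = []
    for i, seed in enumerate(pool):
        if processed[i]:
            continue
        processed[i] = True
        group = [seed]
        best_by_sample: dict[str, tuple[float, int]] = {}
        for j in range(len(pool)):
            if processed[j]:
                continue
            other = pool[j]
            if other.sample == seed.sample:
                continue
            ro = _reciprocal_overlap(seed, other)
            if ro > min_reciprocal_overlap:
                prev = best_by_sample.get(other.sample)
                if prev is not None:
                    warnings.warn(
                        f"sample {other.sample}: multiple calls overlap "
                        f"{seed.region}; keeping the larger overlap"
                    )
                if prev is None or ro > prev[0]:
                    best_by_sample[other.sample] = (ro, j)
        for _, j in best_by_sample.values():
            processed[j] = True
            group.append(pool[j])
        start = max(c.start for c in group)
        end = min(c.end for c in group)
        mc = MergedCall(seed.chrom, start, end, group)
        if contexts:
            for sample, ctx in contexts.items():
                try:
                    mc.genotypes[sample] = genotype_region(
                        seed.chrom,
                        start,
                        end,
                        ctx.rd,
                        ctx.rd_stats,
                        ctx.assembly,
                        q0_100=ctx.q0_100,
                        rd_100=ctx.rd_100,
                        likelihood=ctx.likelihood,
                    )
                except (KeyError, ValueError):
                    continue
        merged.append(mc)
    return merged


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    name: str
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int


def load_gene_table(path: str) -> list[GeneRecord]:
    """BED-like TSV: chrom, start (0-based), end, name, gene_id."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"gene table line {lineno}: need 5 columns")
            genes.append(
                GeneRecord(
                    name=parts[3],
                    gene_id=parts[4],
                    chrom=parts[0],
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                )
            )
    return genes


def _gene_relation(gene: GeneRecord, start: int, end: int) -> str | None:
    if gene.end < start or gene.start > end:
        return None
    if gene.start >= start and gene.end <= end:
        return "inside"
    if gene.start < start and gene.end > end:
        return "covering"
    if gene.start < start:
        return "intersects-left-breakpoint"
    return "intersects-right-breakpoint"


def annotate_calls(
    calls: Sequence[CnvCall], genes: Sequence[GeneRecord] | None
) -> list[str]:
    """Per-call annotation strings listing overlapping genes and their
    position relative to the call."""
    if genes is None:
        warnings.warn("no gene table loaded; annotation skipped")
        return ["" for _ in calls]
    out = []
    for call in calls:
        tags = []
        for gene in genes:
            if gene.chrom != call.chrom:
                continue
            rel = _gene_relation(gene, call.start, call.end)
            if rel:
                tags.append(f"{gene.name}({gene.gene_id}):{rel}")
        out.append(",".join(tags))
    return out
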