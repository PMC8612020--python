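"""Read-depth pipeline: extract binned depth from alignments, rebin,
correct GC bias, fit global statistics, mean-shift segment and call CNVs.

The segmentation follows the classic multi-scale mean-shift recipe for
binned coverage: at each position-space bandwidth ``h`` the mean-shift
vector is computed with a Gaussian kernel in bin index and a Gaussian
kernel in signal space (bin variance taken Poisson-like as
``s**2 * level / m``), segment boundaries are placed where the vector
flips from leftward to rightward, bin values are replaced by segment
means, and the procedure is iterated to convergence before moving to the
next bandwidth.  A final significance-driven merge joins adjacent
segments whose means are statistically indistinguishable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .genome import (
    BASE_BIN,
    GapSet,
    GenomeAssembly,
    NO_GAP_DISTANCE,
    UnknownChromosomeError,
    _norm_chrom,
    distance_to_gap,
)

#: Sentinel for e-val3/e-val4 on calls too short to trim boundary bins.
EVAL_UNDEFINED = float("nan")


@dataclass
class BinnedTrack:
    """Per-chromosome numeric arrays at a fixed bin size (multiple of 100 bp)."""

    bin_size: int
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size % BASE_BIN != 0 or self.bin_size <= 0:
            raise ValueError(
                f"bin size {self.bin_size} must be a positive multiple of {BASE_BIN} bp"
            )

    def chrom(self, name: str) -> np.ndarray:
        return self.values[name]

    def total(self, chrom: str) -> float:
        return float(np.nansum(self.values[chrom]))


@dataclass
class RdStats:
    """Global RD statistics: Gaussian-fit mean/sd of the autosomal binned-RD
    histogram plus per-GC-percent mean depth."""

    mean: float
    sd: float
    gc_mean: np.ndarray  # indexed by integer GC percent 0..100; NaN = sparse
    bin_size: int
    n_bins_used: int = 0


@dataclass
class Segment:
    chrom: str
    first_bin: int
    last_bin: int  # inclusive
    mean: float

    @property
    def n_bins(self) -> int:
        return self.last_bin - self.first_bin + 1


@dataclass
class CnvCall:
    type: str  # "deletion" | "duplication"
    chrom: str
    start: int  # 1-based inclusive
    end: int
    norm_rd: float
    e_val1: float
    e_val2: float
    e_val3: float
    e_val4: float
    q0: float
    pN: float
    dG: float
    sample: str = ""

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def region(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def row(self) -> list:
        return [
            self.type,
            self.region,
            self.size,
            self.norm_rd,
            self.e_val1,
            self.e_val2,
            self.e_val3,
            self.e_val4,
            self.q0,
            self.pN,
            self.dG,
        ]


TSV_COLUMNS = [
    "type",
    "region",
    "size",
    "normRD",
    "e_val1",
    "e_val2",
    "e_val3",
    "e_val4",
    "q0",
    "pN",
    "dG",
]


# ---------------------------------------------------------------------------
# Alignment parsing
# ---------------------------------------------------------------------------

def parse_alignments(
    path: str,
    assembly: GenomeAssembly,
    *,
    reference: str | None = None,
) -> tuple[BinnedTrack, BinnedTrack, dict]:
    """Count primary mapped non-duplicate reads per 100-bp bin.

    A read contributes one count to the bin containing its leftmost aligned
    base.  A parallel track counts the subset with mapping quality 0.
    Returns ``(rd_100, q0_100, report)`` where *report* tallies processed,
    filtered and unresolvable-chromosome reads.
    """
    import pysam

    rd = {c: np.zeros(assembly.n_bins(c), dtype=np.int64) for c in assembly.chromosomes}
    q0 = {c: np.zeros(assembly.n_bins(c), dtype=np.int64) for c in assembly.chromosomes}
    report = {"used": 0, "filtered": 0, "unknown_chrom": 0}
    mode_kwargs = {"reference_filename": reference} if reference else {}
    with pysam.AlignmentFile(path, **mode_kwargs) as af:
        name_map = {
            ref: _norm_chrom(ref, assembly.chromosomes) for ref in af.references
        }
        last_pos: dict[str, int] = {}
        for read in af:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                report["filtered"] += 1
                continue
            chrom = name_map.get(read.reference_name)
            if chrom is None:
                report["unknown_chrom"] += 1
                continue
            pos = read.reference_start  # 0-based leftmost
            if pos < last_pos.get(chrom, -1):
                raise ValueError(
                    f"alignments not coordinate-sorted at {read.reference_name}:{pos + 1}"
                )
            last_pos[chrom] = pos
            b = pos // BASE_BIN
            if b >= len(rd[chrom]):
                report["filtered"] += 1
                continue
            rd[chrom][b] += 1
            if read.mapping_quality == 0:
                q0[chrom][b] += 1
            report["used"] += 1
    return BinnedTrack(BASE_BIN, rd), BinnedTrack(BASE_BIN, q0), report


# ---------------------------------------------------------------------------
# Binning and GC correction
# ---------------------------------------------------------------------------

def rebin(track: BinnedTrack, bin_size: int) -> BinnedTrack:
    """Sum constituent 100-bp bins into larger bins (conserves totals)."""
    if bin_size % track.bin_size != 0 or bin_size <= 0:
        raise ValueError(
            f"bin size {bin_size} must be a positive multiple of the stored "
            f"{track.bin_size}-bp bins"
        )
    factor = bin_size // track.bin_size
    if factor == 1:
        return BinnedTrack(bin_size, {c: v.copy() for c, v in track.values.items()})
    out = {}
    for chrom, vals in track.values.items():
        nbins = -(-len(vals) // factor)
        padded = np.pad(vals.astype(np.float64), (0, nbins * factor - len(vals)))
        out[chrom] = padded.reshape(nbins, factor).sum(axis=1)
    return BinnedTrack(bin_size, out)


def gc_per_bin(assembly: GenomeAssembly, bin_size: int) -> BinnedTrack:
    """Integer GC percent per bin, pooled from 100-bp GC/AT counts.

    GC% = round(100 * GC / (GC + AT)); bins with no called bases get -1
    (unusable).
    """
    gc100 = BinnedTrack(BASE_BIN, assembly.gc_100)
    at100 = BinnedTrack(BASE_BIN, assembly.at_100)
    gc = rebin(gc100, bin_size)
    at = rebin(at100, bin_size)
    out = {}
    for chrom in assembly.chromosomes:
        g, a = gc.values[chrom], at.values[chrom]
        denom = g + a
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.rint(100.0 * g / denom)
        pct[denom == 0] = -1
        out[chrom] = pct.astype(np.int64)
    return BinnedTrack(bin_size, out)


def _partial_tail_fraction(assembly: GenomeAssembly, chrom: str, bin_size: int) -> float:
    rem = assembly.lengths[chrom] % bin_size
    return rem / bin_size if rem else 1.0


def fit_rd_stats(
    rd: BinnedTrack,
    gc: BinnedTrack,
    assembly: GenomeAssembly,
    *,
    min_gc_class_bins: int = 2,
    min_usable_bins: int = 100,
) -> RdStats:
    """Fit the global RD level from the autosomal bin-count histogram.

    (m, s) come from a Gaussian fit to the histogram peak rather than from
    raw moments, so zero-inflated bins and CNV regions perturb the estimate
    less.  ``gc_mean[g]`` is the plain mean depth of usable autosomal bins
    whose GC class is ``g``.
    """
    vals, gcs = [], []
    for chrom in assembly.chromosomes:
        if not assembly.autosomes.get(chrom, False):
            continue
        v = rd.values[chrom].astype(np.float64)
        g = gc.values[chrom]
        usable = g >= 0
        # exclude the partial terminal bin from histogram statistics
        if assembly.lengths[chrom] % rd.bin_size:
            usable = usable.copy()
            usable[-1] = False
        vals.append(v[usable])
        gcs.append(g[usable])
    if not vals:
        raise ValueError("no usable autosomal bins")
    values = np.concatenate(vals)
    gcvals = np.concatenate(gcs)
    if len(values) < min_usable_bins:
        raise ValueError(
            f"too few usable autosomal bins ({len(values)} < {min_usable_bins})"
        )
    m, s = _fit_gaussian_peak(values)
    gc_mean = np.full(101, np.nan)
    for g in range(101):
        sel = gcvals == g
        if sel.sum() >= min_gc_class_bins:
            gc_mean[g] = values[sel].mean()
    return RdStats(mean=m, sd=s, gc_mean=gc_mean, bin_size=rd.bin_size, n_bins_used=len(values))


def _fit_gaussian_peak(values: np.ndarray) -> tuple[float, float]:
    """Gaussian fit to the histogram around its mode."""
    positive = values[values > 0]
    if positive.size == 0:
        return 0.0, 0.0
    mu0 = float(np.median(positive))
    sd0 = float(positive.std())
    if sd0 == 0:
        warnings.warn("degenerate constant RD signal; sd set to 0")
        return mu0, 0.0
    lo, hi = max(0.0, mu0 - 5 * sd0), mu0 + 5 * sd0
    nbins = 120
    hist, edges = np.histogram(positive, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, sd):
        return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    peak = centers[np.argmax(hist)]
    try:
        popt, _ = optimize.curve_fit(
            gauss,
            centers,
            hist,
            p0=[hist.max(), peak, max(sd0 / 2, (hi - lo) / nbins)],
            maxfev=5000,
        )
        mu, sd = float(popt[1]), abs(float(popt[2]))
        if not (lo <= mu <= hi) or not np.isfinite(mu):
            raise RuntimeError("fit wandered off")
    except RuntimeError:
        mu, sd = float(positive.mean()), sd0
    return mu, sd


def gc_correct(
    rd: BinnedTrack, stats_: RdStats, gc: BinnedTrack
) -> tuple[BinnedTrack, dict[str, np.ndarray]]:
    """Scale each bin by ``m / m_gc`` of its GC class.

    Bins whose GC class is unusable, sparse or has zero mean are left
    uncorrected and flagged.  Returns ``(corrected, flags)`` where flags
    mark the uncorrectable bins per chromosome.
    """
    out, flags = {}, {}
    for chrom, vals in rd.values.items():
        g = gc.values[chrom]
        corrected = vals.astype(np.float64).copy()
        bad = np.zeros(len(vals), dtype=bool)
        usable = g >= 0
        cls = np.where(usable, g, 0)
        mgc = stats_.gc_mean[cls]
        ok = usable & np.isfinite(mgc) & (mgc > 0)
        corrected[ok] = vals[ok] * stats_.mean / mgc[ok]
        bad[~ok] = True
        out[chrom] = corrected
        flags[chrom] = bad
    return BinnedTrack(rd.bin_size, out), flags


# ---------------------------------------------------------------------------
# Mean-shift segmentation
# ---------------------------------------------------------------------------

DEFAULT_BANDWIDTHS = (2, 4, 8, 16, 32, 64, 128)


def _mean_shift_pass(levels: np.ndarray, var: np.ndarray, h: int) -> np.ndarray:
    """Mean-shift vector per bin with Gaussian kernels in index and signal."""
    n = len(levels)
    shift = np.zeros(n)
    span = 3 * h
    for d in range(1, span + 1):
        w_pos = math.exp(-0.5 * (d / h) ** 2) * d
        # rightward neighbors at +d
        diff = levels[d:] - levels[:-d]
        w_sig = np.exp(-0.5 * diff**2 / (var[d:] + var[:-d]))
        shift[:-d] += w_pos * w_sig
        shift[d:] -= w_pos * w_sig
    return shift


def _segment_levels(levels: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Replace values with per-segment means; *boundaries* marks segment starts."""
    out = np.empty_like(levels)
    starts = np.nonzero(boundaries)[0]
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else len(levels)
        out[s:e] = levels[s:e].mean()
    return out


def mean_shift_segment(
    rd: BinnedTrack,
    stats_: RdStats,
    exclude: dict[str, np.ndarray] | None = None,
    *,
    bandwidths: Sequence[int] = DEFAULT_BANDWIDTHS,
    merge_alpha: float = 0.01,
    max_iter: int = 5,
) -> list[Segment]:
    """Multi-scale mean-shift partition of corrected RD into segments.

    Deterministic for fixed input.  Excluded (flagged) bins keep their
    positions but are assigned the running local level so they neither
    create nor destroy boundaries.
    """
    m, s = stats_.mean, stats_.sd
    segments: list[Segment] = []
    for chrom, raw in rd.values.items():
        n = len(raw)
        if n == 0:
            continue
        x = raw.astype(np.float64).copy()
        excl = None if exclude is None else exclude.get(chrom)
        if excl is not None and excl.any():
            good = ~excl
            if good.any():
                x[excl] = np.interp(np.nonzero(excl)[0], np.nonzero(good)[0], x[good])
            else:
                segments.append(Segment(chrom, 0, n - 1, float("nan")))
                continue
        if n == 1:
            segments.append(Segment(chrom, 0, 0, float(x[0])))
            continue
        levels = x.copy()
        prev_bounds: np.ndarray | None = None
        for h in bandwidths:
            if h >= n:
                break
            for _ in range(max_iter):
                var = _level_variance(levels, m, s)
                shift = _mean_shift_pass(levels, var, h)
                boundaries = np.zeros(n, dtype=bool)
                boundaries[0] = True
                # boundary between i-1 and i where the vector flips from
                # leftward (<0) to rightward (>=0): a density valley
                flips = (shift[:-1] < 0) & (shift[1:] >= 0)
                boundaries[1:][flips] = True
                if prev_bounds is not None:
                    # keep established significant boundaries: flanking
                    # same-level segments otherwise attract each other
                    # across a short event at large h and erase it
                    keep = _significant_boundaries(x, prev_bounds, m, s)
                    boundaries |= keep
                new_levels = _segment_levels(x, boundaries)
                prev_bounds = boundaries
                if np.allclose(new_levels, levels, rtol=1e-12, atol=1e-12):
                    break
                levels = new_levels
        segs = _levels_to_segments(chrom, levels)
        segs = _merge_insignificant(segs, x, m, s, merge_alpha)
        segments.extend(segs)
    return segments


def _significant_boundaries(
    x: np.ndarray, boundaries: np.ndarray, m: float, s: float, alpha: float = 1e-4
) -> np.ndarray:
    """Subset of *boundaries* whose adjacent segments have clearly
    different means (model-variance z-test at *alpha*)."""
    keep = np.zeros_like(boundaries)
    keep[0] = True
    starts = np.nonzero(boundaries)[0]
    for k in range(1, len(starts)):
        a0 = starts[k - 1]
        a1 = starts[k]
        b1 = starts[k + 1] if k + 1 < len(starts) else len(x)
        seg_a = Segment("", a0, a1 - 1, float(x[a0:a1].mean()))
        seg_b = Segment("", a1, b1 - 1, float(x[a1:b1].mean()))
        if _segment_pair_pvalue(seg_a, seg_b, x, m, s) < alpha:
            keep[a1] = True
    return keep


def _level_variance(levels: np.ndarray, m: float, s: float) -> np.ndarray:
    """Poisson-like signal variance per bin: s^2 scaled by level/m."""
    if s <= 0 or m <= 0:
        return np.full(len(levels), max(s, 1e-12) ** 2)
    return np.maximum(s**2 * np.maximum(levels, 0.0) / m, 1e-12)


def _levels_to_segments(chrom: str, levels: np.ndarray) -> list[Segment]:
    segs = []
    start = 0
    for i in range(1, len(levels)):
        if levels[i] != levels[i - 1]:
            segs.append(Segment(chrom, start, i - 1, float(levels[start])))
            start = i
    segs.append(Segment(chrom, start, len(levels) - 1, float(levels[start])))
    return segs


def _merge_insignificant(
    segs: list[Segment], x: np.ndarray, m: float, s: float, alpha: float
) -> list[Segment]:
    """Greedily join adjacent segments whose means are indistinguishable."""
    changed = True
    while changed and len(segs) > 1:
        changed = False
        best_p, best_i = alpha, -1
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            p = _segment_pair_pvalue(a, b, x, m, s)
            if p > best_p:
                best_p, best_i = p, i
        if best_i >= 0:
            a, b = segs[best_i], segs[best_i + 1]
            joined = x[a.first_bin : b.last_bin + 1]
            segs[best_i : best_i + 2] = [
                Segment(a.chrom, a.first_bin, b.last_bin, float(joined.mean()))
            ]
            changed = True
    return segs


def _segment_pair_pvalue(a: Segment, b: Segment, x: np.ndarray, m: float, s: float) -> float:
    va = x[a.first_bin : a.last_bin + 1]
    vb = x[b.first_bin : b.last_bin + 1]
    if s <= 0:
        return 1.0 if a.mean == b.mean else 0.0
    # z-test with model variance (robust for 1-bin segments)
    var_a = max(s**2 * max(a.mean, 0.0) / m, 1e-12) / len(va)
    var_b = max(s**2 * max(b.mean, 0.0) / m, 1e-12) / len(vb)
    z = abs(a.mean - b.mean) / math.sqrt(var_a + var_b)
    return 2.0 * stats.norm.sf(z)


# ---------------------------------------------------------------------------
# CNV calling
# ---------------------------------------------------------------------------

def call_cnvs(
    segments: list[Segment],
    rd: BinnedTrack,
    stats_: RdStats,
    q0_100: BinnedTrack | None,
    rd_100: BinnedTrack | None,
    assembly: GenomeAssembly,
    gaps: GapSet | None = None,
    *,
    del_threshold: float = 0.75,
    dup_threshold: float = 1.25,
    max_join_gap_bins: int = 1,
    sample: str = "",
) -> list[CnvCall]:
    """Turn significantly shifted segments into annotated CNV calls.

    Candidate segments with normalized RD below *del_threshold* or above
    *dup_threshold* are (per type) joined across gaps of at most
    *max_join_gap_bins* bins and scored with e-val1..4, q0, pN and dG.
    """
    m, s = stats_.mean, stats_.sd
    bin_size = rd.bin_size
    genome_bins = sum(len(v) for v in rd.values.values())
    calls: list[CnvCall] = []
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda g: g.first_bin)
        candidates = []
        for seg in segs:
            norm = seg.mean / m if m > 0 else float("nan")
            if norm < del_threshold:
                candidates.append((seg.first_bin, seg.last_bin, "deletion"))
            elif norm > dup_threshold:
                candidates.append((seg.first_bin, seg.last_bin, "duplication"))
        merged: list[list] = []
        for fb, lb, typ in candidates:
            if merged and merged[-1][2] == typ and fb - merged[-1][1] - 1 <= max_join_gap_bins:
                merged[-1][1] = lb
            else:
                merged.append([fb, lb, typ])
        x = rd.values[chrom].astype(np.float64)
        for fb, lb, typ in merged:
            vals = x[fb : lb + 1]
            start = fb * bin_size + 1
            end = min((lb + 1) * bin_size, assembly.lengths[chrom])
            norm = float(vals.mean() / m)
            e1 = _t_test_pvalue(vals, m)
            e2 = _gaussian_tail_pvalue(vals.mean(), len(vals), m, s, genome_bins)
            if len(vals) >= 3:
                inner = vals[1:-1]
                e3 = _t_test_pvalue(inner, m)
                e4 = _gaussian_tail_pvalue(inner.mean(), len(inner), m, s, genome_bins)
            else:
                e3 = e4 = EVAL_UNDEFINED
            q0_frac = _region_q0(chrom, start, end, rd_100, q0_100)
            pn = region_n_fraction(assembly, chrom, start, end)
            dg = (
                distance_to_gap(chrom, start, end, gaps)
                if gaps is not None
                else NO_GAP_DISTANCE
            )
            calls.append(
                CnvCall(
                    type=typ,
                    chrom=chrom,
                    start=start,
                    end=end,
                    norm_rd=norm,
                    e_val1=e1,
                    e_val2=e2,
                    e_val3=e3,
                    e_val4=e4,
                    q0=q0_frac,
                    pN=pn,
                    dG=dg,
                    sample=sample,
                )
            )
    calls.sort(key=lambda c: (list(assembly.chromosomes).index(c.chrom), c.start))
    return calls


def _t_test_pvalue(vals: np.ndarray, m: float) -> float:
    if len(vals) < 2 or np.allclose(vals, vals[0]):
        return 0.0 if (len(vals) and vals[0] != m) else 1.0
    res = stats.ttest_1samp(vals, m)
    return float(res.pvalue)


def _gaussian_tail_pvalue(
    region_mean: float, n: int, m: float, s: float, genome_bins: int
) -> float:
    if s <= 0:
        return 0.0 if region_mean != m else 1.0
    z = abs(region_mean - m) / (s / math.sqrt(n))
    p = 2.0 * stats.norm.sf(z)
    p *= genome_bins / max(n, 1)  # Bonferroni over region-count proxy
    return float(min(p, 1.0))


def _region_q0(
    chrom: str, start: int, end: int, rd_100: BinnedTrack | None, q0_100: BinnedTrack | None
) -> float:
    if rd_100 is None or q0_100 is None or chrom not in rd_100.values:
        return 0.0
    b0, b1 = (start - 1) // BASE_BIN, (end - 1) // BASE_BIN
    total = rd_100.values[chrom][b0 : b1 + 1].sum()
    if total <= 0:
        return 0.0
    return float(q0_100.values[chrom][b0 : b1 + 1].sum() / total)


def region_n_fraction(assembly: GenomeAssembly, chrom: str, start: int, end: int) -> float:
    """Fraction of N bases in a 1-based inclusive region, from the 100-bp
    N track with partial boundary bins weighted by overlap."""
    n100 = assembly.n_100[chrom]
    r0, r1 = start - 1, end  # 0-based half-open
    b0, b1 = r0 // BASE_BIN, (r1 - 1) // BASE_BIN
    total_n = 0.0
    for b in range(b0, b1 + 1):
        bs, be = b * BASE_BIN, min((b + 1) * BASE_BIN, assembly.lengths[chrom])
        ov = min(be, r1) - max(bs, r0)
        if ov <= 0:
            continue
        total_n += n100[b] * ov / (be - bs)
    return float(total_n / (end - start + 1))
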