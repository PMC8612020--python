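"""Allelic-imbalance pipeline: variant ingestion, strict-mask filtering,
per-site B-allele frequencies and per-bin symmetrized-beta likelihoods.

For an unphased heterozygous site with ``alt`` and ``ref`` read counts the
allele-fraction likelihood is the symmetrized beta

    L(p) ∝ p**alt * (1-p)**ref + p**ref * (1-p)**alt

which is invariant under swapping ref and alt.  Per-bin likelihoods are
pointwise products of site likelihoods over a discretized grid on
[0, 0.5] (101 points by default), accumulated in log space and
max-normalized, and the grid argmax is the maximum-likelihood BAF level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import BASE_BIN, StrictMask
from .rd import BinnedTrack

DEFAULT_GRID_POINTS = 101
_RENORM_EVERY = 50  # refresh log-offset while accumulating products

_BASES = frozenset("ACGT")


@dataclass
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    qual: float
    genotype: str  # "0/1" | "1/1"
    in_mask: bool = True
    depth: int | None = None

    @property
    def is_het(self) -> bool:
        return self.genotype == "0/1"


def _is_admissible(ref: str, alt: str) -> bool:
    """SNPs and single-letter indels only; everything else is ignored."""
    if len(ref) == 1 and len(alt) == 1:
        return True  # SNP (or 1-bp substitution)
    if len(ref) == 2 and len(alt) == 1 and ref[0] == alt[0]:
        return True  # 1-bp deletion
    if len(ref) == 1 and len(alt) == 2 and alt[0] == ref[0]:
        return True  # 1-bp insertion
    return False


def parse_variants(path: str, sample: str | int = 0) -> tuple[list[VariantSite], dict]:
    """Read SNP / 1-bp-indel sites from a VCF.

    Allele counts come from FORMAT/AD when present, otherwise they are
    reconstructed from DP and an allele-fraction field (AF/VAF/FREQ);
    sites with neither are skipped.  Multi-allelic records and longer
    indels are tallied and dropped.  Returns ``(sites, report)``.
    """
    import pysam

    sites: list[VariantSite] = []
    report = {"used": 0, "ignored_alleles": 0, "no_genotype": 0, "no_counts": 0}
    with pysam.VariantFile(path) as vf:
        sample_names = list(vf.header.samples)
        if isinstance(sample, int):
            sample_name = sample_names[sample] if sample_names else None
        else:
            sample_name = sample
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                report["ignored_alleles"] += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if not _is_admissible(ref, alt):
                report["ignored_alleles"] += 1
                continue
            if sample_name is None:
                report["no_genotype"] += 1
                continue
            fmt = rec.samples[sample_name]
            gt = fmt.get("GT")
            if gt is None or None in gt or len(gt) != 2:
                report["no_genotype"] += 1
                continue
            if sorted(gt) == [0, 1]:
                genotype = "0/1"
            elif tuple(gt) == (1, 1):
                genotype = "1/1"
            else:
                report["no_genotype"] += 1
                continue
            counts = _allele_counts(fmt)
            if counts is None:
                report["no_counts"] += 1
                continue
            ref_i, alt_i = counts
            dp = fmt.get("DP")
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    ref_count=ref_i,
                    alt_count=alt_i,
                    qual=float(rec.qual) if rec.qual is not None else float("nan"),
                    genotype=genotype,
                    depth=int(dp) if dp is not None else ref_i + alt_i,
                )
            )
            report["used"] += 1
    return sites, report


def _allele_counts(fmt) -> tuple[int, int] | None:
    ad = fmt.get("AD")
    if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
        return int(ad[0]), int(ad[1])
    dp = fmt.get("DP")
    for key in ("AF", "VAF", "FREQ"):
        af = fmt.get(key)
        if dp is not None and af is not None:
            if isinstance(af, (tuple, list)):
                af = af[0]
            alt = int(round(float(af) * int(dp)))
            return int(dp) - alt, alt
    return None


def apply_strict_mask(sites: Iterable[VariantSite], mask: StrictMask) -> list[VariantSite]:
    """Set ``in_mask`` per site; downstream likelihoods use in-mask hets only."""
    out = []
    for site in sites:
        site.in_mask = mask.contains(site.chrom, site.pos)
        out.append(site)
    return out


def baf(site: VariantSite) -> float:
    """B-allele frequency alt/(ref+alt); NaN when depth is zero."""
    total = site.ref_count + site.alt_count
    if total <= 0:
        return float("nan")
    return site.alt_count / total


def maf(site: VariantSite) -> float:
    """Minor allele frequency min(BAF, 1-BAF)."""
    b = baf(site)
    return min(b, 1.0 - b) if b == b else float("nan")


def make_grid(points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Uniform grid on [0, 0.5] including both endpoints."""
    if points < 2:
        raise ValueError("grid needs at least 2 points")
    return np.linspace(0.0, 0.5, points)


def site_log_likelihood(alt: int, ref: int, grid: np.ndarray) -> np.ndarray:
    """Log of the symmetrized-beta likelihood on *grid* (unnormalized)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(grid)
        log1mp = np.log1p(-grid)

        def power_term(e_p: int, e_q: int) -> np.ndarray:
            # e_p*log(p) + e_q*log(1-p), with x**0 == 1 even at x == 0
            t = np.zeros_like(grid)
            if e_p:
                t = t + e_p * logp
            if e_q:
                t = t + e_q * log1mp
            return t

        out = np.logaddexp(power_term(alt, ref), power_term(ref, alt))
    out[np.isnan(out)] = -np.inf
    return out


def site_likelihood(site: VariantSite, grid: np.ndarray) -> np.ndarray:
    """Max-normalized symmetrized-beta likelihood of one het site."""
    ll = site_log_likelihood(site.alt_count, site.ref_count, grid)
    return _normalize_log(ll)


def _normalize_log(ll: np.ndarray) -> np.ndarray:
    peak = np.max(ll)
    if not np.isfinite(peak):
        return np.zeros_like(ll)
    return np.exp(ll - peak)


def _argmax_prefer_high(values: np.ndarray) -> int:
    """Argmax with ties broken toward the larger index (p closer to 0.5)."""
    return len(values) - 1 - int(np.argmax(values[::-1]))


@dataclass
class BinLikelihood:
    """Per-bin discretized BAF likelihoods plus summary counts."""

    bin_size: int
    grid: np.ndarray
    likelihood: dict[str, np.ndarray]  # (n_bins, G); all-zero row = empty bin
    het_count: dict[str, np.ndarray]
    hom_count: dict[str, np.ndarray]
    mean_baf: dict[str, np.ndarray]
    mean_maf: dict[str, np.ndarray]

    def ml_baf(self, chrom: str) -> np.ndarray:
        """Grid location of per-bin maximum likelihood; NaN for empty bins."""
        lk = self.likelihood[chrom]
        out = np.full(len(lk), np.nan)
        for i, row in enumerate(lk):
            if row.max() > 0:
                out[i] = self.grid[_argmax_prefer_high(row)]
        return out

    def is_empty(self, chrom: str) -> np.ndarray:
        return self.likelihood[chrom].max(axis=1) == 0


def bin_likelihood(
    sites: Sequence[VariantSite],
    bin_size: int,
    grid: np.ndarray | None = None,
    *,
    chrom_lengths: dict[str, int] | None = None,
) -> BinLikelihood:
    """Accumulate per-bin products of in-mask het site likelihoods.

    Hom sites contribute to counts only.  Accumulation is in log space with
    periodic renormalization so long products cannot underflow; each bin's
    final curve is scaled so its maximum is 1.
    """
    if bin_size % BASE_BIN:
        raise ValueError(f"bin size must be a multiple of {BASE_BIN}")
    if grid is None:
        grid = make_grid()
    per_chrom: dict[str, dict[int, np.ndarray]] = {}
    counters: dict[str, dict[str, dict[int, float]]] = {}
    factor_counts: dict[str, dict[int, int]] = {}
    max_bin: dict[str, int] = {}
    for site in sites:
        b = (site.pos - 1) // bin_size
        max_bin[site.chrom] = max(max_bin.get(site.chrom, 0), b)
        c = counters.setdefault(
            site.chrom, {"het": {}, "hom": {}, "baf": {}, "maf": {}, "nfreq": {}}
        )
        if site.genotype == "1/1":
            c["hom"][b] = c["hom"].get(b, 0) + 1
            continue
        if not site.is_het:
            continue
        bv = baf(site)
        if bv == bv:
            c["baf"][b] = c["baf"].get(b, 0.0) + bv
            c["maf"][b] = c["maf"].get(b, 0.0) + min(bv, 1 - bv)
            c["nfreq"][b] = c["nfreq"].get(b, 0) + 1
        if not site.in_mask:
            continue
        if site.ref_count + site.alt_count <= 0:
            continue
        c["het"][b] = c["het"].get(b, 0) + 1
        ll = site_log_likelihood(site.alt_count, site.ref_count, grid)
        acc = per_chrom.setdefault(site.chrom, {})
        fc = factor_counts.setdefault(site.chrom, {})
        if b in acc:
            acc[b] = acc[b] + ll
            fc[b] += 1
            if fc[b] % _RENORM_EVERY == 0:
                peak = np.max(acc[b])
                if np.isfinite(peak):
                    acc[b] -= peak
        else:
            acc[b] = ll.copy()
            fc[b] = 1
    chroms = set(max_bin)
    if chrom_lengths:
        chroms |= set(chrom_lengths)
    G = len(grid)
    likelihood, het_n, hom_n, mbaf, mmaf = {}, {}, {}, {}, {}
    for chrom in chroms:
        if chrom_lengths and chrom in chrom_lengths:
            nbins = -(-chrom_lengths[chrom] // bin_size)
        else:
            nbins = max_bin.get(chrom, -1) + 1
        lk = np.zeros((nbins, G))
        hets = np.zeros(nbins, dtype=np.int64)
        homs = np.zeros(nbins, dtype=np.int64)
        mb = np.full(nbins, np.nan)
        mm = np.full(nbins, np.nan)
        c = counters.get(chrom, {"het": {}, "hom": {}, "baf": {}, "maf": {}, "nfreq": {}})
        for b, ll in per_chrom.get(chrom, {}).items():
            if b < nbins:
                lk[b] = _normalize_log(ll)
        for b, v in c["het"].items():
            if b < nbins:
                hets[b] = v
        for b, v in c["hom"].items():
            if b < nbins:
                homs[b] = v
        for b, n in c["nfreq"].items():
            if b < nbins and n > 0:
                mb[b] = c["baf"][b] / n
                mm[b] = c["maf"][b] / n
        likelihood[chrom] = lk
        het_n[chrom] = hets
        hom_n[chrom] = homs
        mbaf[chrom] = mb
        mmaf[chrom] = mm
    return BinLikelihood(bin_size, grid, likelihood, het_n, hom_n, mbaf, mmaf)


def rd_from_variant_depth(
    sites: Sequence[VariantSite],
    bin_size: int,
    *,
    chrom_lengths: dict[str, int] | None = None,
) -> BinnedTrack:
    """Per-bin mean variant DP as a read-depth proxy.

    Variant-free bins are NaN (missing, not zero) so rebinned means ignore
    them.  Useful at large (>= 10 kb) bins where the DP proxy tracks true
    coverage well.
    """
    sums: dict[str, dict[int, float]] = {}
    counts: dict[str, dict[int, int]] = {}
    max_bin: dict[str, int] = {}
    any_depth = False
    for site in sites:
        dp = site.depth if site.depth is not None else site.ref_count + site.alt_count
        if dp is None or dp <= 0:
            continue
        any_depth = True
        b = (site.pos - 1) // bin_size
        sums.setdefault(site.chrom, {})[b] = sums.get(site.chrom, {}).get(b, 0.0) + dp
        counts.setdefault(site.chrom, {})[b] = counts.get(site.chrom, {}).get(b, 0) + 1
        max_bin[site.chrom] = max(max_bin.get(site.chrom, 0), b)
    if not any_depth:
        raise ValueError("no variant sites carry depth information")
    out = {}
    chroms = set(max_bin) | (set(chrom_lengths) if chrom_lengths else set())
    for chrom in chroms:
        if chrom_lengths and chrom in chrom_lengths:
            nbins = -(-chrom_lengths[chrom] // bin_size)
        else:
            nbins = max_bin.get(chrom, -1) + 1
        vals = np.full(nbins, np.nan)
        for b, s in sums.get(chrom, {}).items():
            if b < nbins:
                vals[b] = s / counts[chrom][b]
        out[chrom] = vals
    return BinnedTrack(bin_size, out)
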