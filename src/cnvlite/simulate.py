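"""Synthetic fixture generation: small reference genomes, alignments and
variant files with planted deletion / duplication / CNN-LOH truth.

Reads are emitted pre-"aligned" — positions are drawn directly, no mapping
step — so the fixtures exercise the depth and allele machinery, not an
aligner.  Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genome import BASE_BIN, GenomeAssembly, StrictMask, compute_content

DEFAULT_READ_LENGTH = 150


@dataclass
class TruthEvent:
    """A planted event: copies per haplotype and optional cell fraction."""

    type: str  # "deletion" | "duplication" | "cnn_loh"
    chrom: str
    start: int  # 1-based inclusive
    end: int
    hap_copies: tuple[int, int] = (1, 1)
    cell_fraction: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.hap_copies)
        if self.type == "deletion" and total >= 2:
            raise ValueError("deletion must have total copies < 2")
        if self.type == "duplication" and total <= 2:
            raise ValueError("duplication must have total copies > 2")
        if self.type == "cnn_loh" and (total != 2 or 0 not in self.hap_copies):
            raise ValueError("cnn_loh needs total copies 2 with one haplotype at 0")

    @property
    def total_copies(self) -> int:
        return sum(self.hap_copies)

    def copy_factor(self) -> float:
        """Depth multiplier relative to diploid, mixed by cell fraction."""
        cf = self.cell_fraction
        return cf * self.total_copies / 2.0 + (1.0 - cf)


def deletion(chrom: str, start: int, end: int, cell_fraction: float = 1.0) -> TruthEvent:
    return TruthEvent("deletion", chrom, start, end, (1, 0), cell_fraction)


def duplication(chrom: str, start: int, end: int, cell_fraction: float = 1.0) -> TruthEvent:
    return TruthEvent("duplication", chrom, start, end, (2, 1), cell_fraction)


def cnn_loh(chrom: str, start: int, end: int, cell_fraction: float = 1.0) -> TruthEvent:
    return TruthEvent("cnn_loh", chrom, start, end, (2, 0), cell_fraction)


def write_truth(events: Sequence[TruthEvent], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("type\tchrom\tstart\tend\thap_a\thap_b\tcell_fraction\n")
        for ev in events:
            fh.write(
                f"{ev.type}\t{ev.chrom}\t{ev.start}\t{ev.end}\t"
                f"{ev.hap_copies[0]}\t{ev.hap_copies[1]}\t{ev.cell_fraction}\n"
            )


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def simulate_reference(
    lengths: dict[str, int],
    *,
    gc_profile: str | float = 0.5,
    gc_blocks: Sequence[tuple[float, float]] | None = None,
    gaps: dict[str, Sequence[tuple[int, int]]] | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Random sequences with a controllable GC landscape and planted N gaps.

    *gc_profile* is either a constant GC fraction, the string "sine" for a
    sinusoidal landscape between 0.3 and 0.7, or "blocks" with *gc_blocks*
    giving (fraction-of-length, gc) pieces.  *gaps* holds 0-based half-open
    N intervals per chromosome.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for chrom, length in sorted(lengths.items()):
        if length < 10_000:
            raise ValueError(f"{chrom}: simulated chromosomes must be >= 10 kb")
        pos = np.arange(length)
        if gc_profile == "sine":
            gc = 0.5 + 0.2 * np.sin(2 * np.pi * pos / 200_000.0)
        elif gc_profile == "blocks":
            blocks = gc_blocks or [(0.5, 0.3), (0.5, 0.7)]
            gc = np.empty(length)
            offset = 0
            for frac, g in blocks:
                n = int(round(frac * length))
                gc[offset : offset + n] = g
                offset += n
            gc[offset:] = blocks[-1][1]
        else:
            gc = np.full(length, float(gc_profile))
        u = rng.random(length)
        v = rng.random(length)
        # choose G/C with prob gc, split 50/50 within each class
        bases = np.where(
            u < gc,
            np.where(v < 0.5, ord("G"), ord("C")),
            np.where(v < 0.5, ord("A"), ord("T")),
        ).astype(np.uint8)
        if gaps and chrom in gaps:
            for s, e in gaps[chrom]:
                bases[s:e] = ord("N")
        out[chrom] = bases.tobytes().decode("ascii")
    return out


def write_fasta(sequences: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def _copy_factor_track(
    length: int, chrom: str, events: Sequence[TruthEvent]
) -> np.ndarray:
    nbins = -(-length // BASE_BIN)
    factor = np.ones(nbins)
    for ev in events:
        if ev.chrom != chrom:
            continue
        if ev.end > length:
            raise ValueError(f"event {ev.chrom}:{ev.start}-{ev.end} outside reference")
        b0 = (ev.start - 1) // BASE_BIN
        b1 = (ev.end - 1) // BASE_BIN
        factor[b0 : b1 + 1] = ev.copy_factor()
    return factor


def simulate_alignments(
    sequences: dict[str, str],
    path: str,
    *,
    coverage: float = 10.0,
    read_length: int = DEFAULT_READ_LENGTH,
    events: Sequence[TruthEvent] = (),
    gc_bias: Callable[[float], float] | None = None,
    q0_fraction: float = 0.0,
    seed: int = 0,
) -> None:
    """Write a coordinate-sorted SAM with Poisson-placed reads.

    Per 100-bp bin the expected read count is
    ``coverage * 100 / read_length`` scaled by the local copy factor and by
    ``gc_bias(gc_fraction)`` when given.  A *q0_fraction* of reads gets
    mapping quality 0; the rest get 60.  N-gap bins produce no reads.
    """
    import pysam

    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    assembly = compute_content(sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(sequences[c])} for c in sequences],
    }
    base_rate = coverage * BASE_BIN / read_length
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for tid, chrom in enumerate(sequences):
            seq = sequences[chrom]
            length = len(seq)
            factor = _copy_factor_track(length, chrom, events)
            gc100 = assembly.gc_100[chrom]
            at100 = assembly.at_100[chrom]
            n100 = assembly.n_100[chrom]
            rate = base_rate * factor
            if gc_bias is not None:
                denom = gc100 + at100
                with np.errstate(invalid="ignore", divide="ignore"):
                    gcf = np.where(denom > 0, gc100 / np.maximum(denom, 1), 0.5)
                rate = rate * np.array([gc_bias(g) for g in gcf])
            rate = np.where(n100 == np.minimum(length - np.arange(len(n100)) * BASE_BIN, BASE_BIN), 0.0, rate)
            counts = rng.poisson(rate)
            read_idx = 0
            for b, k in enumerate(counts):
                if k == 0:
                    continue
                bin_start = b * BASE_BIN
                limit = max(min(BASE_BIN, length - read_length - bin_start), 1)
                offsets = np.sort(rng.integers(0, limit, size=k))
                mapqs = np.where(rng.random(k) < q0_fraction, 0, 60)
                for off, mq in zip(offsets, mapqs):
                    pos = bin_start + int(off)
                    a = pysam.AlignedSegment()
                    a.query_name = f"sim_{chrom}_{read_idx}"
                    read_idx += 1
                    frag = seq[pos : pos + read_length].upper().replace("N", "A")
                    if len(frag) < read_length:
                        frag = frag + "A" * (read_length - len(frag))
                    a.query_sequence = frag
                    a.reference_id = tid
                    a.reference_start = pos
                    a.mapping_quality = int(mq)
                    a.cigarstring = f"{read_length}M"
                    a.flag = 0
                    out.write(a)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def _site_alt_fraction(ev: TruthEvent | None, rng: np.random.Generator) -> float:
    """Alt-allele read fraction for a germline-het site given the local
    event; 0 means the alt haplotype was lost (site reverts to hom-ref,
    not reported), 1 means the site is now homozygous alt."""
    if ev is None:
        return 0.5
    cf = ev.cell_fraction
    ca, cb = ev.hap_copies
    c_alt = ca if rng.random() < 0.5 else cb
    num = cf * c_alt + (1 - cf) * 1.0
    den = cf * (ca + cb) + (1 - cf) * 2.0
    return num / den


def simulate_vcf(
    lengths: dict[str, int],
    path: str,
    *,
    het_density: float = 1 / 1500.0,
    depth: int = 30,
    events: Sequence[TruthEvent] = (),
    mask: StrictMask | None = None,
    outlier_fraction: float = 0.0,
    sample: str = "SIM",
    seed: int = 0,
) -> list[dict]:
    """Write a VCF of het (and event-forced hom) SNPs with binomial counts.

    Diploid sites draw alt counts from Binomial(depth, 1/2); inside a
    one-haplotype duplication the per-site fraction is 2/3 or 1/3 by random
    haplotype assignment; deletions and CNN-LOH regions emit homozygous
    records instead of hets.  An *outlier_fraction* of extra sites is
    placed outside mask P regions with corrupted allele fractions.
    Returns the emitted site dicts (for truth checks).
    """
    if het_density <= 0:
        raise ValueError("het density must be positive")
    rng = np.random.default_rng(seed)
    ev_by_chrom: dict[str, list[TruthEvent]] = {}
    for ev in events:
        ev_by_chrom.setdefault(ev.chrom, []).append(ev)
    emitted: list[dict] = []
    for chrom in sorted(lengths):
        length = lengths[chrom]
        n_sites = rng.poisson(het_density * length)
        positions = np.sort(rng.integers(1, length + 1, size=n_sites))
        positions = np.unique(positions)
        for pos in positions:
            local = None
            for ev in ev_by_chrom.get(chrom, []):
                if ev.start <= pos <= ev.end:
                    local = ev
                    break
            if mask is not None and not mask.contains(chrom, int(pos)):
                continue  # honest sites live inside P regions
            f = _site_alt_fraction(local, rng)
            d = max(int(rng.poisson(depth)), 1)
            if f <= 0.0:
                continue  # alt haplotype lost: hom-ref, not reported
            if f >= 1.0:
                gt = "1/1"
                alt_n = d
            else:
                gt = "0/1"
                alt_n = int(rng.binomial(d, f))
            emitted.append(
                {"chrom": chrom, "pos": int(pos), "gt": gt, "ref_n": d - alt_n,
                 "alt_n": alt_n, "f": f, "event": local.type if local else None,
                 "outlier": False}
            )
        if outlier_fraction > 0 and mask is not None:
            n_out = rng.poisson(outlier_fraction * len(positions))
            placed = 0
            attempts = 0
            while placed < n_out and attempts < 50 * max(n_out, 1):
                attempts += 1
                pos = int(rng.integers(1, length + 1))
                if mask.contains(chrom, pos):
                    continue
                d = max(int(rng.poisson(depth)), 1)
                f = float(rng.uniform(0.05, 0.95))
                alt_n = int(rng.binomial(d, f))
                emitted.append(
                    {"chrom": chrom, "pos": pos, "gt": "0/1", "ref_n": d - alt_n,
                     "alt_n": alt_n, "f": f, "event": None, "outlier": True}
                )
                placed += 1
    emitted.sort(key=lambda s: (s["chrom"], s["pos"]))
    _write_vcf(emitted, lengths, path, sample)
    return emitted


def _write_vcf(sites: list[dict], lengths: dict[str, int], path: str, sample: str) -> None:
    bases = "ACGT"
    rng = np.random.default_rng(12345)  # cosmetic ref/alt base choice only
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cnvlite-simulate\n")
        for chrom in sorted(lengths):
            fh.write(f"##contig=<ID={chrom},length={lengths[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for s in sites:
            i = rng.integers(0, 4)
            ref = bases[i]
            alt = bases[(i + 1 + rng.integers(0, 3)) % 4]
            if alt == ref:
                alt = bases[(i + 1) % 4]
            dp = s["ref_n"] + s["alt_n"]
            fh.write(
                f"{s['chrom']}\t{s['pos']}\t.\t{ref}\t{alt}\t50\tPASS\t.\t"
                f"GT:AD:DP\t{s['gt']}:{s['ref_n']},{s['alt_n']}:{dp}\n"
            )


# ---------------------------------------------------------------------------
# Direct binned-RD simulation (no alignment round trip)
# ---------------------------------------------------------------------------

def simulate_binned_rd(
    n_bins: int,
    reads_per_bin: float,
    *,
    events: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
) -> np.ndarray:
    """Poisson bin counts at a diploid rate with planted copy factors.

    *events* are (first_bin, last_bin, copy_factor) with inclusive bin
    indices; copy_factor 0.5 models a one-haplotype deletion, 1.5 a
    one-haplotype duplication.
    """
    rng = np.random.default_rng(seed)
    rate = np.full(n_bins, float(reads_per_bin))
    for b0, b1, f in events:
        rate[b0 : b1 + 1] *= f
    return rng.poisson(rate).astype(np.float64)


def strict_mask_from_intervals(
    intervals: dict[str, Sequence[tuple[int, int]]]
) -> StrictMask:
    """Build a mask directly from 0-based half-open intervals."""
    return StrictMask(
        {c: np.asarray(sorted(v), dtype=np.int64).reshape(-1, 2) for c, v in intervals.items()}
    )
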