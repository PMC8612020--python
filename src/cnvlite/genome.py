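"""Reference-genome resources: per-100-bp base composition, accessibility
mask and assembly-gap geometry.

All sequence content is reduced to three per-bin integer tracks (GC, AT, N
counts in 100-bp windows) so that downstream GC correction and N-fraction
computations never need the FASTA again.  Coordinate conventions:

* BED-style interval files are 0-based half-open.
* User-facing positions/regions are 1-based inclusive.
* Bin ``b`` of size ``s`` covers 1-based ``[b*s + 1, (b+1)*s]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

BASE_BIN = 100
#: Sentinel returned by :func:`distance_to_gap` for gap-free chromosomes.
NO_GAP_DISTANCE = float("inf")

_GC_BYTES = frozenset(b"GCgc")
_AT_BYTES = frozenset(b"ATat")
_N_BYTES = frozenset(b"Nn")


class UnknownChromosomeError(KeyError):
    """Raised when a query names a chromosome absent from the resource."""


def _norm_chrom(name: str, known: Iterable[str]) -> str | None:
    """Resolve *name* against *known* allowing a 'chr' prefix mismatch."""
    known = set(known)
    if name in known:
        return name
    alt = name[3:] if name.startswith("chr") else "chr" + name
    if alt in known:
        return alt
    return None


@dataclass
class GenomeAssembly:
    """Per-chromosome lengths and 100-bp GC/AT/N composition tracks."""

    chromosomes: list[str]
    lengths: dict[str, int]
    gc_100: dict[str, np.ndarray]
    at_100: dict[str, np.ndarray]
    n_100: dict[str, np.ndarray]
    autosomes: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.autosomes:
            self.autosomes = {c: _default_autosome(c) for c in self.chromosomes}

    def n_bins(self, chrom: str, bin_size: int = BASE_BIN) -> int:
        return -(-self.lengths[chrom] // bin_size)

    def resolve(self, name: str) -> str:
        resolved = _norm_chrom(name, self.chromosomes)
        if resolved is None:
            raise UnknownChromosomeError(name)
        return resolved


def _default_autosome(chrom: str) -> bool:
    stripped = chrom[3:] if chrom.startswith("chr") else chrom
    return stripped.isdigit()


def compute_content(
    sequences: Mapping[str, str | bytes],
    autosomes: Mapping[str, bool] | None = None,
) -> GenomeAssembly:
    """Count GC/AT/N bases per 100-bp bin for every chromosome.

    Lowercase bases count the same as uppercase; IUPAC ambiguity codes other
    than N count toward none of the three tracks.  The terminal bin may be
    partial, in which case its counts sum to ``length mod 100``.
    """
    chroms: list[str] = []
    lengths: dict[str, int] = {}
    gc: dict[str, np.ndarray] = {}
    at: dict[str, np.ndarray] = {}
    nn: dict[str, np.ndarray] = {}
    for name, seq in sequences.items():
        if isinstance(seq, str):
            seq = seq.encode("ascii")
        if len(seq) == 0:
            raise ValueError(f"chromosome {name!r} has empty sequence")
        arr = np.frombuffer(seq, dtype=np.uint8)
        is_gc = np.isin(arr, np.frombuffer(b"GCgc", dtype=np.uint8))
        is_at = np.isin(arr, np.frombuffer(b"ATat", dtype=np.uint8))
        is_n = np.isin(arr, np.frombuffer(b"Nn", dtype=np.uint8))
        nbins = -(-len(seq) // BASE_BIN)
        pad = nbins * BASE_BIN - len(seq)
        def binsum(mask: np.ndarray) -> np.ndarray:
            padded = np.pad(mask.astype(np.int64), (0, pad))
            return padded.reshape(nbins, BASE_BIN).sum(axis=1)
        chroms.append(name)
        lengths[name] = len(seq)
        gc[name] = binsum(is_gc)
        at[name] = binsum(is_at)
        nn[name] = binsum(is_n)
    flags = dict(autosomes) if autosomes else {}
    return GenomeAssembly(chroms, lengths, gc, at, nn, flags)


def assembly_from_fasta(path: str, autosomes: Mapping[str, bool] | None = None) -> GenomeAssembly:
    """Build a :class:`GenomeAssembly` from an (indexed) FASTA file."""
    import pysam

    with pysam.FastaFile(path) as fa:
        seqs = {name: fa.fetch(name) for name in fa.references}
    return compute_content(seqs, autosomes)


@dataclass
class StrictMask:
    """Accessibility mask: per-chromosome sorted P ("passed") intervals,
    0-based half-open."""

    intervals: dict[str, np.ndarray]  # shape (k, 2)
    skipped_chromosomes: int = 0

    def contains(self, chrom: str, position: int) -> bool:
        """Membership of a 1-based *position* in the P set."""
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            return False
        p0 = position - 1
        idx = np.searchsorted(ivs[:, 0], p0, side="right") - 1
        return idx >= 0 and p0 < ivs[idx, 1]

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for start, end in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{start}\t{end}\n")


def _merge_intervals(pairs: list[tuple[int, int]]) -> np.ndarray:
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    pairs.sort()
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def load_strict_mask(path: str, assembly: GenomeAssembly | None = None) -> StrictMask:
    """Load P intervals from a BED file, merging overlaps.

    Lines naming chromosomes unknown to *assembly* (when given) are skipped
    and tallied; malformed lines raise with the offending line number.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {line!r}") from exc
            if start < 0 or end < start:
                raise ValueError(f"malformed BED line {lineno}: bad interval")
            if assembly is not None:
                resolved = _norm_chrom(chrom, assembly.chromosomes)
                if resolved is None:
                    skipped += 1
                    continue
                chrom = resolved
            raw.setdefault(chrom, []).append((start, end))
    if skipped:
        warnings.warn(f"strict mask: skipped {skipped} lines on unknown chromosomes")
    return StrictMask({c: _merge_intervals(v) for c, v in raw.items()}, skipped)


@dataclass
class GapSet:
    """Assembly gaps (maximal N runs) per chromosome, 0-based half-open."""

    intervals: dict[str, np.ndarray]

    def chrom_gaps(self, chrom: str) -> np.ndarray:
        return self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64))


def find_gaps(
    source: GenomeAssembly | Mapping[str, str | bytes],
) -> GapSet:
    """Locate assembly gaps.

    Given raw sequences, gaps are the maximal runs of N at base resolution.
    Given only an assembly's ``n_100`` track, gaps are resolved at 100-bp
    granularity as maximal runs of bins that are entirely N.
    """
    out: dict[str, np.ndarray] = {}
    if isinstance(source, GenomeAssembly):
        for chrom in source.chromosomes:
            n = source.n_100[chrom]
            length = source.lengths[chrom]
            bin_full = np.arange(len(n)) * BASE_BIN
            bin_len = np.minimum(length - bin_full, BASE_BIN)
            full = n == bin_len
            out[chrom] = _runs_to_intervals(full, BASE_BIN, length)
    else:
        for chrom, seq in source.items():
            if isinstance(seq, str):
                seq = seq.encode("ascii")
            arr = np.frombuffer(seq, dtype=np.uint8)
            is_n = np.isin(arr, np.frombuffer(b"Nn", dtype=np.uint8))
            out[chrom] = _runs_to_intervals(is_n, 1, len(seq))
    return GapSet(out)


def _runs_to_intervals(mask: np.ndarray, unit: int, length: int) -> np.ndarray:
    if mask.size == 0 or not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0] * unit
    ends = np.minimum(np.nonzero(diff == -1)[0] * unit, length)
    return np.column_stack([starts, ends]).astype(np.int64)


def distance_to_gap(
    chrom: str, start: int, end: int, gaps: GapSet, *, known_chromosomes: Iterable[str] | None = None
) -> float:
    """Distance in bp from a 1-based inclusive region to the nearest gap.

    Returns 0 when the region overlaps a gap, the count of bases strictly
    between region and gap otherwise, and :data:`NO_GAP_DISTANCE` when the
    chromosome carries no gaps.
    """
    if known_chromosomes is not None and chrom not in set(known_chromosomes):
        raise UnknownChromosomeError(chrom)
    ivs = gaps.chrom_gaps(chrom)
    if len(ivs) == 0:
        return NO_GAP_DISTANCE
    r0, r1 = start - 1, end  # 0-based half-open
    best = NO_GAP_DISTANCE
    for g0, g1 in ivs:
        if g0 < r1 and r0 < g1:
            return 0.0
        if g0 >= r1:
            best = min(best, float(g0 - r1))
        else:
            best = min(best, float(r0 - g1))
    return best


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive ``chrom:start-end`` region string."""
    chrom, _, span = region.partition(":")
    if not span:
        raise ValueError(f"region {region!r} must look like chr:start-end")
    start_s, _, end_s = span.replace(",", "").partition("-")
    start, end = int(start_s), int(end_s)
    if start < 1 or end < start:
        raise ValueError(f"region {region!r}: need 1 <= start <= end")
    return chrom, start, end
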