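import numpy as np
import pytest

from cnvlite.genome import BASE_BIN, GenomeAssembly


def make_assembly(lengths: dict, gc_fraction: float = 0.5, autosomes=None) -> GenomeAssembly:
    """Uniform-composition assembly without touching any sequence."""
    gc, at, nn = {}, {}, {}
    for chrom, length in lengths.items():
        nbins = -(-length // BASE_BIN)
        full = np.full(nbins, int(round(gc_fraction * BASE_BIN)), dtype=np.int64)
        rem = length - (nbins - 1) * BASE_BIN
        full[-1] = int(round(gc_fraction * rem))
        gc[chrom] = full
        atv = np.full(nbins, BASE_BIN, dtype=np.int64) - full
        atv[-1] = rem - full[-1]
        at[chrom] = atv
        nn[chrom] = np.zeros(nbins, dtype=np.int64)
    flags = autosomes or {c: True for c in lengths}
    return GenomeAssembly(list(lengths), dict(lengths), gc, at, nn, flags)


def write_sam(path, reads, lengths, read_length=100):
    """Write a minimal coordinate-sorted SAM.

    *reads* is a list of (chrom, pos_1based, mapq, flag) tuples.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, length in lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for i, (chrom, pos, mapq, flag) in enumerate(reads):
            seq = "A" * read_length
            fh.write(
                f"r{i}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{read_length}M\t*\t0\t0\t{seq}\t*\n"
            )


@pytest.fixture
def tmp_sam(tmp_path):
    def _make(reads, lengths, read_length=100):
        path = tmp_path / "reads.sam"
        write_sam(path, reads, lengths, read_length)
        return str(path)

    return _make
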