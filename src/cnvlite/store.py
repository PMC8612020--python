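"""Single-file keyed persistence for tracks and calls, plus browser/report
export.

Layout is hierarchical HDF5 with keys ``<signal>/<chrom>/<binsize>/<flags>``;
100-bp base-resolution signals are stored once and every derived (rebinned
or corrected) signal is reproducible from them, so the container stays
small.  Missing values are NaN, distinct from genuine zeros.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import h5py
import numpy as np

from .genome import BASE_BIN, GenomeAssembly
from .rd import BinnedTrack, CnvCall, TSV_COLUMNS

FLAG_RAW = "raw"
FLAG_GC_CORRECTED = "gc"


def _key(signal: str, chrom: str, bin_size: int, flags: str = FLAG_RAW) -> str:
    return f"{signal}/{chrom}/{bin_size}/{flags}"


class KeyedStore:
    """HDF5-backed key → array store with simple metadata."""

    def __init__(self, path: str, mode: str = "a"):
        self.path = path
        self._h5 = h5py.File(path, mode)

    def __enter__(self) -> "KeyedStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        self._h5.close()

    # -- raw key access -----------------------------------------------------
    def put(self, key: str, array: np.ndarray) -> None:
        if key in self._h5:
            del self._h5[key]
        self._h5.create_dataset(key, data=np.asarray(array), compression="gzip")

    def get(self, key: str) -> np.ndarray:
        if key not in self._h5:
            near = [k for k in self.keys() if k.split("/")[0] == key.split("/")[0]]
            hint = f"; nearest existing keys: {near[:5]}" if near else ""
            raise KeyError(f"no signal stored under {key!r}{hint}")
        return self._h5[key][...]

    def keys(self) -> list[str]:
        found: list[str] = []
        self._h5.visititems(
            lambda name, obj: found.append(name) if isinstance(obj, h5py.Dataset) else None
        )
        return sorted(found)

    def __contains__(self, key: str) -> bool:
        return key in self._h5

    # -- signal-level access ------------------------------------------------
    def put_signal(
        self, signal: str, chrom: str, bin_size: int, array: np.ndarray, flags: str = FLAG_RAW
    ) -> None:
        self.put(_key(signal, chrom, bin_size, flags), array)

    def get_signal(
        self, signal: str, chrom: str, bin_size: int, flags: str = FLAG_RAW
    ) -> np.ndarray:
        return self.get(_key(signal, chrom, bin_size, flags))

    def put_track(self, signal: str, track: BinnedTrack, flags: str = FLAG_RAW) -> None:
        for chrom, vals in track.values.items():
            self.put_signal(signal, chrom, track.bin_size, vals, flags)

    def get_track(
        self, signal: str, chroms: Iterable[str], bin_size: int, flags: str = FLAG_RAW
    ) -> BinnedTrack:
        return BinnedTrack(
            bin_size, {c: self.get_signal(signal, c, bin_size, flags) for c in chroms}
        )

    # -- metadata -----------------------------------------------------------
    def set_meta(self, **kwargs) -> None:
        for k, v in kwargs.items():
            self._h5.attrs[k] = v

    def get_meta(self, key: str):
        return self._h5.attrs.get(key)

    # -- assembly resources -------------------------------------------------
    def put_assembly(self, assembly: GenomeAssembly) -> None:
        self._h5.attrs["chromosomes"] = json.dumps(assembly.chromosomes)
        self._h5.attrs["lengths"] = json.dumps(assembly.lengths)
        self._h5.attrs["autosomes"] = json.dumps(assembly.autosomes)
        for chrom in assembly.chromosomes:
            self.put_signal("gc_content", chrom, BASE_BIN, assembly.gc_100[chrom])
            self.put_signal("at_content", chrom, BASE_BIN, assembly.at_100[chrom])
            self.put_signal("n_content", chrom, BASE_BIN, assembly.n_100[chrom])

    def get_assembly(self) -> GenomeAssembly:
        chroms = json.loads(self._h5.attrs["chromosomes"])
        lengths = json.loads(self._h5.attrs["lengths"])
        autosomes = json.loads(self._h5.attrs["autosomes"])
        return GenomeAssembly(
            chroms,
            lengths,
            {c: self.get_signal("gc_content", c, BASE_BIN) for c in chroms},
            {c: self.get_signal("at_content", c, BASE_BIN) for c in chroms},
            {c: self.get_signal("n_content", c, BASE_BIN) for c in chroms},
            autosomes,
        )

    # -- calls --------------------------------------------------------------
    def put_calls(self, calls: Sequence[CnvCall], bin_size: int) -> None:
        rows = [json.dumps(call.row() + [call.chrom, call.sample]) for call in calls]
        data = np.array(rows, dtype=h5py.string_dtype())
        key = f"calls/{bin_size}"
        if key in self._h5:
            del self._h5[key]
        self._h5.create_dataset(key, data=data)

    def get_calls(self, bin_size: int) -> list[CnvCall]:
        raw = self.get(f"calls/{bin_size}")
        calls = []
        for row in raw:
            fields = json.loads(row.decode() if isinstance(row, bytes) else row)
            typ, region, size, norm, e1, e2, e3, e4, q0, pn, dg, chrom, sample = fields
            _, span = region.split(":")
            start, end = (int(v) for v in span.split("-"))
            calls.append(
                CnvCall(typ, chrom, start, end, norm, e1, e2, e3, e4, q0, pn,
                        float(dg) if dg is not None else float("inf"), sample)
            )
        return calls


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

JBROWSE_BIN_SIZES = (1_000, 10_000, 100_000)


def write_bedgraph(track: BinnedTrack, lengths: dict[str, int], path: str) -> int:
    """Write a track as 0-based half-open bedGraph; NaN bins are skipped.

    Returns the number of data lines written.
    """
    n = 0
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            length = lengths.get(chrom)
            for b, v in enumerate(vals):
                if not np.isfinite(v):
                    continue
                start = b * track.bin_size
                end = start + track.bin_size
                if length is not None:
                    end = min(end, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")
                n += 1
    return n


def export_tracks_jbrowse(
    tracks: dict[str, dict[int, BinnedTrack]],
    lengths: dict[str, int],
    out_dir: str,
    *,
    sample: str = "sample",
) -> list[str]:
    """Export per-signal bedGraph files at each resolution plus a manifest.

    *tracks* maps signal name → {bin size → track}.  Returns the created
    file paths (manifest last).
    """
    if not tracks or all(not v for v in tracks.values()):
        raise ValueError("no tracks to export")
    os.makedirs(out_dir, exist_ok=True)
    created = []
    manifest = {"sample": sample, "tracks": []}
    for signal, by_size in tracks.items():
        for bin_size, track in sorted(by_size.items()):
            fname = f"{sample}_{signal}_{bin_size}.bedgraph"
            path = os.path.join(out_dir, fname)
            write_bedgraph(track, lengths, path)
            created.append(path)
            manifest["tracks"].append(
                {"signal": signal, "bin_size": bin_size, "file": fname}
            )
    manifest_path = os.path.join(out_dir, f"{sample}_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    created.append(manifest_path)
    return created


def calls_to_tsv(calls: Sequence[CnvCall], path: str) -> None:
    """Write calls as TSV in the canonical 11-column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for call in calls:
            fh.write("\t".join(_fmt(v) for v in call.row()) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        if v != v:
            return "nan"
        if v == float("inf"):
            return "inf"
        return f"{v:.6g}"
    return str(v)


def calls_to_vcf(
    calls: Sequence[CnvCall], lengths: dict[str, int], path: str, *, sample: str = "SAMPLE"
) -> None:
    """Write calls as a minimal structural-variant VCF (SVTYPE=DEL/DUP)."""
    svtype = {"deletion": "DEL", "duplication": "DUP"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cnvlite\n")
        for chrom, length in lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=NORMRD,Number=1,Type=Float,Description="Normalized read depth">\n')
        fh.write('##INFO=<ID=EVAL1,Number=1,Type=Float,Description="t-test p-value vs global mean">\n')
        fh.write('##INFO=<ID=EVAL2,Number=1,Type=Float,Description="Gaussian-tail p-value">\n')
        fh.write('##INFO=<ID=Q0,Number=1,Type=Float,Description="Fraction of zero-quality reads">\n')
        fh.write('##INFO=<ID=PN,Number=1,Type=Float,Description="Fraction of N bases">\n')
        fh.write('##INFO=<ID=DG,Number=1,Type=Float,Description="Distance to nearest gap">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for i, call in enumerate(calls, start=1):
            st = svtype[call.type]
            pos = max(call.start - 1, 1)  # by convention the base before the event
            svlen = call.end - pos
            if st == "DEL":
                svlen = -svlen
            dg = "1000000000" if call.dG == float("inf") else _fmt(call.dG)
            info = (
                f"SVTYPE={st};END={call.end};SVLEN={svlen};"
                f"NORMRD={_fmt(call.norm_rd)};EVAL1={_fmt(call.e_val1)};"
                f"EVAL2={_fmt(call.e_val2)};Q0={_fmt(call.q0)};"
                f"PN={_fmt(call.pN)};DG={dg}"
            )
            fh.write(
                f"{call.chrom}\t{pos}\tcnv{i}\tN\t<{st}>\t.\tPASS\t{info}\tGT\t./.\n"
            )
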