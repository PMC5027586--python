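"""Strict text-format I/O: bedGraph, BED6/BED12, GFF3, chrom.sizes, TSV.

Conventions: bedGraph and BED are 0-based half-open; GFF3 is 1-based closed
and converted on read/write.  Parsers reject malformed lines with the line
number; writers emit coordinate-sorted output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import StrandedCoverage

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed6",
    "write_bed6",
    "write_bed12",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_coverage",
    "write_coverage",
    "sha256_file",
    "write_manifest",
]


def _fail(path, lineno: int, msg: str):
    raise ValueError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------- chrom sizes


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                _fail(path, lineno, f"expected 2 tab-separated fields, got {len(fields)}")
            try:
                size = int(fields[1])
            except ValueError:
                _fail(path, lineno, f"non-integer size {fields[1]!r}")
            if size <= 0:
                _fail(path, lineno, "chromosome size must be positive")
            sizes[fields[0]] = size
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ------------------------------------------------------------------ bedGraph


def read_bedgraph(path, chrom_sizes: dict[str, int], bin_width: int) -> dict[str, np.ndarray]:
    """Read a 4-column bedGraph into per-chromosome bin arrays.

    Every interval must align to the bin grid; bins not covered by any
    interval are zero.
    """
    arrays = {
        chrom: np.zeros(-(-size // bin_width), dtype=np.int64)
        for chrom, size in chrom_sizes.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                _fail(path, lineno, f"expected 4 fields, got {len(fields)}")
            chrom, s, e, v = fields
            if chrom not in arrays:
                _fail(path, lineno, f"unknown chromosome {chrom!r}")
            try:
                start, end = int(s), int(e)
                value = float(v)
            except ValueError:
                _fail(path, lineno, "non-numeric coordinates or value")
            if end <= start:
                _fail(path, lineno, f"inverted interval {start}-{end}")
            if start % bin_width or end % bin_width:
                _fail(path, lineno, f"interval {start}-{end} off the {bin_width}-bp grid")
            if end > chrom_sizes[chrom] + bin_width - 1:
                _fail(path, lineno, "interval beyond chromosome end")
            ival = int(round(value))
            arrays[chrom][start // bin_width : end // bin_width] = ival
    return arrays


def write_bedgraph(arrays: dict[str, np.ndarray], bin_width: int, path) -> None:
    """Write bin arrays as bedGraph, merging equal-valued adjacent bins.

    Zero-valued runs are omitted (bedGraph convention).
    """
    with open(path, "w") as fh:
        for chrom in sorted(arrays):
            arr = arrays[chrom]
            if len(arr) == 0:
                continue
            # boundaries of constant runs
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s * bin_width}\t{e * bin_width}\t{v}\n")


# ---------------------------------------------------------------------- BED


def read_bed6(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                _fail(path, lineno, f"expected >=6 fields, got {len(fields)}")
            chrom, s, e, name, score, strand = fields[:6]
            try:
                start, end = int(s), int(e)
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            if end <= start:
                _fail(path, lineno, f"inverted interval {start}-{end}")
            if strand not in {"+", "-", "."}:
                _fail(path, lineno, f"bad strand {strand!r}")
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed6(df: pd.DataFrame, path) -> None:
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{row.score}\t{row.strand}"
            )
            extras = list(row)[6:]
            if extras:
                fh.write("\t" + "\t".join(str(x) for x in extras))
            fh.write("\n")


def write_bed12(df: pd.DataFrame, path) -> None:
    """Write gene intervals as single-block BED12 records."""
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            length = row.end - row.start
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\t{row.strand}\t"
                f"{row.start}\t{row.end}\t0\t1\t{length},\t0,\n"
            )


# --------------------------------------------------------------------- GFF3


def read_gff3_genes(path) -> pd.DataFrame:
    """Read gene features from GFF3, converting to 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                _fail(path, lineno, f"expected 9 fields, got {len(fields)}")
            chrom, _src, ftype, s, e, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(s), int(e)
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            if end1 < start1:
                _fail(path, lineno, f"inverted interval {start1}-{end1}")
            if strand not in {"+", "-"}:
                _fail(path, lineno, f"bad strand {strand!r}")
            gene_id = ""
            for part in attrs.split(";"):
                if part.startswith("ID="):
                    gene_id = part[3:]
            if not gene_id:
                _fail(path, lineno, "gene without ID attribute")
            rows.append((gene_id, chrom, start1 - 1, end1, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_gff3_genes(genes: pd.DataFrame, path) -> None:
    genes = genes.sort_values(["chrom", "start", "end"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tgroseqtk\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


# ---------------------------------------------------------- coverage bundles


def write_coverage(cov: StrandedCoverage, out_dir, stem: str) -> list[Path]:
    """Write one library as plus/minus bedGraph plus a JSON sidecar."""
    out_dir = Path(out_dir)
    plus_path = out_dir / f"{stem}_plus.bedgraph"
    minus_path = out_dir / f"{stem}_minus.bedgraph"
    meta_path = out_dir / f"{stem}.coverage.json"
    write_bedgraph({c: v[0] for c, v in cov.chroms.items()}, cov.bin_width, plus_path)
    write_bedgraph({c: v[1] for c, v in cov.chroms.items()}, cov.bin_width, minus_path)
    meta = {
        "library_id": cov.library_id,
        "bin_width": cov.bin_width,
        "stranded": cov.stranded,
        "total_tags": cov.total_tags,
        "chrom_sizes": {c: cov.chrom_length(c) for c in sorted(cov.chroms)},
    }
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return [plus_path, minus_path, meta_path]


def read_coverage(out_dir, stem: str) -> StrandedCoverage:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{stem}.coverage.json").read_text())
    sizes = {c: int(s) for c, s in meta["chrom_sizes"].items()}
    bw = int(meta["bin_width"])
    plus = read_bedgraph(out_dir / f"{stem}_plus.bedgraph", sizes, bw)
    minus = read_bedgraph(out_dir / f"{stem}_minus.bedgraph", sizes, bw)
    return StrandedCoverage(
        chroms={c: (plus[c], minus[c]) for c in sizes},
        bin_width=bw,
        library_id=meta["library_id"],
        stranded=bool(meta["stranded"]),
        total_tags=int(meta["total_tags"]),
    )


# ------------------------------------------------------------------ manifest


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(files: dict[str, str], path) -> dict:
    """Write ``{relative path: role}`` with sha256 checksums as JSON."""
    path = Path(path)
    entries = {}
    for rel, role in sorted(files.items()):
        fpath = path.parent / rel
        if not fpath.exists():
            raise IOError(f"manifest entry missing on disk: {fpath}")
        entries[rel] = {"role": role, "sha256": sha256_file(fpath)}
    manifest = {"files": entries}
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
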