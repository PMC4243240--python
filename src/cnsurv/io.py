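"""File readers and writers.

Internal coordinates are 0-based half-open everywhere; SEG files (1-based
inclusive by convention) and cytoband tables are converted at the boundary.
Matrices are plain TSV with an index column.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

SEG_COLUMNS = ["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


class SegFormatError(ValueError):
    pass


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file into internal 0-based half-open segments.

    Returns columns sample_id, chromosome, start, end, n_probes, mean.
    Malformed rows raise :class:`SegFormatError` with the line number.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 6:
            raise SegFormatError("SEG header must have 6 tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise SegFormatError(f"line {lineno}: expected 6 columns, got {len(parts)}")
            try:
                start1, end1 = int(parts[2]), int(parts[3])
                nmark, mean = int(parts[4]), float(parts[5])
            except ValueError as exc:
                raise SegFormatError(f"line {lineno}: {exc}") from None
            if start1 > end1:
                raise SegFormatError(f"line {lineno}: start > end")
            rows.append((parts[0], parts[1], start1 - 1, end1, nmark, mean))
    return pd.DataFrame(
        rows, columns=["sample_id", "chromosome", "start", "end", "n_probes", "mean"]
    )


def write_seg(segments: pd.DataFrame, path) -> None:
    """Write internal segments as SEG (converting to 1-based inclusive)."""
    out = pd.DataFrame(
        {
            "sample": segments["sample_id"],
            "chrom": segments["chromosome"],
            "loc.start": segments["start"] + 1,
            "loc.end": segments["end"],
            "num.mark": segments["n_probes"],
            "seg.mean": segments["mean"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_bed(path, names=("chromosome", "start", "end", "name")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, columns=("chromosome", "start", "end", "name")) -> None:
    df.loc[:, list(columns)].to_csv(path, sep="\t", header=False, index=False)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "arm", "pfs_days", "event", "cycles",
                "death_progression", "msi", "tumour_cell_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return df


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, params: dict, files: list[str]) -> Path:
    """Manifest JSON: parameters plus sha256 of every output file."""
    outdir = Path(outdir)
    manifest = {
        "parameters": params,
        "files": {f: sha256_file(outdir / f) for f in sorted(files)},
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
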