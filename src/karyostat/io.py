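"""Readers and writers for the package's on-disk formats.

Tables are TSV with ``#``-prefixed comment headers recording the tool
version, seed and a hash of the resolved configuration, so every output file
is traceable to the run that produced it. Segments and bins travel as BED
(0-based half-open); segment BED files get a full TSV sidecar with the
numeric columns BED cannot carry.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acgh import CNVSegment, ProbeProfile
from .genome import GenomeLayout
from .relatedness import TumorCNVSet


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(meta: dict | None) -> list[str]:
    lines = ["# karyostat output"]
    if meta:
        lines.append(f"# config_hash={config_hash(meta)}")
        for k, v in sorted(meta.items()):
            lines.append(f"# {k}={v}")
    return lines


def _write_table(path: Path, frame: pd.DataFrame, meta: dict | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def _check_chrom_naming(chroms: pd.Series) -> None:
    has_prefix = chroms.str.startswith("chr")
    if has_prefix.any() and (~has_prefix).any():
        raise ValueError("mixed chromosome naming (some with 'chr' prefix, some without)")


def write_probe_profile(path: str | Path, profile: ProbeProfile, meta: dict | None = None) -> None:
    meta = dict(meta or {})
    meta["sample_id"] = profile.sample_id
    _write_table(Path(path), profile.probes, meta)


def read_probe_profile(path: str | Path, sample_id: str | None = None) -> ProbeProfile:
    """Read a probe TSV (probe_id, chrom, start, end, log2_ratio).

    Malformed numeric fields are reported with their file line number;
    unsorted probes are auto-sorted with a warning; mixed chromosome naming
    is an error.
    """
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    n_comments = sum(1 for ln in raw_lines if ln.startswith("#"))
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"log2_ratio": str})
    required = ["probe_id", "chrom", "start", "end", "log2_ratio"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ratios = pd.to_numeric(df["log2_ratio"], errors="coerce")
    bad = ratios.isna() & df["log2_ratio"].notna()
    if bad.any() or ratios.isna().any():
        row = int(np.flatnonzero(ratios.isna())[0])
        line_no = n_comments + 2 + row  # comments + header + 1-based
        raise ValueError(f"{path}: non-numeric log2_ratio at line {line_no}")
    df["log2_ratio"] = ratios
    _check_chrom_naming(df["chrom"].astype(str))
    if sample_id is None:
        sample_id = path.stem
        for ln in raw_lines[:n_comments]:
            if ln.startswith("# sample_id="):
                sample_id = ln.split("=", 1)[1]
    chrom_order = list(dict.fromkeys(df["chrom"]))
    codes = df["chrom"].map({c: i for i, c in enumerate(chrom_order)})
    srt = np.lexsort((df["start"].to_numpy(), codes.to_numpy()))
    if not np.array_equal(srt, np.arange(len(srt))):
        warnings.warn(f"{path}: probes were not coordinate-sorted; sorting", stacklevel=2)
        df = df.iloc[srt].reset_index(drop=True)
    return ProbeProfile(sample_id, df, chrom_order)


def write_segments(path: str | Path, segments: list[CNVSegment], meta: dict | None = None) -> None:
    """Write segments as 6-column BED plus a full TSV sidecar (<path>.tsv)."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        for s in segments:
            score = int(round(1000 * abs(s.mean_ratio)))
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.sign}\t{score}\t.\n")
    sidecar = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "sign": s.sign,
                "mean_ratio": s.mean_ratio,
                "n_probes": s.n_probes,
                "gene_count": "" if s.gene_count is None else s.gene_count,
            }
            for s in segments
        ],
        columns=["chrom", "start", "end", "sign", "mean_ratio", "n_probes", "gene_count"],
    )
    _write_table(path.with_suffix(path.suffix + ".tsv"), sidecar, meta)


def read_segments(path: str | Path) -> list[CNVSegment]:
    """Read a segment BED file (prefers the TSV sidecar when present)."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".tsv")
    if sidecar.exists():
        df = pd.read_csv(sidecar, sep="\t", comment="#")
        return [
            CNVSegment(
                str(r.chrom), int(r.start), int(r.end), str(r.sign),
                float(r.mean_ratio), int(r.n_probes),
                None if pd.isna(r.gene_count) else int(r.gene_count),
            )
            for r in df.itertuples()
        ]
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
    return [
        CNVSegment(str(r.chrom), int(r.start), int(r.end), str(r.name),
                   mean_ratio=float(r.score) / 1000.0)
        for r in df.itertuples()
    ]


def write_counts(
    path: str | Path, bins_path: str | Path, counts: pd.DataFrame, layout: GenomeLayout,
    meta: dict | None = None,
) -> None:
    frame = counts.copy()
    frame.insert(0, "cell_id", counts.index)
    _write_table(Path(path), frame, meta)
    bins = layout.bins
    with open(bins_path, "w") as fh:
        for c, s, e in zip(bins["chrom"], bins["start"], bins["end"]):
            fh.write(f"{c}\t{s}\t{e}\n")


def read_counts(path: str | Path, bins_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a counts TSV and its companion bin BED; returns (counts, bins)."""
    counts = pd.read_csv(path, sep="\t", comment="#")
    if "cell_id" not in counts.columns:
        raise ValueError(f"{path}: missing cell_id column")
    counts = counts.set_index("cell_id")
    bins = pd.read_csv(bins_path, sep="\t", header=None, names=["chrom", "start", "end"])
    if len(bins) != counts.shape[1]:
        raise ValueError("bin BED does not match count matrix width")
    return counts, bins


def read_manifest(path: str | Path) -> list[TumorCNVSet]:
    """Read a cohort manifest TSV (tumor_id, mouse_id, class, path).

    Segment paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["tumor_id", "mouse_id", "class", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    cohort = []
    for _, r in df.iterrows():
        seg_path = Path(r["path"])
        if not seg_path.is_absolute():
            seg_path = path.parent / seg_path
        cohort.append(
            TumorCNVSet(str(r["tumor_id"]), str(r["mouse_id"]), str(r["class"]),
                        read_segments(seg_path))
        )
    return cohort


def write_manifest(path: str | Path, cohort: list[TumorCNVSet], seg_dir: str | Path,
                   meta: dict | None = None) -> None:
    """Write each tumor's segments as BED under seg_dir plus a manifest TSV."""
    seg_dir = Path(seg_dir)
    seg_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in cohort:
        seg_path = seg_dir / f"{t.tumor_id}.bed"
        write_segments(seg_path, t.segments, meta)
        rows.append(
            {"tumor_id": t.tumor_id, "mouse_id": t.mouse_id, "class": t.tumor_class,
             "path": str(seg_path.resolve())}
        )
    _write_table(Path(path), pd.DataFrame(rows), meta)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
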