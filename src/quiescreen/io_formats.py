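"""Readers/writers for the flat-file formats the pipeline touches.

Coordinate conventions
----------------------
Internal interval arithmetic is 0-based half-open.  SEG files and gene-model
tables are 1-based inclusive on disk (the Broad SEG dialect); conversion
happens on read and is inverted on write, so a write-then-read round trip is
lossless.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


class FormatError(ValueError):
    """Raised when a file does not conform to its declared dialect."""


@dataclass(frozen=True)
class SegFileRecord:
    """One segmented region; coordinates are 0-based half-open internally."""

    sample_id: str
    chromosome: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    num_markers: int
    seg_mean: float

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise FormatError("chromosome must be non-empty")
        if self.end < self.start:
            raise FormatError(
                f"segment end < start ({self.end} < {self.start}) for {self.sample_id}"
            )
        if self.num_markers < 1:
            raise FormatError("num_markers must be >= 1")


def read_seg(path: str | Path) -> list[SegFileRecord]:
    """Read a Broad-dialect SEG file (tab-delimited, header row).

    On-disk coordinates are 1-based inclusive and are converted to the
    internal 0-based half-open convention.
    """
    path = Path(path)
    records: list[SegFileRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty SEG file (header row required)")
    header = lines[0].split("\t")
    missing = [c for c in SEG_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing SEG column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in SEG_COLUMNS}
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        try:
            start1 = int(parts[idx["loc.start"]])
            end1 = int(parts[idx["loc.end"]])
            if end1 < start1:
                raise FormatError(f"end < start ({end1} < {start1})")
            rec = SegFileRecord(
                sample_id=parts[idx["ID"]],
                chromosome=parts[idx["chrom"]],
                start=start1 - 1,
                end=end1,
                num_markers=int(parts[idx["num.mark"]]),
                seg_mean=float(parts[idx["seg.mean"]]),
            )
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_seg(path: str | Path, records: Iterable[SegFileRecord], header_comment: str | None = None) -> None:
    """Write records as a Broad-dialect SEG file (1-based inclusive on disk).

    Floats are written with shortest round-trip representation so a
    read-write-read cycle is byte identical.
    """
    with open(path, "w") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.chromosome}\t{r.start + 1}\t{r.end}\t"
                f"{r.num_markers}\t{r.seg_mean!r}\n"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT content)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.descriptions == other.descriptions


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line (name, description, symbols...).

    Duplicate symbols within a line are deduplicated (order-preserving) with
    a warning; empty sets are dropped with a warning; a duplicate set name is
    an error.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs name and description")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in coll.sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    logger.warning("%s:%d: duplicate symbol %s in set %s", path, lineno, g, name)
                seen[g] = None
            if not seen:
                logger.warning("%s:%d: empty set %s dropped", path, lineno, name)
                continue
            coll.sets[name] = list(seen)
            coll.descriptions[name] = desc
    return coll


def write_gmt(path: str | Path, coll: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + list(genes)) + "\n")


@dataclass
class RunConfig:
    """Every threshold of the pipeline, defaulting to the published values."""

    # copy number
    min_markers: int = 8
    log2_cut: float = 0.5
    cbs_alpha: float = 0.01
    cbs_min_width: int = 2
    # somatic cascade
    somatic_score_min: float = -10.0
    somatic_rank_min: float = 0.1
    fet_score_min: float = 13.0
    # RNA-seq verification
    min_coverage: int = 10
    min_vaf: float = 0.2
    # expression
    sam_q_cut: float = 0.01
    fold_change_cut: float = 2.0
    pcc_cut: float = 0.5
    gsea_min_size: int = 50
    gsea_fdr_cut: float = 0.20
    gsea_p_cut: float = 0.05
    # methylation integration
    pair_p_cut: float = 0.05
    min_probes: int = 5
    beta_hi: float = 0.75
    beta_lo: float = 0.25
    beta_sd_cut: float = 0.25
    flank_bp: int = 10000
    # bisulfite classes
    bisulfite_lo: float = 0.20
    bisulfite_hi: float = 0.80
    # shared
    n_perm: int = 1000
    seed: int = 0
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.as_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def header(self) -> str:
        """Comment header embedded in every output file: seed + config hash."""
        return (
            f"seed={self.seed} config_sha={self.config_hash()} "
            f"coords=1-based-inclusive-on-disk"
        )


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV (first column = feature id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df


def write_matrix(path: str | Path, df: pd.DataFrame, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        df.to_csv(fh, sep="\t")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a plain TSV table with header row (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(path: str | Path, df: pd.DataFrame, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        df.to_csv(fh, sep="\t", index=False)
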