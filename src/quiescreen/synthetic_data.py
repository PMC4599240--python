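"""Synthetic cohorts with the statistical structure the screen assumes.

Everything here is a pure function of (spec, seed): the same spec and seed
produce byte-identical bundles.  Each generated dataset is accompanied by a
TruthTable recording what was implanted, enabling parameter-recovery tests
without any external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from quiescreen.cnv import MarkerTrack
from quiescreen.io_formats import GeneSetCollection, write_gmt, write_matrix, write_table
from quiescreen.methylation import MethylationMatrix
from quiescreen.expression import ExpressionMatrix

MARKER_SPACING_BP = 1000
GENE_BODY_LENGTH = 10000
GENE_SPACING = 30000  # > body + 2 * 10 kb flank: probe-gene windows never overlap


@dataclass
class CohortSpec:
    """Parameters of the simulated two-group design."""

    n_tumor: int = 13
    n_comparator: int = 76
    n_meth_tumor: int = 11
    n_genes: int = 120
    n_probes: int = 160
    driver_promoter_probes: int = 6
    driver_beta_tumor: float = 0.78
    driver_beta_comparator: float = 0.14
    beta_sd: float = 0.05
    driver_fold_change: float = 0.05
    module_size: int = 10
    module_pcc: float = 0.7
    background_beta_shape: tuple = ((0.5, 0.10, 0.05), (0.5, 0.85, 0.05))
    marker_noise_sd: float = 0.1
    expr_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_tumor", "n_comparator", "n_meth_tumor", "n_genes", "n_probes", "driver_promoter_probes", "module_size"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        for f in ("driver_beta_tumor", "driver_beta_comparator"):
            if not 0.0 < getattr(self, f) < 1.0:
                raise ValueError(f"{f} must be in (0, 1)")
        if self.driver_fold_change <= 0:
            raise ValueError("driver_fold_change must be > 0")
        if not -1.0 < self.module_pcc < 1.0:
            raise ValueError("module_pcc must be in (-1, 1)")
        if self.n_meth_tumor > self.n_tumor:
            raise ValueError("n_meth_tumor cannot exceed n_tumor")
        if self.n_probes < self.driver_promoter_probes + 10:
            raise ValueError("n_probes must be >= driver_promoter_probes + 10")
        if self.n_genes < 1 + self.module_size:
            raise ValueError("n_genes must cover driver + module")

    @property
    def tumor_samples(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_tumor)]

    @property
    def comparator_samples(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_comparator)]

    @property
    def meth_tumor_samples(self) -> list[str]:
        return self.tumor_samples[: self.n_meth_tumor]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def probe_ids(self) -> list[str]:
        return [f"cg{i + 1:06d}" for i in range(self.n_probes)]


@dataclass
class TruthTable:
    """Ground truth emitted alongside every simulated dataset."""

    driver_gene: str | None = None
    module_genes: list[str] = field(default_factory=list)
    implants: list[dict] = field(default_factory=list)
    variant_pass: dict[str, bool] = field(default_factory=dict)
    variant_expressed: dict[str, bool] = field(default_factory=dict)
    calibrator_sample: str | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class Implant:
    """A copy-number aberration injected into selected samples."""

    chrom: str
    start_marker: int
    n_markers: int
    mean_log2: float
    samples: tuple[int, ...]  # sample indices carrying the implant


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def gen_marker_track(
    spec: CohortSpec,
    implants: list[Implant] | None = None,
    chrom_markers: dict[str, int] | None = None,
    n_samples: int | None = None,
) -> tuple[list[MarkerTrack], TruthTable]:
    """Marker-level log2 tracks: Normal(0, marker_noise_sd) background with
    implanted windows shifted by their stated mean in the carrier samples.

    Markers sit on an even grid (1 kb spacing) per chromosome.  An implant
    extending past the chromosome's marker count is an error.
    """
    implants = implants or []
    chrom_markers = chrom_markers or {"chr1": 500, "chr2": 300}
    n_samples = n_samples if n_samples is not None else spec.n_tumor
    rng = np.random.default_rng(spec.seed)
    truth = TruthTable()
    for imp in implants:
        if imp.n_markers < 1:
            raise ValueError("implant n_markers must be >= 1")
        if imp.chrom not in chrom_markers:
            raise ValueError(f"implant chromosome {imp.chrom!r} not in track")
        if imp.start_marker + imp.n_markers > chrom_markers[imp.chrom]:
            raise ValueError(f"implant exceeds {imp.chrom} length ({chrom_markers[imp.chrom]} markers)")
    tracks = []
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    for si, sid in enumerate(sample_ids):
        track = MarkerTrack(sample_id=sid)
        for chrom, n in chrom_markers.items():
            positions = np.arange(n, dtype=np.int64) * MARKER_SPACING_BP
            log2 = rng.normal(0.0, spec.marker_noise_sd, size=n)
            for imp in implants:
                if imp.chrom == chrom and si in imp.samples:
                    sl = slice(imp.start_marker, imp.start_marker + imp.n_markers)
                    log2[sl] += imp.mean_log2
            track.add_chromosome(chrom, positions, log2)
        tracks.append(track)
    for imp in implants:
        for si in imp.samples:
            truth.implants.append(
                {
                    "sample": sample_ids[si],
                    "chrom": imp.chrom,
                    "start_marker": imp.start_marker,
                    "n_markers": imp.n_markers,
                    "mean_log2": imp.mean_log2,
                    "start_bp": imp.start_marker * MARKER_SPACING_BP,
                    "end_bp": (imp.start_marker + imp.n_markers - 1) * MARKER_SPACING_BP + 1,
                }
            )
    return tracks, truth


def gen_meth_expr(spec: CohortSpec, rng: np.random.Generator | None = None) -> tuple[dict, TruthTable]:
    """Paired expression + methylation cohort with one implanted driver.

    Expression: genes x (n_tumor + n_comparator) log2 matrix.  The driver's
    tumor mean sits log2(driver_fold_change) below its comparator mean; a
    module of ``module_size`` genes is tied to the driver through a shared
    latent factor calibrated so the expected within-group Pearson r equals
    ``module_pcc``.  Methylation: probes x (n_meth_tumor + n_comparator)
    beta matrix; the driver's promoter probes are drawn truncated-normal
    around the group beta means, background probes from a bimodal beta
    mixture independent of expression.  The probe annotation places the
    driver promoter probes within 1,500 bp of the driver's transcription
    start.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    driver = genes[0]
    module = genes[1 : 1 + spec.module_size]
    samples = spec.tumor_samples + spec.comparator_samples
    n_s = len(samples)
    is_tumor = np.array([s.startswith("T") for s in samples])

    # --- expression ---
    expr = np.empty((spec.n_genes, n_s))
    baselines = rng.uniform(4.0, 10.0, size=spec.n_genes)
    for gi in range(spec.n_genes):
        expr[gi] = baselines[gi] + rng.normal(0.0, spec.expr_noise_sd, size=n_s)
    # driver: tumor shifted by log2 fold change
    d_base = baselines[0]
    expr[0] = d_base + rng.normal(0.0, spec.expr_noise_sd, size=n_s)
    expr[0, is_tumor] += math.log2(spec.driver_fold_change)
    # module: share the driver's within-group z-score through a latent factor
    z = np.empty(n_s)
    for mask in (is_tumor, ~is_tumor):
        v = expr[0, mask]
        z[mask] = (v - v.mean()) / v.std(ddof=0)
    rho = spec.module_pcc
    for k, gene in enumerate(module):
        gi = 1 + k
        noise = rng.normal(0.0, 1.0, size=n_s)
        expr[gi] = baselines[gi] + spec.expr_noise_sd * (rho * z + math.sqrt(1.0 - rho**2) * noise)

    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    expr_labels = pd.Series(np.where(is_tumor, "tumor", "comparator"), index=samples)

    # --- methylation ---
    meth_samples = spec.meth_tumor_samples + spec.comparator_samples
    meth_is_tumor = np.array([s.startswith("T") for s in meth_samples])
    n_ms = len(meth_samples)
    meth = np.empty((spec.n_probes, n_ms))
    ndp = spec.driver_promoter_probes
    for pi in range(ndp):
        meth[pi, meth_is_tumor] = _truncnorm(rng, spec.driver_beta_tumor, spec.beta_sd, int(meth_is_tumor.sum()))
        meth[pi, ~meth_is_tumor] = _truncnorm(rng, spec.driver_beta_comparator, spec.beta_sd, int((~meth_is_tumor).sum()))
    weights = np.array([w for w, _, _ in spec.background_beta_shape])
    weights = weights / weights.sum()
    comps = rng.choice(len(weights), size=(spec.n_probes - ndp, n_ms), p=weights)
    for ci, (_, mu, sd) in enumerate(spec.background_beta_shape):
        mask = comps == ci
        meth[ndp:][mask] = _truncnorm(rng, mu, sd, int(mask.sum()))
    meth_df = pd.DataFrame(meth, index=spec.probe_ids, columns=meth_samples)
    meth_labels = pd.Series(np.where(meth_is_tumor, "tumor", "comparator"), index=meth_samples)

    # --- gene models and probe annotation (non-overlapping +/-10 kb windows) ---
    starts = 30000 + np.arange(spec.n_genes) * GENE_SPACING
    gene_models = pd.DataFrame(
        {
            "symbol": genes,
            "chromosome": "chr1",
            "strand": "+",
            "start": starts,
            "end": starts + GENE_BODY_LENGTH - 1,
        }
    )
    probe_rows = []
    # driver promoter probes: within 1,500 bp of the driver TSS (gene start)
    tss = int(starts[0])
    for pi in range(ndp):
        probe_rows.append((spec.probe_ids[pi], "chr1", tss + 100 + pi * 200, "island"))
    # background probes round-robin inside gene bodies
    relations = ["shore", "shelf", "open_sea", "island"]
    for k in range(ndp, spec.n_probes):
        gi = k % spec.n_genes
        offset = 500 + ((k * 937) % (GENE_BODY_LENGTH - 1000))  # deterministic scatter
        probe_rows.append((spec.probe_ids[k], "chr1", int(starts[gi]) + offset, relations[k % 4]))
    annot = pd.DataFrame(probe_rows, columns=["probe", "chromosome", "position", "island_relation"])

    truth = TruthTable(driver_gene=driver, module_genes=list(module))
    cohort = {
        "expression": ExpressionMatrix(expr_df, expr_labels),
        "methylation": MethylationMatrix(meth_df, meth_labels),
        "probe_annotation": annot,
        "gene_models": gene_models,
    }
    return cohort, truth


def gen_variant_table(
    spec: CohortSpec,
    n_variants: int,
    n_true_pass: int,
    n_expressed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """Variant table with pass/fail truth by construction.

    Exactly ``n_true_pass`` records satisfy somatic_score >= -10,
    somatic_rank >= 0.1 and fet_score >= 13; the rest fail a uniformly
    chosen non-empty subset of the three thresholds.  ``n_expressed`` of the
    passing records (default min(5, n_true_pass)) are given RNA support
    meeting coverage >= 10 and VAF >= 0.2; all other records fail RNA
    verification.
    """
    if n_true_pass > n_variants:
        raise ValueError("n_true_pass cannot exceed n_variants")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if n_expressed is None:
        n_expressed = min(5, n_true_pass)
    if n_expressed > n_true_pass:
        raise ValueError("n_expressed cannot exceed n_true_pass")
    truth = TruthTable()
    rows = []
    expressed_ids = set(rng.choice(n_true_pass, size=n_expressed, replace=False).tolist()) if n_true_pass else set()
    for i in range(n_variants):
        vid = f"v{i + 1:05d}"
        should_pass = i < n_true_pass
        if should_pass:
            score = rng.uniform(-10.0, 60.0)
            rank = rng.uniform(0.1, 1.0)
            fet = rng.uniform(13.0, 120.0)
        else:
            fail_bits = int(rng.integers(1, 8))  # non-empty subset of 3 thresholds
            score = rng.uniform(-120.0, -10.0 - 1e-9) if fail_bits & 1 else rng.uniform(-10.0, 60.0)
            rank = rng.uniform(0.0, 0.1 - 1e-12) if fail_bits & 2 else rng.uniform(0.1, 1.0)
            fet = rng.uniform(0.0, 13.0 - 1e-9) if fail_bits & 4 else rng.uniform(13.0, 120.0)
        expressed = should_pass and i in expressed_ids
        if expressed:
            total = int(rng.integers(10, 200))
            variant_reads = int(np.ceil(0.2 * total)) + int(rng.integers(0, max(1, total - int(np.ceil(0.2 * total)))))
            variant_reads = min(variant_reads, total)
        else:
            if rng.random() < 0.5:
                total = int(rng.integers(0, 10))  # coverage failure
                variant_reads = int(rng.integers(0, total + 1))
            else:
                total = int(rng.integers(10, 200))
                variant_reads = int(rng.integers(0, int(np.floor(0.2 * total - 1e-9)) + 1))
                if variant_reads / total >= 0.2:
                    variant_reads = max(0, int(0.2 * total) - 1)
        rows.append(
            {
                "sample_id": f"T{int(rng.integers(1, spec.n_tumor + 1)):02d}",
                "chromosome": f"chr{int(rng.integers(1, 23))}",
                "position": int(rng.integers(1, 10_000_000)),
                "ref": "ACGT"[int(rng.integers(0, 4))],
                "alt": "TGCA"[int(rng.integers(0, 4))],
                "gene": f"G{int(rng.integers(1, spec.n_genes + 1)):04d}",
                "somatic_score": float(score),
                "somatic_rank": float(rank),
                "fet_score": float(fet),
                "in_dbsnp": bool(rng.random() < 0.3),
                "variant_in_cosmic": bool(rng.random() < 0.1),
                "gene_in_cosmic": bool(rng.random() < 0.5),
                "damaging_predicted": bool(rng.random() < 0.4),
                "rna_total_reads": total,
                "rna_variant_reads": variant_reads,
            }
        )
        truth.variant_pass[vid] = should_pass
        truth.variant_expressed[vid] = expressed
    df = pd.DataFrame(rows)
    df.insert(0, "variant_id", [f"v{i + 1:05d}" for i in range(n_variants)])
    return df, truth


def gen_qpcr_wells(spec: CohortSpec, rng: np.random.Generator, target: str = "LNC1") -> tuple[pd.DataFrame, str]:
    """Ct table: low target expression (high Ct, sometimes undetermined) in
    tumors, clear expression in comparators; housekeeping around 20 cycles.
    Returns the wells table and the calibrator sample (the detectable tumor
    sample with the highest dCt, i.e. the lowest expression)."""
    rows = []
    samples = spec.tumor_samples + spec.comparator_samples[:8]
    dct: dict[str, float] = {}
    for s in samples:
        hk = rng.normal(20.0, 0.3)
        tumor = s.startswith("T")
        undetermined = tumor and rng.random() < 0.3
        for rep in (1, 2):
            rows.append({"sample": s, "target": "GAPDH", "ct": round(float(hk + rng.normal(0, 0.05)), 3), "replicate": rep})
        if undetermined:
            for rep in (1, 2):
                rows.append({"sample": s, "target": target, "ct": np.nan, "replicate": rep})
        else:
            tgt = rng.normal(33.0, 0.5) if tumor else rng.normal(25.0, 0.8)
            for rep in (1, 2):
                rows.append({"sample": s, "target": target, "ct": round(float(tgt + rng.normal(0, 0.05)), 3), "replicate": rep})
            dct[s] = tgt - hk
    calibrator = max(dct, key=dct.get)
    return pd.DataFrame(rows), calibrator


def gen_bisulfite_sites(spec: CohortSpec, rng: np.random.Generator, n_sites: int = 4) -> pd.DataFrame:
    """Trace peak heights for promoter CpG sites of a hypermethylated gene."""
    rows = []
    for i in range(n_sites):
        ratio = float(np.clip(rng.normal(spec.driver_beta_tumor, 0.05), 0.01, 0.99))
        total = float(rng.uniform(80, 160))
        rows.append({"site": f"site{i + 1}", "c_peak": round(ratio * total, 2), "t_peak": round((1 - ratio) * total, 2)})
    return pd.DataFrame(rows)


DEFAULT_IMPLANT = Implant(chrom="chr1", start_marker=120, n_markers=12, mean_log2=0.8, samples=(0,))


def gen_cohort(spec: CohortSpec, out_dir: str | Path, implants: list[Implant] | None = None) -> TruthTable:
    """Write a complete fixture bundle (plain-text dialects) plus truth JSON.

    Same (spec, seed) twice -> byte-identical bundles.  A failed write
    removes every file of the incomplete bundle before re-raising.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"seed={spec.seed} generator=synthetic_data"
    written: list[Path] = []

    def _path(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    try:
        ss = np.random.SeedSequence(spec.seed)
        rngs = [np.random.default_rng(s) for s in ss.spawn(5)]

        tracks, cn_truth = gen_marker_track(spec, implants=implants if implants is not None else [DEFAULT_IMPLANT])
        marker_rows = []
        for t in tracks:
            for chrom, (pos, log2) in t.chroms.items():
                for p, v in zip(pos, log2):
                    marker_rows.append((t.sample_id, chrom, int(p) + 1, float(v)))
        markers = pd.DataFrame(marker_rows, columns=["sample", "chrom", "pos", "log2"])
        write_table(_path("markers.tsv"), markers, header_comment=header + " coords=1-based")

        variants, var_truth = gen_variant_table(spec, n_variants=200, n_true_pass=41, rng=rngs[1])
        write_table(_path("variants.tsv"), variants, header_comment=header)

        cohort, omics_truth = gen_meth_expr(spec, rng=rngs[2])
        write_matrix(_path("expression.tsv"), cohort["expression"].values, header_comment=header)
        write_table(
            _path("expression_labels.tsv"),
            cohort["expression"].labels.rename("group").rename_axis("sample").reset_index(),
            header_comment=header,
        )
        write_matrix(_path("methylation.tsv"), cohort["methylation"].values, header_comment=header)
        write_table(
            _path("methylation_labels.tsv"),
            cohort["methylation"].labels.rename("group").rename_axis("sample").reset_index(),
            header_comment=header,
        )
        write_table(_path("probe_annotation.tsv"), cohort["probe_annotation"], header_comment=header + " coords=1-based")
        write_table(_path("gene_models.tsv"), cohort["gene_models"], header_comment=header + " coords=1-based-inclusive")

        gmt = GeneSetCollection(
            sets={"DRIVER_MODULE": [omics_truth.driver_gene] + omics_truth.module_genes},
            descriptions={"DRIVER_MODULE": "co-regulated module of the implanted driver"},
        )
        write_gmt(_path("sets.gmt"), gmt)

        wells, calibrator = gen_qpcr_wells(spec, rngs[3])
        write_table(_path("qpcr_wells.tsv"), wells, header_comment=header)
        write_table(_path("bisulfite_sites.tsv"), gen_bisulfite_sites(spec, rngs[4]), header_comment=header)

        truth = TruthTable(
            driver_gene=omics_truth.driver_gene,
            module_genes=omics_truth.module_genes,
            implants=cn_truth.implants,
            variant_pass=var_truth.variant_pass,
            variant_expressed=var_truth.variant_expressed,
            calibrator_sample=calibrator,
        )
        truth.to_json(_path("truth.json"))
    except BaseException:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return truth
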