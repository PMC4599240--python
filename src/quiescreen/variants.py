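"""Variant triage: somatic filter cascade, RNA-seq expression verification,
germline candidate filtering, binomial recurrence testing and fusion-caller
consensus.

The somatic/confidence fields (somatic_score, somatic_rank, fet_score) come
from the upstream caller and are treated as opaque numeric filter statistics;
no attempt is made to recompute them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "sample_id", "chromosome", "position", "ref", "alt", "gene",
    "somatic_score", "somatic_rank", "fet_score",
    "in_dbsnp", "variant_in_cosmic", "gene_in_cosmic", "damaging_predicted",
    "rna_total_reads", "rna_variant_reads",
]


@dataclass(frozen=True)
class VariantRecord:
    sample_id: str
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    gene: str
    somatic_score: float
    somatic_rank: float
    fet_score: float
    in_dbsnp: bool = False
    variant_in_cosmic: bool = False
    gene_in_cosmic: bool = False
    damaging_predicted: bool = False
    rna_total_reads: int = 0
    rna_variant_reads: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.somatic_rank <= 1.0:
            raise ValueError(f"somatic_rank {self.somatic_rank} outside [0, 1]")
        if self.rna_variant_reads > self.rna_total_reads:
            raise ValueError("rna_variant_reads exceeds rna_total_reads")

    @property
    def vaf(self) -> float | None:
        """Variant allele fraction; None when no RNA coverage."""
        if self.rna_total_reads <= 0:
            return None
        return self.rna_variant_reads / self.rna_total_reads


@dataclass(frozen=True)
class GeneMutationCount:
    gene: str
    bases_sequenced: int
    observed_mutations: int

    def __post_init__(self) -> None:
        if self.bases_sequenced < 0 or self.observed_mutations < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class FusionCandidate:
    caller: str
    gene_5prime: str
    gene_3prime: str
    chrom_5prime: str = ""
    pos_5prime: int = 0
    chrom_3prime: str = ""
    pos_3prime: int = 0
    supporting_reads: int = 0
    evidence: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.gene_5prime or not self.gene_3prime:
            raise ValueError("fusion partner genes must be non-empty")

    @property
    def pair(self) -> frozenset[str]:
        """Unordered gene pair (5'/3' orientation ignored)."""
        return frozenset((self.gene_5prime, self.gene_3prime))


def somatic_filter_cascade(
    variants: list[VariantRecord],
    somatic_score_min: float = -10.0,
    somatic_rank_min: float = 0.1,
    fet_score_min: float = 13.0,
) -> list[VariantRecord]:
    """Retain variants with somatic_score >= -10 AND somatic_rank >= 0.1 AND
    fet_score >= 13 (all thresholds inclusive).  Per-stage drop counts are
    logged.  Survivor set is invariant to record order."""
    for v in variants:
        for f in ("somatic_score", "somatic_rank", "fet_score"):
            val = getattr(v, f)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                raise ValueError(f"variant {v.sample_id}:{v.chromosome}:{v.position} missing field(s): {f}")
    stage1 = [v for v in variants if v.somatic_score >= somatic_score_min]
    stage2 = [v for v in stage1 if v.somatic_rank >= somatic_rank_min]
    stage3 = [v for v in stage2 if v.fet_score >= fet_score_min]
    logger.info(
        "somatic cascade: %d input, dropped %d (score), %d (rank), %d (fet score); %d retained",
        len(variants), len(variants) - len(stage1), len(stage1) - len(stage2),
        len(stage2) - len(stage3), len(stage3),
    )
    return stage3


def rnaseq_verify(
    variants: list[VariantRecord],
    min_cov: int = 10,
    min_vaf: float = 0.2,
) -> list[VariantRecord]:
    """Variants with RNA-seq expression support: total coverage >= min_cov
    and VAF >= min_vaf (both inclusive).  Zero total coverage means not
    expressed (no VAF is computed)."""
    expressed = []
    for v in variants:
        if v.rna_total_reads < min_cov:
            continue
        vaf = v.vaf
        if vaf is not None and vaf >= min_vaf:
            expressed.append(v)
    return expressed


def germline_candidate_filter(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Germline triage: keep variants in COSMIC-listed genes, predicted
    damaging, and absent from dbSNP unless the specific variant is itself in
    COSMIC (the rescue clause)."""
    return [
        v for v in variants
        if v.gene_in_cosmic and v.damaging_predicted and (not v.in_dbsnp or v.variant_in_cosmic)
    ]


def binomial_recurrence_test(
    counts: list[GeneMutationCount],
    background_rate: float,
    alpha: float = 0.05,
) -> dict[str, dict[str, float]]:
    """Exact upper-tail binomial test per gene.

    p = P(X >= k) with X ~ Binomial(bases_sequenced, background_rate),
    computed exactly (no normal approximation).  Returns per-gene raw p and a
    Bonferroni-adjusted p (against ``alpha`` over the tested genes).
    """
    if not 0.0 < background_rate < 1.0:
        raise ValueError("background_rate must be in (0, 1)")
    m = len(counts)
    out: dict[str, dict[str, float]] = {}
    for c in counts:
        if c.bases_sequenced <= 0:
            raise ValueError(f"gene {c.gene}: bases_sequenced must be > 0")
        if c.observed_mutations == 0:
            p = 1.0
        else:
            # sf(k-1) = P(X >= k); scipy evaluates the regularized incomplete
            # beta function, exact to machine precision for n <= 1e7
            p = float(stats.binom.sf(c.observed_mutations - 1, c.bases_sequenced, background_rate))
        out[c.gene] = {
            "p": p,
            "p_bonferroni": min(1.0, p * m),
            "significant": bool(p * m < alpha),
        }
    return out


def cohort_background_rate(counts: list[GeneMutationCount]) -> float:
    """Default background mutation rate: total mutations / total bases."""
    bases = sum(c.bases_sequenced for c in counts)
    muts = sum(c.observed_mutations for c in counts)
    if bases == 0:
        raise ValueError("no sequenced bases")
    return muts / bases


def fusion_consensus(callsets: dict[str, list[FusionCandidate]]) -> list[FusionCandidate]:
    """Gene pairs reported by every caller (unordered pair match).

    Breakpoints of the first caller's candidate are retained; the matching
    candidates from the other callers are attached as evidence.
    """
    if len(callsets) < 2:
        raise ValueError("fusion consensus requires >= 2 callers")
    callers = list(callsets)
    pair_sets = [{c.pair for c in callsets[name]} for name in callers]
    common = set.intersection(*pair_sets)
    out = []
    for cand in callsets[callers[0]]:
        if cand.pair in common:
            evidence = tuple(
                other
                for name in callers[1:]
                for other in callsets[name]
                if other.pair == cand.pair
            )
            out.append(FusionCandidate(**{**cand.__dict__, "evidence": evidence}))
            common.discard(cand.pair)  # one consensus entry per pair
    return out


def variants_to_frame(variants: list[VariantRecord]):
    import pandas as pd

    return pd.DataFrame(
        [{c: getattr(v, c) for c in VARIANT_COLUMNS} for v in variants],
        columns=VARIANT_COLUMNS,
    )


def frame_to_variants(df) -> list[VariantRecord]:
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing column(s): {', '.join(missing)}")
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        recs.append(
            VariantRecord(
                sample_id=str(d["sample_id"]), chromosome=str(d["chromosome"]),
                position=int(d["position"]), ref=str(d["ref"]), alt=str(d["alt"]),
                gene=str(d["gene"]), somatic_score=float(d["somatic_score"]),
                somatic_rank=float(d["somatic_rank"]), fet_score=float(d["fet_score"]),
                in_dbsnp=bool(d["in_dbsnp"]), variant_in_cosmic=bool(d["variant_in_cosmic"]),
                gene_in_cosmic=bool(d["gene_in_cosmic"]), damaging_predicted=bool(d["damaging_predicted"]),
                rna_total_reads=int(d["rna_total_reads"]), rna_variant_reads=int(d["rna_variant_reads"]),
            )
        )
    return recs
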