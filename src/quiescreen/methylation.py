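"""Methylation-expression integration and bisulfite methylation calls.

Pipeline: map 450K-style probes to genes (gene body +/- 10 kb), collapse
expression probesets to genes (highest-mean probeset), regress expression on
beta per (probe, gene) pair, adjust p-values across pairs, then nominate
genes with >= 5 significant probes whose tumor-group beta means are extreme
(> 0.75 or < 0.25) and tight (SD < 0.25).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ISLAND_RELATIONS = {"island", "shore", "shelf", "open_sea"}


@dataclass
class MethylationMatrix:
    """Beta values (probes x samples) in [0, 1] with a group label per sample.

    Missing beta values are permitted and tracked; they are pairwise-deleted
    during correlation.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            raise ValueError("samples without group label in methylation matrix")
        arr = self.values.to_numpy(float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")

    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=1)


def validate_probe_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    required = {"probe", "chromosome", "position", "island_relation"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"probe annotation missing column(s): {sorted(missing)}")
    if (annot["position"] < 1).any():
        raise ValueError("probe positions must be >= 1 (1-based)")
    bad = set(annot["island_relation"]) - ISLAND_RELATIONS
    if bad:
        raise ValueError(f"unknown CpG-island relation(s): {sorted(bad)}")
    return annot


def map_probes_to_genes(
    annot: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 10000,
) -> pd.DataFrame:
    """Pair each probe with every gene whose body +/- ``flank`` bp contains it.

    ``annot`` columns: probe, chromosome, position (1-based).
    ``genes`` columns: symbol, chromosome, strand, start, end (1-based
    inclusive).  The flank is applied symmetrically on both sides, so strand
    is irrelevant.  A probe may pair with multiple genes.
    """
    pairs = []
    by_chrom = {c: g for c, g in genes.groupby("chromosome")}
    for row in annot.itertuples(index=False):
        g = by_chrom.get(row.chromosome)
        if g is None:
            continue
        hit = g[(g["start"] - flank <= row.position) & (row.position <= g["end"] + flank)]
        for sym in hit["symbol"]:
            pairs.append((row.probe, sym))
    return pd.DataFrame(pairs, columns=["probe", "gene"])


def pick_expression_probe(
    probesets: pd.DataFrame,
    probeset_to_gene: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse a probeset x sample matrix to genes.

    Per gene, the probeset with the highest mean expression across all
    samples wins; returns the gene-level matrix and the chosen probeset per
    gene (selection metadata).
    """
    means = probesets.mean(axis=1)
    chosen: dict[str, str] = {}
    for ps, gene in probeset_to_gene.items():
        if ps not in probesets.index:
            continue
        if gene not in chosen or means[ps] > means[chosen[gene]]:
            chosen[gene] = ps
    sel = pd.Series(chosen, name="probeset")
    out = probesets.loc[sel.to_numpy()].copy()
    out.index = sel.index
    return out, sel


def correlate_meth_expr(
    meth: MethylationMatrix,
    expr: pd.DataFrame,
    pairs: pd.DataFrame,
    min_samples: int = 4,
    max_missing: float = 0.2,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Regress expression on beta for each (probe, gene) pair.

    Ordinary least squares with identity link: t = slope / SE(slope),
    two-sided p on n - 2 degrees of freedom; a negative t means methylation
    and expression are inversely related.  Probes missing beta in more than
    ``max_missing`` of samples are excluded up front; remaining missing
    values are pairwise-deleted.  Adjusted p by Benjamini-Hochberg (or
    ``bonferroni``/``holm``) across all tested pairs.
    """
    shared = [s for s in meth.values.columns if s in expr.columns]
    frac = meth.missing_fraction()
    dropped_missing = set(frac.index[frac > max_missing])
    if dropped_missing:
        logger.warning("%d probe(s) excluded for > %.0f%% missing beta", len(dropped_missing), 100 * max_missing)
    rows = []
    skipped = 0
    for probe, gene in pairs.itertuples(index=False):
        if probe in dropped_missing or probe not in meth.values.index or gene not in expr.index:
            continue
        x = meth.values.loc[probe, shared].to_numpy(float)
        y = expr.loc[gene, shared].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        n = x.size
        if n < min_samples:
            continue
        sxx = float(((x - x.mean()) ** 2).sum())
        syy = float(((y - y.mean()) ** 2).sum())
        if sxx == 0.0 or syy == 0.0:
            logger.warning("pair (%s, %s) has zero variance; skipped", probe, gene)
            skipped += 1
            continue
        sxy = float(((x - x.mean()) * (y - y.mean())).sum())
        slope = sxy / sxx
        resid = y - (y.mean() + slope * (x - x.mean()))
        df = n - 2
        mse = float(resid @ resid) / df
        se = np.sqrt(mse / sxx)
        if se == 0.0:
            t = np.inf if slope > 0 else -np.inf
            p = 0.0
        else:
            t = slope / se
            p = 2.0 * float(stats.t.sf(abs(t), df))
        rows.append({"probe": probe, "gene": gene, "t": t, "p": p, "n": n})
    out = pd.DataFrame(rows, columns=["probe", "gene", "t", "p", "n"])
    out.attrs["skipped_zero_variance"] = skipped
    if len(out):
        out["p_adj"] = multipletests(out["p"].to_numpy(), method=adjust)[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def select_candidate_genes(
    results: pd.DataFrame,
    meth: MethylationMatrix,
    tumor_group: str,
    min_probes: int = 5,
    hi: float = 0.75,
    lo: float = 0.25,
    sd_cut: float = 0.25,
    alpha: float = 0.05,
    p_column: str = "p_adj",
    beta_group: str | None = "tumor",
) -> pd.DataFrame:
    """Nominate silenced/activated candidate genes.

    Step 1 keeps probes with ``p_column`` < ``alpha``.  Step 2 computes the
    per-probe mean and SD of beta across the tumor-group samples (set
    ``beta_group`` to ``"comparator"`` or ``"pooled"`` to average elsewhere).
    Step 3 emits genes with >= ``min_probes`` kept probes that each satisfy
    (mean > hi or mean < lo) and SD < sd_cut.  Direction is hyper when the
    qualifying means are high, hypo when low; mixed genes take the majority
    direction with a warning.
    """
    if not len(results):
        return pd.DataFrame(columns=["gene", "n_qualifying_probes", "direction", "mean_beta", "mean_abs_t", "probes"])
    sig = results[results[p_column] < alpha]
    if beta_group in (None, "tumor"):
        cols = list(meth.labels.index[meth.labels == tumor_group])
    elif beta_group == "comparator":
        cols = list(meth.labels.index[meth.labels != tumor_group])
    elif beta_group == "pooled":
        cols = list(meth.labels.index)
    else:
        raise ValueError(f"unknown beta_group {beta_group!r}")
    rows = []
    for gene, sub in sig.groupby("gene", sort=True):
        qual = []
        for probe, t in zip(sub["probe"], sub["t"]):
            if probe not in meth.values.index:
                continue
            b = meth.values.loc[probe, cols].to_numpy(float)
            b = b[np.isfinite(b)]
            if b.size < 2:
                continue
            m, sd = float(b.mean()), float(b.std(ddof=1))
            if (m > hi or m < lo) and sd < sd_cut:
                qual.append((probe, m, sd, float(t)))
        if len(qual) < min_probes:
            continue
        directions = ["hyper" if m > hi else "hypo" for _, m, _, _ in qual]
        n_hyper = directions.count("hyper")
        if 0 < n_hyper < len(directions):
            logger.warning("gene %s has mixed-direction qualifying probes", gene)
        direction = "hyper" if n_hyper * 2 >= len(directions) else "hypo"
        rows.append(
            {
                "gene": gene,
                "n_qualifying_probes": len(qual),
                "direction": direction,
                "mean_beta": float(np.mean([m for _, m, _, _ in qual])),
                "mean_abs_t": float(np.mean([abs(t) for _, _, _, t in qual])),
                "probes": ";".join(p for p, _, _, _ in qual),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "n_qualifying_probes", "direction", "mean_beta", "mean_abs_t", "probes"])
    if len(out):
        out = out.sort_values(["n_qualifying_probes", "mean_abs_t"], ascending=False, kind="stable").reset_index(drop=True)
    return out


def bisulfite_methylation_call(
    sites: pd.DataFrame,
    lo: float = 0.20,
    hi: float = 0.80,
) -> pd.DataFrame:
    """Per-CpG-site methylation from sequencing trace peak heights.

    ratio = C / (C + T); ratio <= ``lo`` unmethylated, ``lo`` < ratio <=
    ``hi`` partially methylated, ratio > ``hi`` fully methylated.  A site
    with both peaks zero is an error.
    ``sites`` columns: site, c_peak, t_peak.
    """
    required = {"site", "c_peak", "t_peak"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"bisulfite table missing column(s): {sorted(missing)}")
    rows = []
    for row in sites.itertuples(index=False):
        c, t = float(row.c_peak), float(row.t_peak)
        if c < 0 or t < 0:
            raise ValueError(f"site {row.site}: negative peak height")
        if c + t == 0:
            raise ValueError(f"site {row.site}: both peaks zero, ratio undefined")
        ratio = c / (c + t)
        if ratio <= lo:
            cls = "unmethylated"
        elif ratio <= hi:
            cls = "partially_methylated"
        else:
            cls = "fully_methylated"
        rows.append({"site": row.site, "ratio": ratio, "call": cls})
    return pd.DataFrame(rows, columns=["site", "ratio", "call"])
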