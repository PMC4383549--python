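"""Joint analysis of dynamic chromatin, dynamic enhancer and expression.

Covers promoter/distal classification of sites, padded intersection of the
two dynamic-site sets with directional concordance, nearest-gene coupling
of enhancer fold changes to expression fold changes, quartile concordance,
TSS signal profiles, quantile normalization, paired differential
expression, and the genes-near-risk-loci excess test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    ExpressionMatrix,
    Gene,
    GenomeTable,
    GenomicInterval,
    GwasLocus,
    ReadSet,
    nearest_tss,
)
from .differential import DynamicSite, bh_fdr

PROMOTER_MODES = ("upstream1kb", "flank1kb")


@dataclass(frozen=True)
class ConcordanceReport:
    n_chromatin_sites_overlapping: int
    n_enhancer_sites_overlapped: int
    n_concordant: int

    @property
    def pct_concordant(self) -> float:
        if self.n_enhancer_sites_overlapped == 0:
            return float("nan")
        return 100.0 * self.n_concordant / self.n_enhancer_sites_overlapped


@dataclass(frozen=True)
class GeneCoupling:
    gene_id: str
    expression_log2fc: float
    mean_site_log2fc: float
    n_sites: int


def format_pct(numerator: int, denominator: int) -> int:
    """Report-style integer percentage, rounded to nearest (half away from 0)."""
    if denominator == 0:
        raise ValueError("denominator is zero")
    import math
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def promoter_window(gene: Gene, mode: str, flank: int = 1000) -> GenomicInterval:
    """The promoter interval of a gene under the given convention.

    ``upstream1kb``: the ``flank`` bp 5' of the TSS (strand-aware), TSS
    included.  ``flank1kb``: ``flank`` bp on both sides of the TSS.
    """
    tss = gene.tss
    if mode == "upstream1kb":
        if gene.strand == "+":
            start, end = tss - flank, tss + 1
        else:
            start, end = tss, tss + flank + 1
    elif mode == "flank1kb":
        start, end = tss - flank, tss + flank + 1
    else:
        raise ValueError(f"unknown promoter mode {mode!r}")
    return GenomicInterval(gene.chrom, max(0, start), end)


def classify_promoter(
    sites: Sequence[DynamicSite],
    genes: Sequence[Gene],
    mode: str = "flank1kb",
) -> tuple[list[DynamicSite], list[DynamicSite], dict[str, int]]:
    """Split sites into promoter-class and distal by TSS-window intersection.

    Returns (promoter_sites, distal_sites, percentages); the percentages
    dict carries report-style integer values keyed ``pct_promoter`` /
    ``pct_distal``.
    """
    windows = [promoter_window(g, mode) for g in genes]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    promoter, distal = [], []
    for site in sites:
        ws = by_chrom.get(site.interval.chrom, [])
        if any(site.interval.overlaps(w) for w in ws):
            promoter.append(site)
        else:
            distal.append(site)
    n = len(sites)
    pcts = {}
    if n:
        pcts = {
            "pct_promoter": format_pct(len(promoter), n),
            "pct_distal": format_pct(len(distal), n),
        }
    return promoter, distal, pcts


def intersect_dynamic(
    chromatin_sites: Sequence[DynamicSite],
    enhancer_sites: Sequence[DynamicSite],
    pad: int = 300,
) -> tuple[pd.DataFrame, ConcordanceReport]:
    """Pair chromatin sites (expanded ±pad bp) with enhancer sites they touch.

    A pair is concordant when the two sites change in the same direction.
    The report counts distinct chromatin sites with >= 1 pair, distinct
    enhancer sites with >= 1 pair, and — following the denominator used in
    the published concordance figure — the number of overlapped enhancer
    sites with >= 1 concordant pair.
    """
    rows = []
    for ci, cs in enumerate(chromatin_sites):
        expanded = cs.interval.expand(pad)
        for ei, es in enumerate(enhancer_sites):
            if expanded.overlaps(es.interval):
                rows.append({
                    "chromatin_idx": ci, "enhancer_idx": ei,
                    "chrom": cs.interval.chrom,
                    "chromatin_start": cs.interval.start,
                    "chromatin_end": cs.interval.end,
                    "enhancer_start": es.interval.start,
                    "enhancer_end": es.interval.end,
                    "chromatin_direction": cs.direction,
                    "enhancer_direction": es.direction,
                    "concordant": cs.direction == es.direction,
                })
    pairs = pd.DataFrame(rows, columns=[
        "chromatin_idx", "enhancer_idx", "chrom", "chromatin_start",
        "chromatin_end", "enhancer_start", "enhancer_end",
        "chromatin_direction", "enhancer_direction", "concordant",
    ])
    if len(pairs):
        n_chrom = pairs["chromatin_idx"].nunique()
        n_enh = pairs["enhancer_idx"].nunique()
        n_conc = pairs.loc[pairs["concordant"], "enhancer_idx"].nunique()
    else:
        n_chrom = n_enh = n_conc = 0
    return pairs, ConcordanceReport(n_chrom, n_enh, n_conc)


def couple_genes(
    enhancer_sites: Sequence[DynamicSite],
    de_genes: pd.DataFrame,
    genes: Sequence[Gene],
) -> tuple[list[GeneCoupling], float, float]:
    """Mean enhancer fold per DE gene vs its expression fold.

    ``de_genes`` is the paired-DE frame (index gene_id, column ``log2fc``)
    restricted to the significant set.  Each enhancer site is annotated to
    its nearest gene by TSS; per DE gene with >= 1 annotated site the mean
    site log2fc is paired with the expression log2fc.  Returns the
    couplings plus Pearson r and r^2 (NaN when < 3 coupled genes).
    """
    site_fold_by_gene: dict[str, list[float]] = {}
    for site in enhancer_sites:
        gene_id, _ = nearest_tss(site.interval, genes)
        if gene_id:
            site_fold_by_gene.setdefault(gene_id, []).append(site.log2fc)
    couplings = [
        GeneCoupling(g, float(de_genes.loc[g, "log2fc"]),
                     float(np.mean(folds)), len(folds))
        for g, folds in site_fold_by_gene.items()
        if g in de_genes.index
    ]
    if len(couplings) < 3:
        return couplings, float("nan"), float("nan")
    x = np.array([c.mean_site_log2fc for c in couplings])
    y = np.array([c.expression_log2fc for c in couplings])
    r = float(stats.pearsonr(x, y).statistic)
    return couplings, r, r * r


def quartile_concordance(
    de_genes: pd.DataFrame,
    enhancer_sites: Sequence[DynamicSite],
    genes: Sequence[Gene],
) -> pd.DataFrame:
    """Per-quartile fraction of DE genes with a concordant dynamic enhancer.

    Up- and down-regulated genes are handled separately; within each
    direction genes are split into 4 quartiles by |log2 fold| (stable sort,
    boundary ties fall into the lower quartile).  A gene counts as
    concordant when >= 1 enhancer site annotated to it (nearest gene by
    TSS) changes in the same direction as its expression.
    """
    sites_by_gene: dict[str, list[int]] = {}
    for site in enhancer_sites:
        gene_id, _ = nearest_tss(site.interval, genes)
        if gene_id:
            sites_by_gene.setdefault(gene_id, []).append(site.direction)

    rows = []
    for direction, label in ((1, "up"), (-1, "down")):
        sub = de_genes[np.sign(de_genes["log2fc"]) == direction]
        if len(sub) < 4:
            raise ValueError(f"need >= 4 {label}-regulated genes for quartiles")
        order = sub["log2fc"].abs().sort_values(kind="stable").index
        quartiles = np.array_split(np.asarray(order), 4)
        for qi, members in enumerate(quartiles, 1):
            concordant = sum(
                1 for g in members
                if direction in sites_by_gene.get(g, [])
            )
            rows.append({
                "direction": label, "quartile": qi, "n_genes": len(members),
                "n_concordant": concordant,
                "proportion": concordant / len(members),
            })
    return pd.DataFrame(rows)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common reference distribution (the
    row-mean of sorted columns); ties within a column receive the mean of
    the corresponding reference values."""
    if matrix.size == 0:
        raise ValueError("empty matrix")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(len(col))
        assigned[order] = reference
        # ties share the mean of the reference values they span
        out[:, j] = pd.Series(assigned).groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def tss_profile(
    readsets: Sequence[ReadSet],
    genes: Sequence[Gene],
    genome: GenomeTable,
    half_window: int = 1000,
    bin_bp: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reads-per-million around each TSS, per condition.

    Returns (per_gene, profile): per-gene RPM within [TSS-half_window,
    TSS+half_window) for each condition, and the mean RPM per ``bin_bp``
    bin across genes with position measured 5'->3' (minus-strand genes are
    flipped).
    """
    conditions = list(dict.fromkeys(rs.condition for rs in readsets))
    n_bins = 2 * half_window // bin_bp
    usable = [
        g for g in genes
        if g.tss - half_window >= 0 and g.tss + half_window <= genome[g.chrom]
    ]
    per_gene = {}
    profiles = {}
    for cond in conditions:
        sets_c = [rs for rs in readsets if rs.condition == cond]
        lib = sum(rs.library_size for rs in sets_c)
        scale = 1e6 / lib if lib else 0.0
        pooled = {}
        for chrom in genome:
            pooled[chrom] = np.sort(np.concatenate(
                [rs.positions.get(chrom, np.empty(0, dtype=np.int64))
                 for rs in sets_c]
            ))
        totals = np.zeros(len(usable))
        binned = np.zeros((len(usable), n_bins))
        for gi, gene in enumerate(usable):
            pos = pooled[gene.chrom]
            lo, hi = gene.tss - half_window, gene.tss + half_window
            window = pos[np.searchsorted(pos, lo):np.searchsorted(pos, hi)]
            totals[gi] = window.size * scale
            rel = window - lo
            if gene.strand == "-":
                rel = 2 * half_window - 1 - rel
            binned[gi] = np.bincount(rel // bin_bp, minlength=n_bins) * scale
        per_gene[cond] = totals
        profiles[cond] = binned.mean(axis=0)
    per_gene_df = pd.DataFrame(per_gene, index=[g.gene_id for g in usable])
    offsets = np.arange(n_bins) * bin_bp - half_window
    profile_df = pd.DataFrame({"offset": offsets, **profiles})
    return per_gene_df, profile_df


def tss_signal_test(per_gene: pd.DataFrame) -> tuple[float, float]:
    """Paired t-test of per-gene TSS signal between the two conditions."""
    c1, c2 = per_gene.columns[:2]
    res = stats.ttest_rel(per_gene[c2], per_gene[c1])
    return float(res.statistic), float(res.pvalue)


def paired_de(expression: ExpressionMatrix, q_threshold: float = 0.05
              ) -> pd.DataFrame:
    """Per-gene paired t-test across donors (condition 2 minus condition 1).

    Returns a frame indexed by gene with columns log2fc (mean within-donor
    difference), t, p, q and ``significant`` (q < threshold).  Genes with
    zero difference variance get NaN p/q and are flagged ``degenerate``.
    """
    cond1, cond2 = expression.conditions[:2]
    if len(expression.donors) < 2:
        raise ValueError("paired test needs >= 2 donors")
    v1 = expression.condition_values(cond1).to_numpy()
    v2 = expression.condition_values(cond2).to_numpy()
    diffs = v2 - v1
    fold = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    n = diffs.shape[1]
    degenerate = sd == 0
    t = np.full(len(fold), np.nan)
    p = np.full(len(fold), np.nan)
    ok = ~degenerate
    t[ok] = fold[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    q = np.full(len(fold), np.nan)
    q[ok] = bh_fdr(p[ok])
    return pd.DataFrame({
        "log2fc": fold, "t": t, "p": p, "q": q,
        "significant": (q < q_threshold) & ok,
        "degenerate": degenerate,
    }, index=expression.values.index)


def genes_near_loci(
    loci: Sequence[GwasLocus],
    genes: Sequence[Gene],
    de: pd.DataFrame,
    flank: int = 50_000,
) -> tuple[dict[str, list[str]], dict]:
    """Genes within ``flank`` bp of each locus interval plus a DE-excess test.

    A gene qualifies for a locus when its gene body lies within ``flank``
    bp of the locus interval (min..max SNP).  The excess test is an
    upper-tail binomial on the number of DE genes among the qualifying
    genes, with success probability the genome-wide DE fraction among all
    genes present in ``de``.
    """
    per_locus: dict[str, list[str]] = {}
    near: set[str] = set()
    for locus in loci:
        hits = [
            g.gene_id for g in genes
            if g.chrom == locus.chrom
            and locus.interval.expand(flank).overlaps(g.interval)
        ]
        per_locus[locus.locus_id] = hits
        near.update(hits)
    near_in_de = [g for g in near if g in de.index]
    if not near_in_de:
        return per_locus, {"n_genes": 0, "n_de": 0, "p": None}
    background_fraction = float(de["significant"].mean())
    n_de = int(de.loc[near_in_de, "significant"].sum())
    test = stats.binomtest(n_de, len(near_in_de), background_fraction,
                           alternative="greater")
    return per_locus, {
        "n_genes": len(near_in_de),
        "n_de": n_de,
        "background_fraction": background_fraction,
        "p": float(test.pvalue),
    }
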