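"""Per-gene transcriptional read-through quantification and testing.

The read-through index of a gene is the ratio of reads in the window from
the PAS to 50 nt downstream to the reads within the gene body [TSS, PAS),
computed on the gene's strand.  Being a within-gene ratio it is invariant
under any global rescaling of the coverage track, which is why the
housekeeping normalization (scaling every strain to equal reads on a
stably expressed reference gene) leaves it untouched.  Mutant strains are
compared to wild type per gene as log2(rt_mut / rt_wt), and cohort-level
shifts are assessed with rank tests.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import GeneModel, GeneSet, StrandedCoverage, oriented_window

__all__ = [
    "window_count",
    "readthrough_table",
    "compare_to_wt",
    "cohort_test",
    "per_gene_test",
    "housekeeping_normalize",
    "split_by_binding",
    "rt_correlation",
    "pas_usage_index",
]

DEFAULT_POST_WINDOW = (0, 50)


def window_count(
    cov: StrandedCoverage,
    gene: GeneModel,
    start_offset: int,
    end_offset: int,
    anchor: str = "PAS",
    with_flag: bool = False,
):
    """Sum coverage on the gene's strand over an oriented anchor window.

    Offsets are in transcription direction; windows running off the
    chromosome are clipped (flag available via ``with_flag``).
    """
    a = gene.tss if anchor.upper() == "TSS" else gene.pas
    lo, hi = oriented_window(a, gene.strand, start_offset, end_offset)
    total, clipped = cov.window_sum(gene.chrom, gene.strand, lo, hi)
    return (total, clipped) if with_flag else total


def readthrough_table(
    cov: StrandedCoverage,
    genes: GeneSet,
    post_window: Tuple[int, int] = DEFAULT_POST_WINDOW,
    min_body: float = 10.0,
) -> pd.DataFrame:
    """Per-gene post-PAS and gene-body counts and their ratio.

    Genes whose body count falls below ``min_body`` get rt_index NaN and
    ``excluded=True`` rather than being dropped, so cohorts stay aligned
    across strains.
    """
    rows = []
    for g in genes:
        body, bflag = window_count(cov, g, -g.length, 0, anchor="PAS", with_flag=True)
        post, pflag = window_count(
            cov, g, post_window[0], post_window[1], anchor="PAS", with_flag=True
        )
        excluded = body < min_body
        rt = post / body if not excluded else np.nan
        flags = []
        if bflag or pflag:
            flags.append("clipped")
        if excluded:
            flags.append("low_body")
        rows.append(
            {
                "gene_id": g.gene_id,
                "post_pas": post,
                "body": body,
                "rt_index": rt,
                "excluded": excluded,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def compare_to_wt(mut: pd.DataFrame, wt: pd.DataFrame) -> pd.DataFrame:
    """Per-gene log2 fold change of read-through index, mutant over WT.

    Genes excluded in either strain, or with a zero WT index (infinite fold
    change), are flagged and excluded from downstream summary statistics.
    """
    if not mut.index.equals(wt.index):
        raise ValueError("mutant and WT tables cover different gene cohorts")
    rt_m = mut["rt_index"]
    rt_w = wt["rt_index"]
    excluded = mut["excluded"] | wt["excluded"]
    infinite = (~excluded) & (rt_w == 0) & (rt_m > 0)
    both_zero = (~excluded) & (rt_w == 0) & (rt_m == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(rt_m / rt_w)
    log2fc[both_zero] = 0.0  # no read-through in either strain
    out = pd.DataFrame(
        {
            "rt_mut": rt_m,
            "rt_wt": rt_w,
            "log2fc": log2fc,
            "excluded": excluded | infinite,
            "infinite": infinite,
        }
    )
    return out


def _valid_log2fc(comparison: pd.DataFrame) -> np.ndarray:
    vals = comparison.loc[~comparison["excluded"], "log2fc"].to_numpy()
    return vals[np.isfinite(vals)]


def cohort_test(
    comparison: pd.DataFrame,
    null_comparison: Optional[pd.DataFrame] = None,
    alternative: str = "two-sided",
) -> float:
    """Cohort-level significance of a read-through shift.

    With a WT-replicate null comparison, a Wilcoxon-Mann-Whitney rank-sum
    test of the mutant log2fc values against the replicate log2fc values;
    without one, a one-sample Wilcoxon signed-rank test of the mutant
    log2fc values against zero.
    """
    x = _valid_log2fc(comparison)
    if x.size < 2:
        raise ValueError("cohort_test needs at least 2 genes with defined log2fc")
    if null_comparison is not None:
        y = _valid_log2fc(null_comparison)
        if y.size < 2:
            raise ValueError("null comparison needs at least 2 genes")
        return float(stats.mannwhitneyu(x, y, alternative=alternative).pvalue)
    return float(stats.wilcoxon(x, alternative=alternative).pvalue)


def per_gene_test(
    mut_cov: StrandedCoverage,
    wt_cov: StrandedCoverage,
    gene: GeneModel,
    alpha: float = 0.05,
    post_window: Tuple[int, int] = DEFAULT_POST_WINDOW,
    min_positions: int = 10,
) -> Tuple[float, bool]:
    """Kruskal-Wallis test for a single gene's post-PAS coverage shift.

    Observations are per-position post-PAS coverage values, each strain's
    positions normalized by that strain's gene-body mean; the call is
    one-sided 'more read-through than WT': significant requires P < alpha
    and mutant median above WT median.  All-tied data yields p = 1.
    """
    lo, hi = oriented_window(gene.pas, gene.strand, *post_window)
    if hi - lo < min_positions:
        raise ValueError(f"{gene.gene_id}: post-PAS window shorter than {min_positions}")

    def positions(cov: StrandedCoverage) -> np.ndarray:
        size = cov.chrom_sizes[gene.chrom]
        clo, chi = max(lo, 0), min(hi, size)
        vals = cov.get(gene.chrom, gene.strand)[clo:chi]
        body = window_count(cov, gene, -gene.length, 0)
        body_mean = body / gene.length
        if body_mean <= 0:
            raise ValueError(f"{gene.gene_id}: zero gene-body coverage")
        return vals / body_mean

    x = positions(mut_cov)
    y = positions(wt_cov)
    if x.size < min_positions or y.size < min_positions:
        raise ValueError(f"{gene.gene_id}: too few post-PAS positions with data")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0, False
    p = float(stats.kruskal(x, y).pvalue)
    significant = bool(p < alpha and np.median(x) > np.median(y))
    return p, significant


def housekeeping_normalize(
    cov: StrandedCoverage,
    genes: GeneSet,
    reference_gene_id: str = "adh1-like",
    target_constant: float = 1e6,
) -> StrandedCoverage:
    """Scale the whole track so the reference gene's body count equals
    ``target_constant``; robust to pervasive intergenic signal that breaks
    library-size normalization."""
    ref = genes.by_id(reference_gene_id)
    body = window_count(cov, ref, -ref.length, 0)
    if body <= 0:
        raise ValueError(f"reference gene {reference_gene_id} has zero body count")
    return cov.scaled(target_constant / body)


def split_by_binding(
    comparison: pd.DataFrame, binding: pd.Series
) -> Tuple[pd.DataFrame, float]:
    """Compare read-through change between bound and unbound genes.

    Returns per-group median/quartiles/n and the Wilcoxon-Mann-Whitney
    two-sided p-value between the two log2fc distributions.
    """
    binding = binding.reindex(comparison.index).fillna(False).astype(bool)
    ok = ~comparison["excluded"] & np.isfinite(comparison["log2fc"])
    bound = comparison.loc[ok & binding, "log2fc"].to_numpy()
    unbound = comparison.loc[ok & ~binding, "log2fc"].to_numpy()
    if bound.size == 0 or unbound.size == 0:
        raise ValueError("one of the binding groups is empty")
    rows = []
    for name, vals in (("bound", bound), ("unbound", unbound)):
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"group": name, "n": vals.size, "q1": q1, "median": med, "q3": q3})
    p = float(stats.mannwhitneyu(bound, unbound, alternative="two-sided").pvalue)
    return pd.DataFrame(rows).set_index("group"), p


def rt_correlation(a: pd.Series, b: pd.Series, method: str = "spearman") -> float:
    """Rank correlation of two per-gene value series on their shared genes."""
    if method != "spearman":
        raise ValueError("only rank (Spearman) correlation is supported")
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 shared genes")
    rho = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic
    return float(rho)


def pas_usage_index(
    cov: StrandedCoverage,
    gene: GeneModel,
    flank: int = 50,
    pas: Optional[int] = None,
) -> float:
    """Cleavage-efficiency proxy at a PAS: 1 - mean(downstream flank) /
    mean(upstream flank), clipped at 1.  Full signal drop past the PAS
    gives 1; no drop gives 0.  An external PAS annotation may be passed via
    ``pas``; zero upstream signal is undefined and raises."""
    a = gene.pas if pas is None else pas
    up_lo, up_hi = oriented_window(a, gene.strand, -flank, 0)
    dn_lo, dn_hi = oriented_window(a, gene.strand, 0, flank)
    up, _ = cov.window_sum(gene.chrom, gene.strand, up_lo, up_hi)
    dn, _ = cov.window_sum(gene.chrom, gene.strand, dn_lo, dn_hi)
    if up <= 0:
        raise ValueError(f"{gene.gene_id}: zero upstream signal, usage undefined")
    return min(1.0 - (dn / flank) / (up / flank), 1.0)
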