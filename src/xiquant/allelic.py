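"""Allele-specific (maternal/paternal, 'a'/'b') count analysis.

Implements the filtering and ratio pipeline for haplotype-resolved read
counts: DNA-based SNP validation (drop SNPs with a zero count on either
allele, then drop SNPs whose allelic bias deviates from the population
mean by more than one standard deviation), aggregation of SNP counts to
genes, minimum-coverage gene filters, replicate-averaged a:b ratios, IgG
background subtraction for antibody-directed chromatin libraries, and a
per-gene exact-test screen for shifts in allelic skew between conditions
(e.g. reactivation of silenced X-linked genes).

Counts enter as tidy tables: per-SNP rows ``chrom, pos, gene, a_count,
b_count`` (positions 1-based, VCF convention) or gene-level tables indexed
by gene with ``a_count``/``b_count`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SnpFilterReport",
    "filter_snps",
    "aggregate_to_genes",
    "filter_genes",
    "ab_ratios",
    "subtract_igg",
    "reactivation_screen",
    "bed_to_gene_map",
]


@dataclass
class SnpFilterReport:
    n_input: int
    n_removed_zero: int
    n_removed_bias: int
    n_retained: int
    bias_mean: float
    bias_sd: float


def filter_snps(snps: pd.DataFrame) -> tuple[pd.DataFrame, SnpFilterReport]:
    """DNA-library SNP validation.

    Two passes: (1) remove SNPs with zero counts for either allele;
    (2) on the zero-filtered set compute the per-SNP bias ``a/(a+b)`` and
    remove SNPs whose bias deviates from the mean by more than one sample
    standard deviation. When the SD is zero (all biases identical) the
    strict inequality removes nothing.
    """
    if len(snps) < 2:
        raise ValueError("need at least 2 SNPs for the bias filter")
    a = snps["a_count"].to_numpy(dtype=np.float64)
    b = snps["b_count"].to_numpy(dtype=np.float64)
    nonzero = (a > 0) & (b > 0)
    stage1 = snps.loc[nonzero].copy()
    bias = stage1["a_count"] / (stage1["a_count"] + stage1["b_count"])
    mean = float(bias.mean())
    sd = float(bias.std(ddof=1)) if len(bias) > 1 else 0.0
    keep = (bias - mean).abs() <= sd
    retained = stage1.loc[keep].copy()
    report = SnpFilterReport(
        n_input=len(snps),
        n_removed_zero=int((~nonzero).sum()),
        n_removed_bias=int((~keep).sum()),
        n_retained=len(retained),
        bias_mean=mean,
        bias_sd=sd,
    )
    return retained, report


def aggregate_to_genes(
    snp_counts: pd.DataFrame, retained_snps: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict]:
    """Sum per-SNP allele counts to the gene level.

    Only SNPs present in ``retained_snps`` (matched on ``chrom``/``pos``)
    contribute; genes with no retained SNP are absent from the output.
    SNPs with a null/empty gene are excluded and tallied in the report.
    """
    df = snp_counts.copy()
    if retained_snps is not None:
        key = pd.MultiIndex.from_frame(retained_snps[["chrom", "pos"]])
        df = df[pd.MultiIndex.from_frame(df[["chrom", "pos"]]).isin(key)]
    unmapped = df["gene"].isna() | (df["gene"] == "")
    report = {"n_snps_used": int((~unmapped).sum()), "n_snps_unmapped": int(unmapped.sum())}
    df = df.loc[~unmapped]
    gene_table = df.groupby("gene", sort=True)[["a_count", "b_count"]].sum()
    return gene_table, report


def filter_genes(table: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Keep genes whose total allele count strictly exceeds ``min_total``."""
    total = table["a_count"] + table["b_count"]
    return table.loc[total > min_total].copy()


def ab_ratios(
    tables: dict[str | int, pd.DataFrame], min_total: int = 10
) -> pd.DataFrame:
    """Replicate-averaged allelic ratios.

    ``tables`` maps replicate id to a gene-level count table. A gene
    contributes only if it passes the coverage filter in *every* replicate.
    The output has, per gene, the per-replicate proportion ``a/(a+b)``, the
    mean proportion across replicates, and the odds-form ratio ``a/b``
    (infinite where ``b = 0``, flagged and excluded from averaging — means
    are taken on proportions).
    """
    if not tables:
        raise ValueError("need at least one replicate table")
    filtered = {rep: filter_genes(t, min_total) for rep, t in tables.items()}
    common = None
    for t in filtered.values():
        common = t.index if common is None else common.intersection(t.index)
    out = pd.DataFrame(index=common.sort_values())
    props = []
    for rep, t in filtered.items():
        sub = t.loc[out.index]
        prop = sub["a_count"] / (sub["a_count"] + sub["b_count"])
        with np.errstate(divide="ignore"):
            odds = sub["a_count"] / sub["b_count"]
        out[f"prop_a_{rep}"] = prop
        out[f"ratio_ab_{rep}"] = odds
        props.append(prop)
    out["mean_prop_a"] = pd.concat(props, axis=1).mean(axis=1)
    out["any_infinite_ratio"] = ~np.isfinite(
        out[[c for c in out.columns if c.startswith("ratio_ab_")]]
    ).all(axis=1)
    return out


def subtract_igg(
    antibody: pd.DataFrame, igg: pd.DataFrame, min_total: int = 5
) -> pd.DataFrame:
    """IgG background subtraction for antibody-directed libraries.

    Per gene, subtract the IgG library's allele counts from the antibody
    library's (genes absent from IgG are treated as zero background), then
    keep genes with both corrected allele counts non-negative and a
    corrected total strictly greater than ``min_total``.
    """
    igg_aligned = igg.reindex(antibody.index, fill_value=0)
    corrected = pd.DataFrame(
        {
            "a_count": antibody["a_count"] - igg_aligned["a_count"],
            "b_count": antibody["b_count"] - igg_aligned["b_count"],
        },
        index=antibody.index,
    )
    ok = (
        (corrected["a_count"] >= 0)
        & (corrected["b_count"] >= 0)
        & (corrected["a_count"] + corrected["b_count"] > min_total)
    )
    return corrected.loc[ok]


def _pool(tables: list[pd.DataFrame]) -> pd.DataFrame:
    return pd.concat(tables).groupby(level=0)[["a_count", "b_count"]].sum()


def reactivation_screen(
    condition_a: list[pd.DataFrame],
    condition_b: list[pd.DataFrame],
    chrom_by_gene: pd.Series | None = None,
    restrict_chrom: str | None = "chrX",
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-gene shift in allelic skew between two conditions.

    Counts are pooled over replicates within each condition; for each gene
    the 2x2 table (a/b counts x condition) is tested with a two-sided
    conditional exact test (Fisher), the effect is reported as the log2
    fold-change of the a:b odds (0.5 pseudocount on every cell), and
    Benjamini-Hochberg FDR is computed across tested genes. Genes absent
    from either condition are excluded and reported via the
    ``tested`` index. Restriction to one chromosome (default the X) needs a
    ``chrom_by_gene`` mapping.
    """
    pa, pb = _pool(condition_a), _pool(condition_b)
    genes = pa.index.intersection(pb.index)
    if chrom_by_gene is not None and restrict_chrom is not None:
        on_chrom = chrom_by_gene.reindex(genes) == restrict_chrom
        genes = genes[on_chrom.fillna(False).to_numpy()]
    rows = []
    for g in genes:
        a1, b1 = int(pa.loc[g, "a_count"]), int(pa.loc[g, "b_count"])
        a2, b2 = int(pb.loc[g, "a_count"]), int(pb.loc[g, "b_count"])
        odds1 = (a1 + 0.5) / (b1 + 0.5)
        odds2 = (a2 + 0.5) / (b2 + 0.5)
        _, p = fisher_exact([[a1, b1], [a2, b2]], alternative="two-sided")
        rows.append(
            {
                "gene": g,
                "a_ctrl": a1,
                "b_ctrl": b1,
                "a_cond": a2,
                "b_cond": b2,
                "log2_odds_fc": float(np.log2(odds2 / odds1)),
                "p_value": float(p),
            }
        )
    res = pd.DataFrame(
        rows, columns=["gene", "a_ctrl", "b_ctrl", "a_cond", "b_cond", "log2_odds_fc", "p_value"]
    ).set_index("gene")
    if len(res):
        res["fdr"] = multipletests(res["p_value"].to_numpy(), method=fdr_method)[1]
    else:
        res["fdr"] = pd.Series(dtype=float)
    return res


def bed_to_gene_map(bed: pd.DataFrame) -> pd.DataFrame:
    """Convert BED-like gene intervals (0-based, half-open) to 1-based
    inclusive intervals matching VCF-style SNP positions.

    Input columns ``chrom, start, end, gene``; output adds ``start_1based``
    and ``end_1based`` (= start+1 and end, respectively).
    """
    out = bed.copy()
    out["start_1based"] = out["start"] + 1
    out["end_1based"] = out["end"]
    return out


def map_snps_to_genes(snps: pd.DataFrame, gene_map: pd.DataFrame) -> pd.DataFrame:
    """Annotate SNPs (1-based positions) with the gene whose 1-based
    inclusive interval contains them; SNPs in no gene get an empty gene."""
    gm = bed_to_gene_map(gene_map) if "start_1based" not in gene_map.columns else gene_map
    out = snps.copy()
    gene_col = []
    for _, s in out.iterrows():
        hits = gm[
            (gm["chrom"] == s["chrom"])
            & (gm["start_1based"] <= s["pos"])
            & (s["pos"] <= gm["end_1based"])
        ]
        gene_col.append(hits["gene"].iloc[0] if len(hits) else "")
    out["gene"] = gene_col
    return out
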