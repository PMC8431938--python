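"""Allele-specific expression (ASE) of rare pathogenic variant carriers.

A heterozygous carrier expresses both alleles; nonsense-mediated decay and
similar mechanisms deplete the alternate allele in RNA, so the alternate
read count at the variant position follows Binomial(depth, pi) with pi well
below the null 0.5. The stage:

* selects analysis-ready records — heterozygous carriers of rare variants
  (population MAF <= 0.05% by default), the single deepest RNA source per
  carrier-variant, and at least 6 reads covering the allele;
* calls ASE with the exact one-sided (lower-tail) binomial test against
  0.5, BH-adjusted across all tested records, tiered at FDR 0.05 / 0.15;
* tests each gene for enrichment of significant-ASE records with a
  two-sided Fisher exact test (eligibility: >= 3 significant records and a
  significant fraction strictly above 70%);
* tests each predicted variant function class by permutation: ASE statuses
  are shuffled across all records (10,000 times by default) and the p-value
  is the fraction of shuffles whose class proportion strictly exceeds the
  observed one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stats_core
from .expression_impact import tier_of
from .io import KEY_COLS

log = logging.getLogger(__name__)


def _vkey(df: pd.DataFrame) -> pd.Series:
    return (df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + df["ref"] + ":" + df["alt"])


def select_ase_input(records: pd.DataFrame, variants: pd.DataFrame,
                     calls: pd.DataFrame, max_maf: float = 0.0005,
                     min_reads: int = 6) -> pd.DataFrame:
    """Filter RNA allelic-count records down to the analysis-ready set.

    Keeps heterozygous carrier-variants of rare variants (population AF <=
    ``max_maf``; a missing AF passes with a warning), selects the single
    source with the greatest depth at the allele per carrier-variant
    (ties broken by lexicographically smallest source_id), then requires
    ref + alt reads >= ``min_reads``.
    """
    rec = records.copy()
    rec["key"] = _vkey(rec)
    vmeta = variants.copy()
    vmeta["key"] = _vkey(vmeta)
    af = vmeta.drop_duplicates("key").set_index("key")["af"]

    het = calls[calls["zygosity"] == "het"]
    het_pairs = set(zip(het["sample_id"], _vkey(het)))
    rec = rec[[(s, k) in het_pairs for s, k in zip(rec["sample_id"], rec["key"])]]

    rec_af = rec["key"].map(af)
    n_missing = int(rec_af.isna().sum())
    if n_missing:
        log.warning("%d records lack a population AF; treated as rare", n_missing)
    rec = rec[rec_af.isna() | (rec_af <= max_maf)]

    rec = rec.copy()
    rec["depth_at_allele"] = rec["ref_count"] + rec["alt_count"]
    rec = (rec.sort_values(["sample_id", "key", "depth_at_allele", "source_id"],
                           ascending=[True, True, False, True], kind="stable")
           .drop_duplicates(subset=["sample_id", "key"], keep="first"))
    rec = rec[rec["depth_at_allele"] >= min_reads]
    return rec.reset_index(drop=True)


def call_ase(records: pd.DataFrame) -> pd.DataFrame:
    """One-sided binomial ASE test per analysis-ready carrier-variant.

    p = P[X <= alt] under Binomial(ref + alt, 0.5); the alternative is that
    the alternate allele is under-expressed. BH runs over ALL tested
    records pooled.
    """
    out = records.copy()
    if "depth_at_allele" not in out.columns:
        out["depth_at_allele"] = out["ref_count"] + out["alt_count"]
    out["p"] = [stats_core.binom_lower_tail(int(a), int(n))
                for a, n in zip(out["alt_count"], out["depth_at_allele"])]
    out["fdr"] = stats_core.bh_adjust(out["p"].tolist()) if len(out) else []
    out["tier"] = [tier_of(f) for f in out["fdr"]]
    return out


def gene_ase_enrichment(ase_calls: pd.DataFrame, variants: pd.DataFrame,
                        min_sig: int = 3, min_frac: float = 0.7,
                        unit: str = "records") -> pd.DataFrame:
    """Per-gene enrichment of significant-ASE records (two-sided Fisher).

    A gene is eligible when it has at least ``min_sig`` significant records
    and its significant fraction strictly exceeds ``min_frac``. The 2x2
    table crosses in-gene / not-in-gene with significant / not over all
    tested units. ``unit`` = "records" counts carrier-variant records (the
    default); "variants" collapses to unique variants (significant when any
    carrier record is).
    """
    if unit not in ("records", "variants"):
        raise ValueError("unit must be 'records' or 'variants'")
    vmeta = variants.copy()
    vmeta["key"] = _vkey(vmeta)
    gene_of = vmeta.drop_duplicates("key").set_index("key")["gene"]
    df = ase_calls.copy()
    if "key" not in df.columns:
        df["key"] = _vkey(df)
    df["gene"] = df["key"].map(gene_of)
    df["sig"] = df["tier"] == "significant"
    if unit == "variants":
        df = (df.groupby("key")
              .agg(gene=("gene", "first"), sig=("sig", "any"))
              .reset_index())
    total = len(df)
    total_sig = int(df["sig"].sum())
    rows = []
    for gene, grp in df.groupby("gene"):
        n_gene = len(grp)
        k_sig = int(grp["sig"].sum())
        frac = k_sig / n_gene
        if k_sig < min_sig or frac <= min_frac:
            continue
        table = (k_sig, n_gene - k_sig,
                 total_sig - k_sig, (total - n_gene) - (total_sig - k_sig))
        p = stats_core.fisher_exact_two_sided(table)
        rows.append({"gene": gene, "n_records": n_gene, "n_significant": k_sig,
                     "fraction_significant": frac, "p": p})
    res = pd.DataFrame(rows, columns=["gene", "n_records", "n_significant",
                                      "fraction_significant", "p"])
    res["fdr"] = stats_core.bh_adjust(res["p"].tolist()) if len(res) else []
    res["tier"] = [tier_of(f) for f in res["fdr"]]
    return res.sort_values("p", kind="stable").reset_index(drop=True)


def class_ase_enrichment(ase_calls: pd.DataFrame, variants: pd.DataFrame,
                         n_perm: int = 10000, seed: int | None = None,
                         smoothed: bool = False) -> pd.DataFrame:
    """Permutation enrichment of significant ASE per variant function class.

    The statistic is the proportion of significant-ASE records within the
    class. Significance labels are shuffled across all records with class
    sizes fixed; the p-value is the fraction of shuffles whose class
    proportion strictly exceeds the observed one. ``smoothed=True`` applies
    the (b + 1) / (B + 1) correction instead (off by default).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    vmeta = variants.copy()
    vmeta["key"] = _vkey(vmeta)
    class_of = vmeta.drop_duplicates("key").set_index("key")["function_class"]
    df = ase_calls.copy()
    if "key" not in df.columns:
        df["key"] = _vkey(df)
    df["function_class"] = df["key"].map(class_of)
    labels = (df["tier"] == "significant").to_numpy()
    classes = df["function_class"].to_numpy()
    codes, uniques = pd.factorize(classes, sort=True)
    n_classes = len(uniques)
    class_sizes = np.bincount(codes, minlength=n_classes)
    observed = np.bincount(codes, weights=labels, minlength=n_classes) / class_sizes

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_classes, dtype=np.int64)
    lab = labels.astype(np.float64)
    for _ in range(n_perm):
        shuffled = rng.permutation(lab)
        prop = np.bincount(codes, weights=shuffled, minlength=n_classes) / class_sizes
        exceed += prop > observed
    if smoothed:
        pvals = (exceed + 1) / (n_perm + 1)
    else:
        pvals = exceed / n_perm
    return pd.DataFrame({
        "function_class": uniques,
        "n_records": class_sizes,
        "n_significant": np.bincount(codes, weights=labels,
                                     minlength=n_classes).astype(int),
        "observed_proportion": observed,
        "p": pvals,
    })
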