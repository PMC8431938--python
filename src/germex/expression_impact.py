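"""Gene-expression consequences of carried variants.

Tumor expression is first converted to a within-cancer-type percentile with
the right-continuous empirical CDF, so the downstream regression is
invariant to any monotone normalization of the raw matrix. Per gene with at
least three carriers, the percentile is regressed on carrier status plus
age, sex, tumor purity, two genotype principal components and cancer type
(one-hot, lexicographically first type as reference); the carrier
coefficient's two-sided p-values are BH-adjusted across tested genes and
tiered at FDR < 0.05 (significant) and 0.05 <= FDR < 0.15 (suggestive).
A bottom-quartile co-occurrence view breaks carrier observations down by
variant function class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stats_core
from .io import KEY_COLS

log = logging.getLogger(__name__)

FDR_SIGNIFICANT = 0.05
FDR_SUGGESTIVE = 0.15


def tier_of(fdr: float) -> str:
    if np.isnan(fdr):
        return "ns"
    if fdr < FDR_SIGNIFICANT:
        return "significant"
    if fdr < FDR_SUGGESTIVE:
        return "suggestive"
    return "ns"


def expression_percentiles(expression: pd.DataFrame,
                           samples: pd.DataFrame) -> pd.DataFrame:
    """Within gene x cancer-type ecdf percentile of each sample's expression.

    ``expression`` is genes x samples. The percentile of a value is the
    fraction of the stratum's values less than or equal to it (self
    inclusive), so ties share a percentile and the stratum maximum is
    exactly 1. Returns a long frame (sample_id, gene, cancer_type, raw,
    percentile); samples absent from the metadata are skipped.
    """
    meta = samples.set_index("sample_id")["cancer_type"]
    common = [s for s in expression.columns if s in meta.index]
    skipped = set(expression.columns) - set(common)
    if skipped:
        log.info("expression matrix: %d samples lack metadata, skipped", len(skipped))
    long = (expression[common]
            .reset_index()
            .melt(id_vars="gene", var_name="sample_id", value_name="raw"))
    long = long.dropna(subset=["raw"])
    long["cancer_type"] = long["sample_id"].map(meta)
    # fraction of stratum values <= own value == max-rank / stratum size
    grp = long.groupby(["gene", "cancer_type"])["raw"]
    long["percentile"] = grp.rank(method="max") / grp.transform("size")
    return long[["sample_id", "gene", "cancer_type", "raw", "percentile"]]


def _design_matrix(df: pd.DataFrame):
    """Carrier + covariate design with intercept and cancer-type one-hots."""
    cols = {"intercept": np.ones(len(df)), "carrier": df["carrier"].to_numpy(float),
            "age": df["age"].to_numpy(float),
            "sex_male": (df["sex"] == "male").to_numpy(float),
            "tumor_purity": df["tumor_purity"].to_numpy(float),
            "pc1": df["pc1"].to_numpy(float), "pc2": df["pc2"].to_numpy(float)}
    types = sorted(df["cancer_type"].unique())
    for t in types[1:]:  # first type is the reference level
        cols[f"cancer_type_{t}"] = (df["cancer_type"] == t).to_numpy(float)
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names


def fit_variant_expression_model(percentiles: pd.DataFrame,
                                 carriers: pd.DataFrame,
                                 samples: pd.DataFrame,
                                 min_carriers: int = 3) -> pd.DataFrame:
    """Per-gene OLS of expression percentile on carrier status + covariates.

    ``carriers`` has columns (sample_id, gene), one row per carrier of any
    P/LP variant in that gene (multiple variants pool into one indicator).
    Samples lacking any required covariate or the gene's expression are
    dropped. Genes with fewer than ``min_carriers`` carriers (after
    dropping) are not tested; collinear designs are skipped with a log
    entry. Returns a frame (gene, n_carriers, beta_variant, p, fdr, tier).
    """
    covars = samples.set_index("sample_id")[
        ["age", "sex", "cancer_type", "tumor_purity", "pc1", "pc2"]]
    carrier_sets = carriers.groupby("gene")["sample_id"].agg(set)
    rows = []
    for gene in sorted(carrier_sets.index):
        sub = percentiles.loc[percentiles["gene"] == gene,
                              ["sample_id", "percentile"]].copy()
        if sub.empty:
            continue
        sub = sub.join(covars, on="sample_id")
        sub = sub.dropna(subset=["age", "tumor_purity", "pc1", "pc2", "sex",
                                 "cancer_type"])
        sub["carrier"] = sub["sample_id"].isin(carrier_sets[gene]).astype(int)
        n_car = int(sub["carrier"].sum())
        if n_car < min_carriers:
            continue
        X, names = _design_matrix(sub)
        try:
            fit = stats_core.ols_fit(X, sub["percentile"].to_numpy(), names)
        except stats_core.SingularDesignError as exc:
            log.warning("gene %s skipped: %s", gene, exc)
            continue
        except stats_core.InsufficientDataError:
            continue
        beta, _, p = fit.coef("carrier")
        rows.append({"gene": gene, "n_carriers": n_car,
                     "beta_variant": beta, "p": p})
    res = pd.DataFrame(rows, columns=["gene", "n_carriers", "beta_variant", "p"])
    if len(res):
        usable = ~res["p"].isna()
        fdr = np.full(len(res), np.nan)
        fdr[usable.to_numpy()] = stats_core.bh_adjust(res.loc[usable, "p"].tolist())
        res["fdr"] = fdr
    else:
        res["fdr"] = []
    res["tier"] = [tier_of(f) for f in res["fdr"]]
    return res


def quartile_cooccurrence(percentiles: pd.DataFrame, calls: pd.DataFrame,
                          variants: pd.DataFrame, quartile: float = 0.25):
    """Bottom-quartile expression co-occurrence by variant function class.

    Joins each carrier call to the carrier's percentile for the variant's
    gene; per function class reports how many carrier-variant observations
    fall at or below the quartile boundary (inclusive). Observations with
    no expression value are excluded from the denominator. Returns
    ``(per_class, bottom_observations)``.
    """
    vmeta = variants.copy()
    vmeta["key"] = _vkey(vmeta)
    cc = calls.copy()
    cc["key"] = _vkey(cc)
    cc = cc.merge(vmeta[["key", "gene", "function_class"]].drop_duplicates("key"),
                  on="key", how="left")
    pct = percentiles.set_index(["sample_id", "gene"])["percentile"]
    idx = pd.MultiIndex.from_frame(cc[["sample_id", "gene"]])
    cc["percentile"] = pct.reindex(idx).to_numpy()
    cc = cc.dropna(subset=["percentile"])
    cc["bottom_quartile"] = cc["percentile"] <= quartile
    per_class = (cc.groupby("function_class")
                 .agg(n_observations=("bottom_quartile", "size"),
                      n_bottom=("bottom_quartile", "sum"))
                 .reset_index())
    per_class["fraction"] = per_class["n_bottom"] / per_class["n_observations"]
    bottom = cc[cc["bottom_quartile"]][
        ["key", "gene", "function_class", "sample_id", "percentile"]].copy()
    return per_class, bottom


def _vkey(df: pd.DataFrame) -> pd.Series:
    return (df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + df["ref"] + ":" + df["alt"])
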