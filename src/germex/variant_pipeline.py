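"""Variant filtering cascade, non-cancer triage and carrier-frequency summaries.

The cascade mirrors clinical germline practice in a tumor/normal cohort:

1. read-support filter — a call must show >= 5 alternate reads and >= 0.2
   variant allele fraction in BOTH the tumor and the normal sequencing data;
2. a permissive recall path for the 34 non-cancer ACMG secondary-findings
   genes (alt reads >= 5 in either tissue, no VAF clause), unioned in;
3. non-cancer triage — variants are dropped when the gene sits on the
   cancer-predisposition list or any ClinVar trait string looks
   cancer-related ("tumor", "cancer", "neoplasia", or a token ending in
   "-oma" that is not on the benign exception list);
4. selection of pathogenic / likely pathogenic (P/LP) classifications.

Summaries report person-level carrier frequencies overall, per ancestry, per
gene and per inheritance mode, flag variants whose carriers all belong to a
single ancestry, and compare cohort allele frequencies against a
gnomAD-style reference table (per-variant Fisher test with BH adjustment,
per-population Pearson correlation of matched variant frequencies).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core
from .io import KEY_COLS, load_gene_list

CANCER_TERMS = ("tumor", "cancer", "neoplasia")

#: Cohort ancestry -> reference populations whose alleles are pooled.
#: European compares against the union of Finnish and non-Finnish Europeans.
DEFAULT_POPULATION_MAP = {
    "EUR": ("NFE", "FIN"),
    "AFR": ("AFR",),
    "EAS": ("EAS",),
    "SAS": ("SAS",),
    "AMR_LATINX": ("AMR",),
}

_TOKEN_RE = re.compile(r"[a-z]+")


class ReferentialIntegrityError(KeyError):
    """A call references a sample or variant absent from its table."""


def _vkey(df: pd.DataFrame) -> pd.Series:
    return (df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + df["ref"] + ":" + df["alt"])


def filter_read_support(calls: pd.DataFrame, min_alt: int = 5,
                        min_vaf: float = 0.2):
    """Keep calls with sufficient alternate-read support in both tissues.

    Returns ``(retained, rejected)``; ``rejected`` carries a ``reason``
    column. Thresholds are inclusive; a zero total in either tissue rejects
    the call.
    """
    reasons = []
    for row in calls.itertuples(index=False):
        reason = None
        for tissue, alt, total in (("tumor", row.tumor_alt, row.tumor_total),
                                   ("normal", row.normal_alt, row.normal_total)):
            if total == 0:
                reason = f"{tissue}_zero_depth"
                break
            if alt < min_alt:
                reason = f"{tissue}_alt_below_{min_alt}"
                break
            if alt / total < min_vaf:
                reason = f"{tissue}_vaf_below_{min_vaf}"
                break
        reasons.append(reason)
    reasons = pd.Series(reasons, index=calls.index, dtype=object)
    retained = calls[reasons.isna()].copy()
    rejected = calls[reasons.notna()].copy()
    rejected["reason"] = reasons[reasons.notna()]
    return retained, rejected


def filter_acmg_recall(calls: pd.DataFrame, variants: pd.DataFrame,
                       acmg_noncancer_genes=None, min_alt: int = 5) -> pd.DataFrame:
    """Permissive recall of calls in the non-cancer ACMG genes.

    For variants in the listed genes only, a call is recalled when it has
    >= ``min_alt`` alternate reads in tumor OR normal; no VAF requirement
    applies on this path.
    """
    if acmg_noncancer_genes is None:
        acmg_noncancer_genes = load_gene_list(default="acmg_noncancer_genes")
    if not acmg_noncancer_genes:
        raise ValueError("ACMG recall gene set must be non-empty")
    gene_of = dict(zip(_vkey(variants), variants["gene"]))
    keys = _vkey(calls)
    in_genes = keys.map(lambda k: gene_of.get(k) in acmg_noncancer_genes)
    enough = (calls["tumor_alt"] >= min_alt) | (calls["normal_alt"] >= min_alt)
    return calls[in_genes & enough].copy()


def union_calls(*call_sets: pd.DataFrame) -> pd.DataFrame:
    """Union of call tables, de-duplicated by (sample, variant key)."""
    merged = pd.concat(call_sets, ignore_index=True)
    return merged.drop_duplicates(subset=["sample_id"] + KEY_COLS).reset_index(drop=True)


def _trait_is_cancer_related(trait: str, cancer_terms, oma_exceptions) -> str | None:
    low = trait.lower()
    for term in cancer_terms:
        if term in low:
            return f"trait_contains_{term}"
    for token in _TOKEN_RE.findall(low):
        word = token[:-1] if token.endswith("omas") else token
        if word.endswith("oma") and word not in oma_exceptions:
            return f"trait_oma_token_{word}"
    return None


def filter_non_cancer(variants: pd.DataFrame, cancer_genes=None,
                      cancer_terms=CANCER_TERMS, oma_exceptions=None):
    """Drop cancer-related variants; returns ``(retained, excluded)``.

    A variant is excluded when its gene is on the cancer-predisposition
    list, or any ClinVar trait string contains a cancer term
    (case-insensitive), or any trait token ends in "-oma" and is not on the
    benign exception list. ``excluded`` carries a ``reason`` column.
    """
    if cancer_genes is None:
        cancer_genes = load_gene_list(default="cancer_genes")
    if oma_exceptions is None:
        oma_exceptions = load_gene_list(default="oma_exceptions")
    oma_exceptions = {w.lower() for w in oma_exceptions}
    reasons = []
    for row in variants.itertuples(index=False):
        if row.gene in cancer_genes:
            reasons.append("gene_on_cancer_list")
            continue
        reason = None
        for trait in str(row.traits).split("|"):
            if trait:
                reason = _trait_is_cancer_related(trait, cancer_terms, oma_exceptions)
                if reason:
                    break
        reasons.append(reason)
    reasons = pd.Series(reasons, index=variants.index, dtype=object)
    retained = variants[reasons.isna()].copy()
    excluded = variants[reasons.notna()].copy()
    excluded["reason"] = reasons[reasons.notna()]
    return retained, excluded


def select_nc_plp(variants: pd.DataFrame, calls: pd.DataFrame | None = None):
    """Retain pathogenic / likely pathogenic variants and count them.

    Returns ``(plp_variants, summary)`` where summary reports the unique
    variant count, affected gene count and (when calls are given) the
    sample-variant count restricted to the selected variants.
    """
    plp = variants[variants["classification"].isin(["P", "LP"])].copy()
    summary = {
        "n_unique_variants": int(_vkey(plp).nunique()) if len(plp) else 0,
        "n_genes": int(plp["gene"].nunique()) if len(plp) else 0,
    }
    if calls is not None:
        keys = set(_vkey(plp))
        sub = calls[_vkey(calls).isin(keys)]
        summary["n_sample_variants"] = int(len(sub.drop_duplicates(
            subset=["sample_id"] + KEY_COLS)))
    return plp, summary


@dataclass
class CohortSummary:
    """Carrier counts/frequencies overall, by ancestry, gene and inheritance."""

    overall: dict
    per_ancestry: pd.DataFrame
    per_gene: pd.DataFrame
    per_inheritance: pd.DataFrame
    variant_carriers: pd.DataFrame  # one row per (variant, sample) with ancestry
    ancestry_sizes: pd.Series = field(default=None)


def _check_referential(calls, variants, samples):
    vkeys = set(_vkey(variants))
    missing_v = set(_vkey(calls)) - vkeys
    if missing_v:
        raise ReferentialIntegrityError(
            f"calls reference {len(missing_v)} unknown variant keys, e.g. "
            f"{sorted(missing_v)[:3]}")
    missing_s = set(calls["sample_id"]) - set(samples["sample_id"])
    if missing_s:
        raise ReferentialIntegrityError(
            f"calls reference {len(missing_s)} unknown samples, e.g. "
            f"{sorted(missing_s)[:3]}")


def summarize_carriers(calls: pd.DataFrame, variants: pd.DataFrame,
                       samples: pd.DataFrame) -> CohortSummary:
    """Person-level carrier summary of the P/LP variant set.

    A carrier is a sample with at least one retained P/LP call and counts
    once regardless of how many variants it carries (homozygotes also count
    once). Frequencies divide by the ancestry-group size (overall: the full
    cohort) and are reported as percentages rounded to 2 decimals.
    """
    _check_referential(calls, variants, samples)
    n_cohort = len(samples)
    vmeta = variants.copy()
    vmeta["key"] = _vkey(vmeta)
    cc = calls.copy()
    cc["key"] = _vkey(cc)
    cc = cc.merge(vmeta[["key", "gene", "inheritance"]].drop_duplicates("key"),
                  on="key", how="left")
    cc = cc.merge(samples[["sample_id", "ancestry"]], on="sample_id", how="left")

    carriers = cc["sample_id"].unique()
    overall = {
        "carriers": int(len(carriers)),
        "n": int(n_cohort),
        "pct": _pct(len(carriers), n_cohort),
    }

    sizes = samples.groupby("ancestry")["sample_id"].nunique()
    by_anc = cc.groupby("ancestry")["sample_id"].nunique()
    var_by_anc = cc.groupby("ancestry")["key"].nunique()
    per_ancestry = pd.DataFrame({
        "n_samples": sizes,
        "carriers": by_anc.reindex(sizes.index, fill_value=0),
        "n_variants": var_by_anc.reindex(sizes.index, fill_value=0),
    }).fillna(0).astype(int)
    per_ancestry["pct"] = [
        _pct(c, n) for c, n in zip(per_ancestry["carriers"], per_ancestry["n_samples"])]
    per_ancestry = per_ancestry.reset_index()

    pg = cc.groupby("gene")["sample_id"].nunique().rename("carriers").reset_index()
    pg["pct"] = [_pct(c, n_cohort) for c in pg["carriers"]]
    pg_anc = (cc.groupby(["gene", "ancestry"])["sample_id"].nunique()
              .rename("carriers").reset_index())
    pg_anc["n_samples"] = pg_anc["ancestry"].map(sizes)
    pg_anc["pct"] = [_pct(c, n) for c, n in zip(pg_anc["carriers"], pg_anc["n_samples"])]
    per_gene = pg.merge(pg_anc, on="gene", how="left", suffixes=("", "_ancestry"))

    pi = cc.groupby("inheritance")["sample_id"].nunique().rename("carriers").reset_index()
    pi["pct"] = [_pct(c, n_cohort) for c in pi["carriers"]]

    return CohortSummary(
        overall=overall,
        per_ancestry=per_ancestry,
        per_gene=per_gene,
        per_inheritance=pi,
        variant_carriers=cc[["key", "sample_id", "ancestry", "gene",
                             "inheritance", "zygosity"]].copy(),
        ancestry_sizes=sizes,
    )


def _pct(num: int, den: int) -> float:
    if den == 0:
        return 0.0
    # round-half-up to 2 decimals for display parity with printed tables
    return float(np.floor(num / den * 10000 + 0.5) / 100)


def flag_population_specific(summary: CohortSummary, min_group_size: int = 100,
                             disqualifying=("MIX", "OTHER")) -> pd.DataFrame:
    """Variants whose carriers all belong to a single large ancestry group.

    Carriers of mixed/other ancestry disqualify exclusivity (admixture makes
    the claim unsafe); ancestry groups below ``min_group_size`` samples are
    not reported.
    """
    vc = summary.variant_carriers
    rows = []
    for key, grp in vc.groupby("key"):
        ancs = set(grp["ancestry"])
        if len(ancs) != 1:
            continue
        anc = next(iter(ancs))
        if anc in disqualifying:
            continue
        if summary.ancestry_sizes.get(anc, 0) < min_group_size:
            continue
        rows.append({"key": key, "gene": grp["gene"].iloc[0], "ancestry": anc,
                     "n_carriers": int(grp["sample_id"].nunique())})
    return pd.DataFrame(rows, columns=["key", "gene", "ancestry", "n_carriers"])


def compare_to_reference(summary: CohortSummary, reference: pd.DataFrame,
                         population_map=None):
    """Cohort-vs-reference allele-frequency comparison.

    Per variant and matched population, builds the 2x2 table
    ``[[cohort_AC, cohort_AN - cohort_AC], [ref_AC, ref_AN - ref_AC]]``
    with cohort AN = 2 * ancestry-group size (autosomal diploid), applies a
    two-sided Fisher exact test, and BH-adjusts across all variants tested
    within a population. Also reports the Pearson correlation of allele
    frequencies for variants present in both tables, per population.

    Returns ``(per_variant, per_population)`` data frames.
    """
    if population_map is None:
        population_map = DEFAULT_POPULATION_MAP
    vc = summary.variant_carriers
    sizes = summary.ancestry_sizes
    ref = reference.copy()
    ref["key"] = _vkey(ref)

    # cohort allele counts: het carriers contribute 1 allele, hom 2
    dose = vc["zygosity"].map({"het": 1, "hom": 2})
    ac = (vc.assign(dose=dose)
          .groupby(["key", "ancestry"])["dose"].sum().reset_index())

    rows = []
    for anc, pops in population_map.items():
        n_group = int(sizes.get(anc, 0))
        if n_group == 0:
            continue
        an_cohort = 2 * n_group
        sub = ac[ac["ancestry"] == anc]
        refp = (ref[ref["population"].isin(pops)]
                .groupby("key")[["allele_count", "allele_number"]].sum())
        for row in sub.itertuples(index=False):
            if row.key not in refp.index:
                continue
            rac, ran = (int(refp.loc[row.key, "allele_count"]),
                        int(refp.loc[row.key, "allele_number"]))
            cac = int(row.dose)
            p = stats_core.fisher_exact_two_sided(
                (cac, an_cohort - cac, rac, ran - rac))
            rows.append({"key": row.key, "ancestry": anc,
                         "cohort_ac": cac, "cohort_an": an_cohort,
                         "ref_ac": rac, "ref_an": ran, "p": p})
    per_variant = pd.DataFrame(
        rows, columns=["key", "ancestry", "cohort_ac", "cohort_an",
                       "ref_ac", "ref_an", "p"])
    if len(per_variant):
        fdr = np.full(len(per_variant), np.nan)
        for anc in per_variant["ancestry"].unique():
            mask = (per_variant["ancestry"] == anc).to_numpy()
            fdr[mask] = stats_core.bh_adjust(per_variant.loc[mask, "p"].tolist())
        per_variant["fdr"] = fdr
    else:
        per_variant["fdr"] = []

    pop_rows = []
    for anc in per_variant["ancestry"].unique() if len(per_variant) else []:
        sub = per_variant[per_variant["ancestry"] == anc]
        if len(sub) < 3:
            continue
        f_cohort = sub["cohort_ac"] / sub["cohort_an"]
        f_ref = sub["ref_ac"] / sub["ref_an"]
        try:
            r, p = stats_core.pearson(f_cohort.to_numpy(), f_ref.to_numpy())
        except ValueError:
            continue
        pop_rows.append({"ancestry": anc, "n_variants": len(sub),
                         "pearson_r": r, "p": p})
    per_population = pd.DataFrame(
        pop_rows, columns=["ancestry", "n_variants", "pearson_r", "p"])
    return per_variant, per_population
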