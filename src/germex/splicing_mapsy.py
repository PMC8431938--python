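"""Mis-splicing classification from massively parallel splicing assay counts.

A MaPSy-style assay reports, per variant and per context (in vitro / in
vivo), the counts of correctly spliced species attributable to the
reference and the alternate allele. A variant is classified as mis-splicing
when, in BOTH assays, the exact two-sided binomial test against a balanced
0.5 allelic split reaches BH-adjusted FDR < 0.05 AND the log2 allelic ratio
falls below -log2(1.5) (alternate allele depleted at least 1.5-fold among
correctly spliced products). Classified variants are then matched back to
cohort variants by exact genomic key.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import stats_core
from .io import KEY_COLS

RATIO_CUT = -math.log2(1.5)


class InputIntegrityError(ValueError):
    """Duplicate assay record for one variant, or mismatched genome builds."""


def allelic_ratio(ref_count: int, alt_count: int, pseudocount: float = 0.5) -> float:
    """log2((alt + pseudocount) / (ref + pseudocount)); negative = alt depleted."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    return math.log2((alt_count + pseudocount) / (ref_count + pseudocount))


def _binom_two_sided(alt: int, n: int) -> float:
    """Exact two-sided binomial p vs 0.5: min(1, 2 * min(lower, upper))."""
    if n == 0:
        return 1.0
    lower = stats_core.binom_lower_tail(alt, n)
    upper = 1.0 if alt == 0 else 1.0 - stats_core.binom_lower_tail(alt - 1, n)
    return min(1.0, 2.0 * min(lower, upper))


def call_mis_splicing(mapsy: pd.DataFrame, fdr_cut: float = 0.05,
                      ratio_cut: float = RATIO_CUT,
                      pseudocount: float = 0.5) -> pd.DataFrame:
    """Classify each variant from its in-vitro and in-vivo allelic counts.

    Per assay: exact two-sided binomial p of the alt/ref split vs 0.5, BH
    adjusted across variants WITHIN the assay. mis_splicing is true only
    when FDR < ``fdr_cut`` and ratio < ``ratio_cut`` hold in both assays; a
    variant missing either assay is called false and flagged incomplete.
    """
    df = mapsy.copy()
    df["key"] = _vkey(df)
    dup = df.duplicated(subset=["key", "assay"])
    if dup.any():
        bad = df.loc[dup, ["key", "assay"]].iloc[0]
        raise InputIntegrityError(
            f"duplicate {bad['assay']} record for variant {bad['key']}")
    builds = set(df["build"])
    if len(builds) > 1:
        raise InputIntegrityError(f"mixed genome builds in assay table: {sorted(builds)}")

    df["ratio"] = [allelic_ratio(r, a, pseudocount)
                   for r, a in zip(df["ref_count"], df["alt_count"])]
    df["p"] = [_binom_two_sided(int(a), int(r + a))
               for r, a in zip(df["ref_count"], df["alt_count"])]
    parts = []
    for assay, grp in df.groupby("assay"):
        grp = grp.copy()
        grp["fdr"] = stats_core.bh_adjust(grp["p"].tolist())
        parts.append(grp)
    df = pd.concat(parts, ignore_index=True)

    wide = df.pivot(index=["key"] + KEY_COLS + ["build"], columns="assay",
                    values=["ratio", "fdr"])
    out = pd.DataFrame(index=wide.index).reset_index()
    for assay, suffix in (("in_vitro", "vitro"), ("in_vivo", "vivo")):
        for field in ("ratio", "fdr"):
            col = (field, assay)
            out[f"{field}_{suffix}"] = (
                wide[col].to_numpy() if col in wide.columns else np.nan)
    out["incomplete"] = out[["fdr_vitro", "fdr_vivo"]].isna().any(axis=1)
    out["mis_splicing"] = (
        ~out["incomplete"]
        & (out["fdr_vitro"] < fdr_cut) & (out["ratio_vitro"] < ratio_cut)
        & (out["fdr_vivo"] < fdr_cut) & (out["ratio_vivo"] < ratio_cut))
    return out


def match_to_cohort(splicing_calls: pd.DataFrame, variants: pd.DataFrame,
                    calls: pd.DataFrame | None = None,
                    ase_calls: pd.DataFrame | None = None) -> pd.DataFrame:
    """Exact-key join of mis-splicing calls onto cohort variants.

    Requires identical genome-build tags on both sides (no silent liftover).
    When DNA calls are supplied, reports carrier counts per matched variant;
    when ASE calls are supplied, cross-references each carrier's ASE tier.
    """
    sb = set(splicing_calls["build"])
    vb = set(variants["build"])
    if sb and vb and sb != vb:
        raise InputIntegrityError(
            f"genome build mismatch: assay {sorted(sb)} vs cohort {sorted(vb)}")
    vmeta = variants.copy()
    vmeta["key"] = _vkey(vmeta)
    matched = splicing_calls.merge(
        vmeta[["key", "gene", "function_class", "classification"]].drop_duplicates("key"),
        on="key", how="inner")
    if calls is not None:
        cc = calls.copy()
        cc["key"] = _vkey(cc)
        n_carriers = cc.groupby("key")["sample_id"].nunique()
        matched["n_carriers"] = matched["key"].map(n_carriers).fillna(0).astype(int)
    if ase_calls is not None and len(ase_calls):
        ac = ase_calls.copy()
        if "key" not in ac.columns:
            ac["key"] = _vkey(ac)
        sig = ac[ac["tier"] == "significant"].groupby("key")["sample_id"].nunique()
        tested = ac.groupby("key")["sample_id"].nunique()
        matched["n_ase_tested"] = matched["key"].map(tested).fillna(0).astype(int)
        matched["n_ase_significant"] = matched["key"].map(sig).fillna(0).astype(int)
    return matched


def _vkey(df: pd.DataFrame) -> pd.Series:
    return (df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + df["ref"] + ":" + df["alt"])
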