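"""Synthetic cohort generator with planted ground truth.

Emits the seven tables the pipeline consumes — sample metadata, annotated
variants, DNA carrier calls, RNA allelic counts, a gene-expression matrix,
splicing-assay counts and a reference-population frequency table — from a
single seeded configuration, together with the planted truth (which
variants truly show allele-specific expression, lower their gene's
expression, mis-splice, are cancer-related, or are exclusive to one
ancestry). Every pipeline stage is therefore testable end-to-end with a
known answer and no external data.

Defaults mirror the cohort the pipeline is designed around: 10,389 samples
with the ancestry composition of a large pan-cancer study (8,279 European,
971 African, 652 East Asian, 305 Latinx/Native American, 50 South Asian,
106 mixed, 26 other), per-ancestry carrier rates near the observed carrier
frequencies, binomially sampled reads at a 0.5 heterozygous allele fraction
over negative-binomially distributed depths, a planted ASE alternate-allele
fraction of 0.1, a planted carrier expression-percentile shift of 0.3, and
a planted 1:3 mis-splicing allelic ratio at depth 300.

A separate registry of deterministic "headline fixtures" constructs inputs
whose summary statistics equal specific printed counts exactly, for
worked-example tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANCESTRY_DEFAULT_COUNTS = {
    "EUR": 8279, "AFR": 971, "EAS": 652, "AMR_LATINX": 305,
    "SAS": 50, "MIX": 106, "OTHER": 26,
}
_N_DEFAULT = sum(ANCESTRY_DEFAULT_COUNTS.values())  # 10,389

DEFAULT_CARRIER_RATES = {
    "EUR": 0.2675, "AFR": 0.1298, "EAS": 0.1166, "AMR_LATINX": 0.1508,
    "SAS": 0.10, "MIX": 0.15, "OTHER": 0.10,
}

DEFAULT_CLASS_MIX = {
    "missense": 0.45, "nonsense": 0.15, "frameshift": 0.10,
    "splice_site": 0.08, "synonymous": 0.03, "inframe": 0.05, "other": 0.14,
}

CANCER_TRAITS = ("Hereditary cancer-predisposing syndrome",
                 "Malignant tumor of breast", "Neoplasia of the colon",
                 "Melanoma, cutaneous malignant")
BENIGN_TRAITS = ("Myopathy, congenital", "Deafness, autosomal recessive",
                 "Glaucoma 1, open angle", "Metabolic disorder",
                 "Cardiomyopathy, dilated", "Spastic paraplegia")

REF_POP_SIZES = {  # individuals per reference population (exome-scale)
    "NFE": 51000, "FIN": 10800, "ASJ": 5000, "AFR": 8100,
    "EAS": 9000, "SAS": 15300, "AMR": 17200, "OTH": 3000,
}

_COHORT_TO_REF = {"EUR": "NFE", "AFR": "AFR", "EAS": "EAS", "SAS": "SAS",
                  "AMR_LATINX": "AMR", "MIX": "OTH", "OTHER": "OTH"}


class ConfigError(ValueError):
    """Invalid simulation configuration; message lists offending fields."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; the seed is mandatory."""

    seed: int
    n_samples: int = _N_DEFAULT
    ancestry_proportions: dict = field(
        default_factory=lambda: {k: v / _N_DEFAULT
                                 for k, v in ANCESTRY_DEFAULT_COUNTS.items()})
    n_variants: int = 800
    carrier_rates: dict = field(default_factory=lambda: dict(DEFAULT_CARRIER_RATES))
    fraction_cancer_related: float = 0.20
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    fraction_ase: float = 0.10          # variants with planted ASE
    ase_effect: float = 0.1             # alt-allele RNA fraction when planted
    fraction_expression_genes: float = 0.10  # genes with planted carrier shift
    expression_effect: float = 0.3      # carrier percentile shift (downward)
    expression_noise_sd: float = 0.1
    fraction_mis_splice: float = 0.15   # of assay-characterized variants
    mis_splice_alt_prob: float = 0.25   # 1:3 alt:ref among spliced species
    mapsy_fraction: float = 0.30        # variants characterized by the assay
    mapsy_depth: int = 300
    fraction_pop_exclusive: float = 0.05
    dna_depth_mean: float = 60.0
    dna_depth_dispersion: float = 5.0
    rna_depth_mean: float = 40.0
    rna_depth_dispersion: float = 5.0
    hom_rate: float = 0.002
    n_cancer_types: int = 8
    build: str = "GRCh37"

    def validate(self) -> None:
        problems = []
        if self.seed is None:
            problems.append("seed is mandatory")
        if self.n_samples < 1:
            problems.append("n_samples must be >= 1")
        if abs(sum(self.ancestry_proportions.values()) - 1.0) > 1e-9:
            problems.append("ancestry_proportions must sum to 1")
        for name, rate in self.carrier_rates.items():
            if not 0.0 <= rate <= 1.0:
                problems.append(f"carrier rate for {name} outside [0, 1]")
        for name in ("fraction_cancer_related", "fraction_ase",
                     "fraction_expression_genes", "fraction_mis_splice",
                     "mapsy_fraction", "fraction_pop_exclusive",
                     "ase_effect", "mis_splice_alt_prob", "hom_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} outside [0, 1]")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the tables."""

    variant_flags: pd.DataFrame   # key, cancer_related, ase, expression_lowering,
                                  # mis_splicing, exclusive_ancestry
    expression_genes: set         # genes with a planted carrier shift
    carriers: dict                # sample_id -> list of carried variant keys


def _neg_binom_depth(rng, mean, dispersion, size, floor=1):
    p = dispersion / (dispersion + mean)
    return np.maximum(rng.negative_binomial(dispersion, p, size=size), floor)


def _draw_key(rng, used):
    while True:
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(10_000, 50_000_000))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        key = (chrom, pos, ref, alt)
        if key not in used:
            used.add(key)
            return key


def generate_cohort(config: SimulationConfig):
    """Generate the seven input tables plus the planted :class:`GroundTruth`.

    Returns ``(tables, truth)`` where ``tables`` maps
    {"samples", "variants", "calls", "allele_counts", "expression",
    "mapsy", "reference_freq"} to data frames. Deterministic under the
    configured seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    from .io import load_gene_list  # local import to avoid cycle at import time

    # ---- samples -----------------------------------------------------
    ancestries = list(config.ancestry_proportions)
    probs = np.array([config.ancestry_proportions[a] for a in ancestries])
    n = config.n_samples
    sample_anc = rng.choice(ancestries, size=n, p=probs)
    samples = pd.DataFrame({
        "sample_id": [f"S{i:06d}" for i in range(n)],
        "ancestry": sample_anc,
        "age": np.clip(rng.normal(60, 10, n), 20, 90).round(1),
        "sex": rng.choice(["female", "male"], size=n),
        "cancer_type": rng.choice(
            [f"CT{j:02d}" for j in range(config.n_cancer_types)], size=n),
        "tumor_purity": rng.beta(5, 2, n).round(4),
        "pc1": rng.normal(0, 1, n).round(4),
        "pc2": rng.normal(0, 1, n).round(4),
    })

    # ---- variants ----------------------------------------------------
    m = config.n_variants
    n_cancer = int(round(m * config.fraction_cancer_related))
    cancer_pool = sorted(load_gene_list(default="cancer_genes"))
    n_nc_genes = max(1, int(round((m - n_cancer) / 2)))  # ~2 variants per gene
    nc_genes = [f"GENE{j:04d}" for j in range(n_nc_genes)]
    classes = list(config.class_mix)
    class_p = np.array([config.class_mix[c] for c in classes])
    class_p = class_p / class_p.sum()

    used_keys: set = set()
    rows = []
    for j in range(m):
        chrom, pos, ref, alt = _draw_key(rng, used_keys)
        cancer_related = j < n_cancer
        if cancer_related and rng.random() < 0.5:
            gene = str(rng.choice(cancer_pool))
            trait = str(rng.choice(BENIGN_TRAITS))
        elif cancer_related:
            gene = str(rng.choice(nc_genes))
            trait = str(rng.choice(CANCER_TRAITS))
        else:
            gene = str(rng.choice(nc_genes))
            trait = str(rng.choice(BENIGN_TRAITS))
        u = rng.random()
        classification = ("P" if u < 0.35 else "LP" if u < 0.70
                          else "VUS" if u < 0.90 else "prioritized_only")
        u_af = rng.random()
        if u_af < 0.05:
            af = np.nan
        elif u_af < 0.15:
            af = float(rng.uniform(0.001, 0.01))   # too common for ASE
        else:
            af = float(rng.uniform(1e-6, 5e-4))
        u_inh = rng.random()
        inheritance = "AR" if u_inh < 0.6 else "AD" if u_inh < 0.85 else "unknown"
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                     "build": config.build, "gene": gene,
                     "function_class": str(rng.choice(classes, p=class_p)),
                     "traits": trait, "classification": classification,
                     "inheritance": inheritance, "af": af,
                     "_cancer": cancer_related})
    variants = pd.DataFrame(rows)
    keys = (variants["chrom"] + ":" + variants["pos"].astype(str)
            + ":" + variants["ref"] + ":" + variants["alt"])
    variants["_key"] = keys

    # planted flags
    is_nc_plp = (~variants["_cancer"]) & variants["classification"].isin(["P", "LP"])
    nc_idx = variants.index[is_nc_plp].to_numpy()
    rare = variants["af"].isna() | (variants["af"] <= 5e-4)

    ase_flag = np.zeros(m, dtype=bool)
    cand = variants.index[is_nc_plp & rare].to_numpy()
    n_ase = int(round(len(cand) * config.fraction_ase))
    if n_ase:
        ase_flag[rng.choice(cand, size=n_ase, replace=False)] = True

    excl_anc = np.array([""] * m, dtype=object)
    large_groups = [a for a in ancestries if a not in ("MIX", "OTHER")]
    n_excl = int(round(len(nc_idx) * config.fraction_pop_exclusive))
    if n_excl:
        chosen = rng.choice(nc_idx, size=n_excl, replace=False)
        excl_anc[chosen] = rng.choice(large_groups, size=n_excl)
    variants["_ase"] = ase_flag
    variants["_exclusive"] = excl_anc

    nc_gene_names = variants.loc[is_nc_plp, "gene"].unique()
    n_expr = int(round(len(nc_gene_names) * config.fraction_expression_genes))
    expr_genes = set(rng.choice(nc_gene_names, size=n_expr, replace=False)) if n_expr else set()

    # ---- carrier assignment ------------------------------------------
    rates = samples["ancestry"].map(config.carrier_rates).to_numpy(float)
    is_carrier = rng.random(n) < rates
    carriers: dict[str, list[str]] = {}
    call_rows = []
    vkeys = variants["_key"].to_numpy()
    vexcl = variants["_exclusive"].to_numpy()
    eligible_by_anc = {
        anc: nc_idx[(vexcl[nc_idx] == "") | (vexcl[nc_idx] == anc)]
        for anc in ancestries}
    for i in np.flatnonzero(is_carrier):
        anc = samples.at[i, "ancestry"]
        pool = eligible_by_anc[anc]
        if len(pool) == 0:
            continue
        k = 1 + rng.poisson(0.15)
        picked = rng.choice(pool, size=min(k, len(pool)), replace=False)
        sid = samples.at[i, "sample_id"]
        carriers[sid] = [vkeys[j] for j in picked]
        for j in picked:
            call_rows.append((sid, j))
    # non-carrier noise calls on cancer-related / non-P-LP variants, so the
    # triage and classification filters have something to remove
    noise_idx = variants.index[~is_nc_plp].to_numpy()
    if len(noise_idx):
        n_noise = max(1, int(0.02 * n))
        noise_samples = rng.choice(n, size=n_noise, replace=False)
        for i in noise_samples:
            j = int(rng.choice(noise_idx))
            call_rows.append((samples.at[i, "sample_id"], j))

    zyg = np.where(rng.random(len(call_rows)) < config.hom_rate, "hom", "het")
    t_depth = _neg_binom_depth(rng, config.dna_depth_mean,
                               config.dna_depth_dispersion, len(call_rows))
    n_depth = _neg_binom_depth(rng, config.dna_depth_mean,
                               config.dna_depth_dispersion, len(call_rows))
    vaf = np.where(zyg == "hom", 0.98, 0.5)
    t_alt = rng.binomial(t_depth, vaf)
    n_alt = rng.binomial(n_depth, vaf)
    calls = pd.DataFrame({
        "sample_id": [s for s, _ in call_rows],
        "chrom": [variants.at[j, "chrom"] for _, j in call_rows],
        "pos": [variants.at[j, "pos"] for _, j in call_rows],
        "ref": [variants.at[j, "ref"] for _, j in call_rows],
        "alt": [variants.at[j, "alt"] for _, j in call_rows],
        "tumor_alt": t_alt, "tumor_total": t_depth,
        "normal_alt": n_alt, "normal_total": n_depth,
        "zygosity": zyg,
    })

    # ---- RNA allelic counts ------------------------------------------
    rna_rows = []
    for (sid, j), z in zip(call_rows, zyg):
        if z != "het" or not is_nc_plp[j]:
            continue
        n_sources = 1 + int(rng.random() < 0.25)
        pi = config.ase_effect if variants.at[j, "_ase"] else 0.5
        for s in range(n_sources):
            depth = int(_neg_binom_depth(rng, config.rna_depth_mean,
                                         config.rna_depth_dispersion, 1)[0])
            alt_reads = int(rng.binomial(depth, pi))
            rna_rows.append({
                "sample_id": sid, "chrom": variants.at[j, "chrom"],
                "pos": variants.at[j, "pos"], "ref": variants.at[j, "ref"],
                "alt": variants.at[j, "alt"], "source_id": f"bam{s}",
                "ref_count": depth - alt_reads, "alt_count": alt_reads})
    allele_counts = pd.DataFrame(
        rna_rows, columns=["sample_id", "chrom", "pos", "ref", "alt",
                           "source_id", "ref_count", "alt_count"])

    # ---- expression matrix -------------------------------------------
    genes = sorted(set(variants.loc[is_nc_plp, "gene"]))
    carrier_of_gene: dict[str, set] = {g: set() for g in genes}
    gene_of_idx = variants["gene"].to_dict()
    for (sid, j) in call_rows:
        if is_nc_plp[j]:
            g = gene_of_idx[j]
            if g in carrier_of_gene:
                carrier_of_gene[g].add(sid)
    expr = rng.random((len(genes), n))  # latent uniform scale
    sid_index = {s: i for i, s in enumerate(samples["sample_id"])}
    for gi, g in enumerate(genes):
        if g not in expr_genes:
            continue
        for sid in carrier_of_gene[g]:
            expr[gi, sid_index[sid]] = np.clip(
                0.5 - config.expression_effect
                + rng.normal(0, config.expression_noise_sd), 1e-4, 1 - 1e-4)
    expression = pd.DataFrame(expr.round(6), index=pd.Index(genes, name="gene"),
                              columns=samples["sample_id"])

    # ---- MaPSy counts ------------------------------------------------
    n_mapsy = int(round(m * config.mapsy_fraction))
    mapsy_idx = rng.choice(m, size=n_mapsy, replace=False) if n_mapsy else np.array([], int)
    mis_flag = np.zeros(m, dtype=bool)
    n_mis = int(round(n_mapsy * config.fraction_mis_splice))
    if n_mis:
        mis_flag[rng.choice(mapsy_idx, size=n_mis, replace=False)] = True
    mapsy_rows = []
    for j in mapsy_idx:
        pi = config.mis_splice_alt_prob if mis_flag[j] else 0.5
        for assay in ("in_vitro", "in_vivo"):
            alt_reads = int(rng.binomial(config.mapsy_depth, pi))
            mapsy_rows.append({
                "chrom": variants.at[j, "chrom"], "pos": variants.at[j, "pos"],
                "ref": variants.at[j, "ref"], "alt": variants.at[j, "alt"],
                "build": config.build, "assay": assay,
                "ref_count": config.mapsy_depth - alt_reads,
                "alt_count": alt_reads})
    mapsy = pd.DataFrame(mapsy_rows, columns=["chrom", "pos", "ref", "alt",
                                              "build", "assay",
                                              "ref_count", "alt_count"])
    variants["_mis_splicing"] = mis_flag

    # ---- reference frequencies ---------------------------------------
    anc_sizes = samples.groupby("ancestry")["sample_id"].nunique()
    carrier_counts = (calls.assign(
        key=calls["chrom"] + ":" + calls["pos"].astype(str) + ":"
        + calls["ref"] + ":" + calls["alt"])
        .merge(samples[["sample_id", "ancestry"]], on="sample_id")
        .groupby(["key", "ancestry"])["sample_id"].nunique())
    ref_rows = []
    for j in nc_idx:
        key = vkeys[j]
        for pop, size in REF_POP_SIZES.items():
            an = 2 * size
            matched = [a for a, p in _COHORT_TO_REF.items() if p == pop]
            freq = 0.0
            for a in matched:
                c = carrier_counts.get((key, a), 0)
                denom = 2 * int(anc_sizes.get(a, 0)) or 1
                freq = max(freq, c / denom)
            if vexcl[j] and _COHORT_TO_REF.get(vexcl[j]) != pop:
                freq = 0.0
            ac = int(rng.binomial(an, min(freq, 1.0)))
            ref_rows.append({"chrom": variants.at[j, "chrom"],
                             "pos": variants.at[j, "pos"],
                             "ref": variants.at[j, "ref"],
                             "alt": variants.at[j, "alt"],
                             "build": config.build, "population": pop,
                             "allele_count": ac, "allele_number": an})
    reference_freq = pd.DataFrame(
        ref_rows, columns=["chrom", "pos", "ref", "alt", "build",
                           "population", "allele_count", "allele_number"])

    truth = GroundTruth(
        variant_flags=pd.DataFrame({
            "key": variants["_key"],
            "cancer_related": variants["_cancer"],
            "ase": variants["_ase"],
            "expression_lowering": variants["gene"].isin(expr_genes) & is_nc_plp,
            "mis_splicing": variants["_mis_splicing"],
            "exclusive_ancestry": variants["_exclusive"],
        }),
        expression_genes=expr_genes,
        carriers=carriers,
    )
    variants = variants.drop(columns=["_cancer", "_key", "_ase",
                                      "_exclusive", "_mis_splicing"])
    tables = {"samples": samples, "variants": variants, "calls": calls,
              "allele_counts": allele_counts, "expression": expression,
              "mapsy": mapsy, "reference_freq": reference_freq}
    return tables, truth


# ---------------------------------------------------------------------------
# Headline fixtures: deterministic inputs reproducing specific printed counts
# ---------------------------------------------------------------------------

def _mk_samples(counts: dict) -> pd.DataFrame:
    rows = []
    i = 0
    for anc, k in counts.items():
        for _ in range(k):
            rows.append({"sample_id": f"S{i:06d}", "ancestry": anc,
                         "age": 60.0, "sex": "female", "cancer_type": "CT00",
                         "tumor_purity": 0.7, "pc1": 0.0, "pc2": 0.0})
            i += 1
    return pd.DataFrame(rows)


def _mk_variant(chrom, pos, gene, function_class="missense", inheritance="AR",
                classification="P", traits="Metabolic disorder", af=1e-5):
    return {"chrom": str(chrom), "pos": int(pos), "ref": "G", "alt": "A",
            "build": "GRCh37", "gene": gene, "function_class": function_class,
            "traits": traits, "classification": classification,
            "inheritance": inheritance, "af": af}


def _mk_call(sample_id, var, zygosity="het", alt=30, total=60):
    return {"sample_id": sample_id, "chrom": var["chrom"], "pos": var["pos"],
            "ref": var["ref"], "alt": var["alt"],
            "tumor_alt": alt, "tumor_total": total,
            "normal_alt": alt, "normal_total": total, "zygosity": zygosity}


def _fixture_carriers_overall():
    """10,389 samples, 2,505 carriers; AD/AR split 215/2,288 (+2 unknown)."""
    samples = _mk_samples(ANCESTRY_DEFAULT_COUNTS)
    v_ad = _mk_variant(1, 1000, "GENE_AD", inheritance="AD")
    v_ar = _mk_variant(2, 2000, "GENE_AR", inheritance="AR")
    v_unk = _mk_variant(3, 3000, "GENE_UNK", inheritance="unknown")
    variants = pd.DataFrame([v_ad, v_ar, v_unk])
    per_anc = {  # ancestry -> (AD carriers, AR carriers, unknown carriers)
        "EUR": (190, 2023, 2), "AFR": (10, 116, 0), "EAS": (8, 68, 0),
        "AMR_LATINX": (5, 41, 0), "MIX": (2, 40, 0),
    }
    by_anc = samples.groupby("ancestry")["sample_id"].agg(list)
    rows = []
    for anc, (n_ad, n_ar, n_unk) in per_anc.items():
        ids = by_anc[anc]
        cursor = 0
        for count, var in ((n_ad, v_ad), (n_ar, v_ar), (n_unk, v_unk)):
            for sid in ids[cursor:cursor + count]:
                rows.append(_mk_call(sid, var))
            cursor += count
    calls = pd.DataFrame(rows)
    return {"samples": samples, "variants": variants, "calls": calls}


def _fixture_spg7_eur():
    """SPG7 carriers: 100 European (of 8,279), one each LATINX/AFR/SAS."""
    counts = {"EUR": 8279, "AMR_LATINX": 305, "AFR": 971, "SAS": 50}
    samples = _mk_samples(counts)
    v = _mk_variant(16, 89620000, "SPG7", inheritance="AR",
                    traits="Spastic paraplegia 7")
    variants = pd.DataFrame([v])
    by_anc = samples.groupby("ancestry")["sample_id"].agg(list)
    rows = [_mk_call(sid, v) for sid in by_anc["EUR"][:100]]
    for anc in ("AMR_LATINX", "AFR", "SAS"):
        rows.append(_mk_call(by_anc[anc][0], v))
    calls = pd.DataFrame(rows)
    return {"samples": samples, "variants": variants, "calls": calls}


def _fixture_nonsense_quartile():
    """376 nonsense observations (137 bottom-quartile), 1,169 missense (271)."""
    spec_counts = (("nonsense", "GENE_NS", 376, 137, "4", 4000),
                   ("missense", "GENE_MS", 1169, 271, "5", 5000))
    n_samples = max(c[2] for c in spec_counts)
    samples = _mk_samples({"EUR": n_samples})
    ids = samples["sample_id"].tolist()
    var_rows, call_rows, pct_rows = [], [], []
    for fclass, gene, n_obs, n_bottom, chrom, pos in spec_counts:
        v = _mk_variant(chrom, pos, gene, function_class=fclass)
        var_rows.append(v)
        for i in range(n_obs):
            sid = ids[i]
            call_rows.append(_mk_call(sid, v))
            pct_rows.append({"sample_id": sid, "gene": gene,
                             "cancer_type": "CT00", "raw": 0.0,
                             "percentile": 0.20 if i < n_bottom else 0.80})
    return {"samples": samples, "variants": pd.DataFrame(var_rows),
            "calls": pd.DataFrame(call_rows),
            "percentiles": pd.DataFrame(pct_rows)}


def _fixture_ase_counts():
    """657 analysis-ready RNA records: 173 significant, 28 suggestive ASE.

    Significant records carry an extreme imbalance (alt = 0 of 30) whose
    lower-tail p survives BH at any rank here; suggestive records use
    alt = 9 of 30 (exact lower tail 0.0214), which lands the shared BH
    value at rank 201/657 in [0.05, 0.15); the remaining 456 are balanced.
    """
    samples = _mk_samples({"EUR": 657})
    ids = samples["sample_id"].tolist()
    var_rows, call_rows, rec_rows = [], [], []
    plan = [("sig", 173, 0, 30), ("sug", 28, 9, 21), ("null", 456, 15, 15)]
    i = 0
    for label, count, alt_reads, ref_reads in plan:
        for _ in range(count):
            gene = f"GENE_{label.upper()}{i % 60:02d}"
            v = _mk_variant(str(1 + i % 22), 10_000 + i, gene)
            var_rows.append(v)
            sid = ids[i]
            call_rows.append(_mk_call(sid, v))
            rec_rows.append({"sample_id": sid, "chrom": v["chrom"],
                             "pos": v["pos"], "ref": v["ref"], "alt": v["alt"],
                             "source_id": "bam0", "ref_count": ref_reads,
                             "alt_count": alt_reads})
            i += 1
    return {"samples": samples, "variants": pd.DataFrame(var_rows),
            "calls": pd.DataFrame(call_rows),
            "allele_counts": pd.DataFrame(rec_rows)}


def _fixture_nc_plp_counts():
    """753 unique P/LP variants in 363 genes; 2,920 sample-variants (4 hom)."""
    var_rows = []
    gene_i = 0
    # 27 genes x 3 variants + 336 genes x 2 variants = 753
    for n_per, n_genes in ((3, 27), (2, 336)):
        for _ in range(n_genes):
            gene = f"GENE{gene_i:04d}"
            for k in range(n_per):
                var_rows.append(_mk_variant(str(1 + gene_i % 22),
                                            100_000 + 10 * gene_i + k, gene))
            gene_i += 1
    # a few non-P/LP rows that selection must drop
    var_rows.append(_mk_variant("22", 99_000_001, "GENE_VUS", classification="VUS"))
    var_rows.append(_mk_variant("22", 99_000_002, "GENE_B", classification="B"))
    variants = pd.DataFrame(var_rows)
    plp = variants[variants["classification"].isin(["P", "LP"])].reset_index(drop=True)
    samples = _mk_samples({"EUR": 2505})
    ids = samples["sample_id"].tolist()
    call_rows = []
    for i in range(2505):  # every carrier gets one variant
        v = plp.iloc[i % len(plp)].to_dict()
        call_rows.append(_mk_call(ids[i], v))
    for i in range(415):   # 415 carriers get a second, distinct variant
        v = plp.iloc[(i + 400) % len(plp)].to_dict()
        if (i + 400) % len(plp) == i % len(plp):
            v = plp.iloc[(i + 401) % len(plp)].to_dict()
        call_rows.append(_mk_call(ids[i], v))
    calls = pd.DataFrame(call_rows).drop_duplicates(
        subset=["sample_id", "chrom", "pos", "ref", "alt"])
    assert len(calls) == 2920, len(calls)
    for i in range(4):
        calls.iloc[i, calls.columns.get_loc("zygosity")] = "hom"
    return {"samples": samples, "variants": variants, "calls": calls}


_FIXTURES = {
    "carriers_overall": _fixture_carriers_overall,
    "spg7_eur": _fixture_spg7_eur,
    "nonsense_quartile": _fixture_nonsense_quartile,
    "ase_counts": _fixture_ase_counts,
    "nc_plp_counts": _fixture_nc_plp_counts,
}


def generate_headline_fixture(name: str) -> dict:
    """Build a registered deterministic fixture by name.

    Returns a dict of input tables; raises ``KeyError`` listing the
    registered names when the name is unknown or empty.
    """
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; registered: {sorted(_FIXTURES)}")
    return _FIXTURES[name]()
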