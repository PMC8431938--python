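"""Readers and writers for the pipeline's tab-separated inputs and outputs.

Seven TSV inputs drive the pipeline: sample metadata, the annotated variant
table, per-sample DNA carrier calls, per-sample RNA allelic read counts, a
normalized gene-expression matrix (genes x samples), splicing-assay allelic
counts, and a reference-population allele count/number table. All tables are
plain UTF-8 TSV so they round-trip losslessly through pandas.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

KEY_COLS = ["chrom", "pos", "ref", "alt"]

VARIANT_COLS = KEY_COLS + ["build", "gene", "function_class", "traits",
                           "classification", "inheritance", "af"]
CALL_COLS = ["sample_id"] + KEY_COLS + ["tumor_alt", "tumor_total",
                                        "normal_alt", "normal_total", "zygosity"]
SAMPLE_COLS = ["sample_id", "ancestry", "age", "sex", "cancer_type",
               "tumor_purity", "pc1", "pc2"]
REFERENCE_COLS = KEY_COLS + ["build", "population", "allele_count", "allele_number"]
ALLELE_COUNT_COLS = ["sample_id"] + KEY_COLS + ["source_id", "ref_count", "alt_count"]
MAPSY_COLS = KEY_COLS + ["build", "assay", "ref_count", "alt_count"]

FUNCTION_CLASSES = ("nonsense", "missense", "frameshift", "splice_site",
                    "synonymous", "inframe", "other")
CLASSIFICATIONS = ("P", "LP", "VUS", "LB", "B", "prioritized_only")
INHERITANCE_MODES = ("AD", "AR", "unknown")
ANCESTRIES = ("EUR", "AFR", "EAS", "SAS", "AMR_LATINX", "MIX", "OTHER")
REF_POPULATIONS = ("ASJ", "NFE", "FIN", "AFR", "EAS", "SAS", "AMR", "OTH")

_INT_COLS = {
    "pos", "tumor_alt", "tumor_total", "normal_alt", "normal_total",
    "allele_count", "allele_number", "ref_count", "alt_count",
}
_FLOAT_COLS = {"af", "age", "tumor_purity", "pc1", "pc2"}


class TableFormatError(ValueError):
    """Raised when a TSV row violates the table schema; carries line number."""


def _read_tsv(path, columns, name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise FileNotFoundError(f"{name} table not readable at {path}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: {name} table missing columns {missing}")
    df = df[columns].copy()
    for col in columns:
        if col in _INT_COLS:
            _coerce(df, col, int, path, name)
        elif col in _FLOAT_COLS:
            _coerce(df, col, float, path, name, allow_empty=True)
    return df


def _coerce(df, col, typ, path, name, allow_empty=False):
    converted = []
    for i, raw in enumerate(df[col]):
        if raw == "" and allow_empty:
            converted.append(float("nan"))
            continue
        try:
            converted.append(typ(raw))
        except (TypeError, ValueError):
            # +2: header line plus 1-based numbering
            raise TableFormatError(
                f"{path}: line {i + 2}: column '{col}' of {name} table has "
                f"non-{typ.__name__} value {raw!r}"
            ) from None
    df[col] = converted


def read_variants(path) -> pd.DataFrame:
    df = _read_tsv(path, VARIANT_COLS, "variants")
    bad = df[df["ref"] == df["alt"]]
    if len(bad):
        raise TableFormatError(f"{path}: ref == alt at line {bad.index[0] + 2}")
    if (df["pos"] < 1).any():
        raise TableFormatError(f"{path}: position must be >= 1 (1-based)")
    unknown = set(df["classification"]) - set(CLASSIFICATIONS)
    if unknown:
        raise TableFormatError(f"{path}: unknown classification labels {sorted(unknown)}")
    return df


def read_calls(path) -> pd.DataFrame:
    df = _read_tsv(path, CALL_COLS, "calls")
    for tissue in ("tumor", "normal"):
        bad = df[df[f"{tissue}_alt"] > df[f"{tissue}_total"]]
        if len(bad):
            raise TableFormatError(
                f"{path}: line {bad.index[0] + 2}: {tissue} alt count exceeds total"
            )
    return df


def read_samples(path) -> pd.DataFrame:
    df = _read_tsv(path, SAMPLE_COLS, "samples")
    unknown = set(df["ancestry"]) - set(ANCESTRIES)
    if unknown:
        raise TableFormatError(f"{path}: unknown ancestry labels {sorted(unknown)}")
    return df


def read_reference_freq(path) -> pd.DataFrame:
    df = _read_tsv(path, REFERENCE_COLS, "reference_freq")
    bad = df[df["allele_count"] > df["allele_number"]]
    if len(bad):
        raise TableFormatError(f"{path}: allele_count exceeds allele_number")
    return df


def read_allele_counts(path) -> pd.DataFrame:
    return _read_tsv(path, ALLELE_COUNT_COLS, "allele_counts")


def read_mapsy(path) -> pd.DataFrame:
    df = _read_tsv(path, MAPSY_COLS, "mapsy")
    unknown = set(df["assay"]) - {"in_vitro", "in_vivo"}
    if unknown:
        raise TableFormatError(f"{path}: unknown assay labels {sorted(unknown)}")
    return df


def read_expression(path) -> pd.DataFrame:
    """Genes x samples normalized expression matrix (first column = gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def load_gene_list(path=None, default: str | None = None) -> set[str]:
    """Load a one-symbol-per-line gene list ('#' comments allowed).

    With ``path=None``, loads the packaged default named by ``default``
    ("cancer_genes", "acmg_noncancer_genes" or "oma_exceptions").
    """
    if path is None:
        if default is None:
            raise ValueError("either a path or a packaged default name is required")
        ref = importlib.resources.files("germex.data") / f"{default}.txt"
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    out = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def variant_key_frame(df: pd.DataFrame) -> pd.DataFrame:
    """The (chrom, pos, ref, alt) key columns of any keyed table."""
    return df[KEY_COLS]
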