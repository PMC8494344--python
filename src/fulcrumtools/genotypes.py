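"""Genotyping-sheet ingestion and integration.

Species identities come from molecular barcodes (e.g. SSU / ITS2 amplicon
alignments) performed outside this package; the results are entered by hand
in a genotyping sheet — one row per isolated specimen (S-label) with the
species name of the top alignment hit, a possible-new-species mark, and an
optional strain name. Two sheet schemas are supported: the *general* one,
and a *nematode* extension that adds proliferation and per-marker genotype
columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._tableio import write_table
from .config import ProcessingConfig
from .errors import SchemaError
from .project_io import ProjectLayout

GENERAL_COLUMNS = ("project_id", "s_label", "species_id", "possible_new_sp", "strain_name")
NEMATODE_EXTRA_COLUMNS = ("proliferation", "its2_genotype", "ssu_genotype")

SCHEMAS = {
    "general": GENERAL_COLUMNS,
    "nematode": GENERAL_COLUMNS + NEMATODE_EXTRA_COLUMNS,
}


def read_genotypes(source, schema: str = "general") -> pd.DataFrame:
    """Read a genotyping sheet exported as CSV/TSV.

    The sheet must carry the schema's column names in its header. S-labels
    are normalized (trim, uppercase); a blank ``possible_new_sp`` means
    False and an entered ``1`` means True.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown genotyping schema {schema!r}")
    sep = "\t" if str(source).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(source, dtype=str, sep=sep, keep_default_na=False)
    if len(df.columns) != len(set(df.columns)):
        raise SchemaError("duplicate header names in genotyping sheet")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"genotyping sheet is missing required column(s): {', '.join(missing)}"
        )
    df = df.mask(df == "")
    df["s_label"] = df["s_label"].astype("string").str.strip().str.upper().astype(object)
    df["possible_new_sp"] = (
        df["possible_new_sp"].astype("string").str.strip().fillna("") == "1"
    ).astype(bool)
    return df


@dataclass
class GenotypeReport:
    """Cross-check of the genotyping sheet against the joined field data."""

    issues: pd.DataFrame  # issue, s_label
    sheet_only: set  # A: S-labels in the sheet but absent from the field data
    fulcrum_only: set  # B: S-labels in the field data but absent from the sheet

    @property
    def empty(self) -> bool:
        return self.issues.empty and not self.sheet_only and not self.fulcrum_only

    def to_text(self) -> str:
        lines = ["Genotype review", "=" * 15]
        lines.append(
            self.issues.to_string(index=False) if not self.issues.empty else "no sheet issues"
        )
        lines.append(f"in sheet only: {sorted(self.sheet_only)}")
        lines.append(f"in field data only: {sorted(self.fulcrum_only)}")
        return "\n".join(lines) + "\n"


def check_genotypes(
    genos: pd.DataFrame,
    joined: pd.DataFrame,
    schema: str = "general",
    config: ProcessingConfig | None = None,
) -> GenotypeReport:
    """Flag sheet anomalies and S-label disparities with the field data.

    Sheet anomalies: missing / misformatted / duplicated S-labels, missing
    species identification, missing strain name where a species was called,
    and (nematode schema) missing proliferation or ITS2 entries. Disparities
    are the two set differences between sheet and field-data S-labels.
    """
    config = config or ProcessingConfig()
    import re

    rx = re.compile(config.s_label_pattern)
    rows = []

    def add(issue: str, mask: pd.Series) -> None:
        for s in genos.loc[mask, "s_label"].fillna("(blank)"):
            rows.append({"issue": issue, "s_label": s})

    s = genos["s_label"]
    add("s_label_missing", s.isna())
    add("s_label_misformatted", s.notna() & ~s.fillna("").astype(str).str.match(rx))
    add("s_label_duplicated", s.notna() & s.duplicated(keep=False))
    add("species_id_missing", genos["species_id"].isna())
    add("strain_name_missing", genos["species_id"].notna() & genos["strain_name"].isna())
    if schema == "nematode":
        add("proliferation_missing", genos["proliferation"].isna())
        add("its2_genotype_missing", genos["its2_genotype"].isna())

    sheet_labels = set(s.dropna())
    fulcrum_labels = set(joined["s_label"].dropna()) if "s_label" in joined else set()
    return GenotypeReport(
        issues=pd.DataFrame(rows, columns=["issue", "s_label"]),
        sheet_only=sheet_labels - fulcrum_labels,
        fulcrum_only=fulcrum_labels - sheet_labels,
    )


def join_geno_fulc(
    genos: pd.DataFrame,
    joined: pd.DataFrame,
    layout: ProjectLayout | None = None,
) -> pd.DataFrame:
    """Left-join species identifications onto the joined field data.

    Row count is preserved: field rows without a genotype keep nulls. A
    duplicated S-label in the sheet contributes only its first occurrence
    (deterministic) and raises a per-row flag. When ``layout`` is given, the
    result is persisted to ``data/processed/genotypes`` as CSV plus a JSON
    sidecar of column types.
    """
    sheet = genos.copy()
    dup_labels = set(sheet.loc[sheet["s_label"].duplicated(keep=False), "s_label"].dropna())
    sheet = sheet[sheet["s_label"].notna()].drop_duplicates("s_label", keep="first")
    geno_cols = [c for c in sheet.columns if c != "s_label"]
    renamed = sheet.rename(columns={c: f"geno_{c}" if c in joined.columns else c for c in geno_cols})

    out = joined.merge(renamed, on="s_label", how="left")
    pns = out["possible_new_sp"].astype(object)
    out["possible_new_sp"] = pns.where(pns.notna(), False).astype(bool)
    out["flag_s_label_duplicated_in_sheet"] = (
        out["s_label"].map(lambda v: v in dup_labels if pd.notna(v) else False).astype(bool)
    )
    if len(out) != len(joined):
        raise AssertionError("genotype join changed row count")

    if layout is not None:
        write_table(out, layout.processed_genotypes_dir / "final_genotyped.csv")
    return out
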