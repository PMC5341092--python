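"""Merge covariate layers and category labels into the analysis table.

Staged eligibility filters, each feeding an auditable exclusion ledger:
duplicate-ID collapse, missing dN/dS (non-1-to-1 orthologue or dS-saturated
estimate), absence from the PPI network, missing knockout data, missing GO
biological-process data, and finally the classifier's category exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotype import (
    CATEGORY_EXCLUDED,
    CATEGORY_LETHALITY,
    CATEGORY_NO_DATA,
    CATEGORY_NONESSENTIAL,
    CATEGORY_SUBINFERTILITY,
)

ANALYSIS_CATEGORIES = (
    CATEGORY_SUBINFERTILITY,
    CATEGORY_LETHALITY,
    CATEGORY_NONESSENTIAL,
)


@dataclass
class ExclusionLedger:
    """Ordered (stage, reason, count, gene_ids) records."""

    entries: list = field(default_factory=list)
    notes: list = field(default_factory=list)  # informational, non-balancing

    def add(self, stage: str, reason: str, gene_ids):
        gene_ids = sorted(gene_ids)
        if gene_ids:
            self.entries.append(
                {"stage": stage, "reason": reason, "count": len(gene_ids),
                 "gene_ids": gene_ids}
            )

    def note(self, stage: str, reason: str, gene_ids):
        gene_ids = sorted(gene_ids)
        if gene_ids:
            self.notes.append(
                {"stage": stage, "reason": reason, "count": len(gene_ids),
                 "gene_ids": gene_ids}
            )

    @property
    def total(self) -> int:
        """Genes removed from the universe (notes do not count)."""
        return sum(e["count"] for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = self.entries + self.notes
        if not rows:
            return pd.DataFrame(columns=["stage", "reason", "count", "gene_ids"])
        df = pd.DataFrame(rows)
        df["gene_ids"] = df["gene_ids"].map(lambda g: "|".join(g))
        return df


def load_ortholog_rates(path, ledger: ExclusionLedger | None = None):
    """Read a gene-level substitution-rate TSV, keeping usable estimates.

    Rows are kept when ``homology_type`` is a 1-to-1 orthologue and the
    estimate is not masked for dS saturation.  Malformed numeric rows are
    rejected with a warning count in the ledger.
    """
    import warnings

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "homology_type", "dn", "ds", "dnds", "masked"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rates table missing columns: {sorted(missing)}")

    bad_numeric = []
    for col in ("dn", "ds", "dnds"):
        converted = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad_numeric.extend(df.loc[converted.isna(), "gene_id"].tolist())
        df[col] = converted
    bad_numeric = set(bad_numeric)
    if bad_numeric:
        warnings.warn(f"{len(bad_numeric)} rate rows with malformed numerics")

    one2one = df["homology_type"].isin(["1-to-1", "ortholog_one2one"])
    unmasked = ~df["masked"].str.lower().isin(["true", "1", "yes"])
    usable = one2one & unmasked & ~df["gene_id"].isin(bad_numeric)

    if ledger is not None:
        ledger.add("rates", "no 1-to-1 dN/dS estimate",
                   df.loc[~one2one, "gene_id"])
        ledger.add("rates", "dS-saturated (masked) estimate",
                   df.loc[one2one & ~unmasked, "gene_id"])
        ledger.add("rates", "malformed rate value", bad_numeric)

    out = df.loc[usable, ["gene_id", "dn", "ds", "dnds"]].copy()
    if "chromosome" in df.columns:
        out["chromosome"] = df.loc[usable, "chromosome"].values
    return out.set_index("gene_id")


def assemble(rates: pd.DataFrame, degrees: pd.DataFrame, tau: pd.Series,
             multifun: pd.DataFrame, categories: pd.DataFrame,
             gene_universe=None):
    """Inner-join all layers into the final per-gene analysis table.

    Returns ``(records, ledger)``; ``records`` holds only genes assigned to
    one of the three analysis categories with every covariate present.
    Duplicate gene ids within a layer collapse to the first occurrence by
    sorted id.
    """
    ledger = ExclusionLedger()

    def dedup(frame, stage):
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()]
            ledger.note(stage, "duplicate id collapsed", set(dup))
            frame = frame[~frame.index.duplicated(keep="first")]
        return frame

    rates = dedup(rates.sort_index(), "rates")
    degrees = dedup(degrees.sort_index(), "network")
    tau = tau[~tau.index.duplicated(keep="first")].sort_index()
    multifun = dedup(multifun.sort_index(), "go")
    categories = dedup(categories.sort_index(), "phenotype")

    if gene_universe is None:
        universe = set(rates.index) | set(degrees.index) | set(tau.index) \
            | set(multifun.index) | set(categories.index)
    else:
        universe = set(gene_universe)
    universe = pd.Index(sorted(universe))

    present = pd.Series(True, index=universe)

    stages = [
        ("rates", "no dN/dS estimate available", rates.index),
        ("network", "not contained in the PPI network", degrees.index),
        ("phenotype", "lack of murine KO data",
         categories.index[categories["category"] != CATEGORY_NO_DATA]),
        ("go", "lacking GO biological process data", multifun.index),
        ("tau", "tau undefined (no expression)", tau.index),
    ]
    for stage, reason, idx in stages:
        lost = present.index[present & ~present.index.isin(idx)]
        ledger.add(stage, reason, lost)
        present[lost] = False

    # category-level exclusions, attributed per classifier reason
    cat = categories.reindex(present.index[present])
    for reason in cat["exclusion_reason"].dropna().unique():
        if reason == "no_phenotype_data":
            continue
        lost = cat.index[(cat["category"] == CATEGORY_EXCLUDED)
                         & (cat["exclusion_reason"] == reason)]
        ledger.add("category", reason, lost)
        present[lost] = False

    keep = present.index[present]
    records = pd.DataFrame(index=keep)
    records["category"] = categories.loc[keep, "category"]
    records["dn"] = rates.loc[keep, "dn"]
    records["ds"] = rates.loc[keep, "ds"]
    records["dnds"] = rates.loc[keep, "dnds"]
    records["degree"] = degrees.loc[keep, "degree"].astype(int)
    records["tau"] = tau.loc[keep]
    records["multifunctionality"] = multifun.loc[
        keep, "multifunctionality"].astype(int)
    if "immunity" in multifun.columns:
        records["immunity"] = multifun.loc[keep, "immunity"].astype(bool)
    if "chromosome" in rates.columns:
        records["x_linked"] = rates.loc[keep, "chromosome"].eq("X")
    records.index.name = "gene_id"

    if len(records) + ledger.total != len(universe):  # pragma: no cover
        raise AssertionError("ledger counts do not balance the universe")
    return records, ledger
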