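"""Reading, validation, QC filtering and harmonization of GWAS summary statistics.

The interchange object is a plain :class:`pandas.DataFrame` with the canonical
columns ``SNP CHR BP A1 A2 BETA SE P N INFO FRQ`` (and a derived ``Z``),
wrapped lightly by :class:`SumstatsTable` for validation. Effect sizes are
kept in standardized (per-SD) units internally: :func:`standardize` converts
per-allele effects using beta = z / sqrt(N), se = 1 / sqrt(N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "SumstatsTable",
    "TraitMeta",
    "read_sumstats",
    "qc_filter",
    "effective_n",
    "harmonize_panels",
    "power_gate",
    "standardize",
]

MANDATORY = ["SNP", "A1", "A2", "BETA", "SE", "P", "N"]
PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class TraitMeta:
    """Per-GWAS metadata used by the power screen."""

    name: str
    is_binary: bool = False
    n_cases: int | None = None
    n_controls: int | None = None
    reported_h2: float | None = None
    h2_z: float | None = None

    def __post_init__(self) -> None:
        if self.is_binary and (not self.n_cases or not self.n_controls):
            raise ValueError(f"binary trait {self.name!r} needs case and control counts")

    @property
    def effective_n(self) -> float:
        if not self.is_binary:
            raise ValueError("effective N is defined for binary traits")
        return effective_n(self.n_cases, self.n_controls)


class SumstatsTable:
    """Validated per-SNP association records for one trait.

    Thin wrapper over a DataFrame; most pipeline code operates on ``.df``
    directly. Construction enforces the row invariants (positive SE, p in
    (0, 1], distinct alleles, unique SNP ids) by *dropping* violating rows
    with a logged count, matching how summary files are cleaned in practice.
    """

    def __init__(self, df: pd.DataFrame, name: str = "trait", validate: bool = True):
        self.name = name
        if validate:
            df = self._clean(df)
        self.df = df.reset_index(drop=True)

    @staticmethod
    def _clean(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in MANDATORY if c not in df.columns]
        if missing:
            raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
        df = df.copy()
        for col in ["BETA", "SE", "P", "N", "INFO", "FRQ", "BP", "CHR"]:
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="coerce")
        df["A1"] = df["A1"].astype(str).str.upper()
        df["A2"] = df["A2"].astype(str).str.upper()
        n0 = len(df)
        numeric = ["BETA", "SE", "P", "N"]
        ok = df[numeric].notna().all(axis=1)
        ok &= df["SE"] > 0
        ok &= (df["P"] > 0) & (df["P"] <= 1)
        ok &= df["A1"] != df["A2"]
        ok &= ~df["SNP"].duplicated(keep="first")
        dropped = n0 - int(ok.sum())
        if dropped:
            logger.info("dropped %d malformed row(s) of %d", dropped, n0)
        df = df.loc[ok].copy()
        if len(df) == 0:
            raise ValueError("no rows survive validation")
        df["Z"] = df["BETA"] / df["SE"]
        return df

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "SumstatsTable":
        return SumstatsTable(self.df.copy(), name=self.name, validate=False)


def read_sumstats(path, column_map: dict[str, str] | None = None,
                  name: str | None = None, or_to_beta: bool = False) -> SumstatsTable:
    """Read a summary-statistics TSV into a validated :class:`SumstatsTable`.

    ``column_map`` maps canonical names to file column names (e.g.
    ``{"BETA": "b", "P": "pval"}``); unmapped canonical columns are looked up
    under their own names. With ``or_to_beta``, the mapped BETA column is
    interpreted as an odds ratio and log-transformed.
    """
    df = pd.read_csv(path, sep=r"\s+|\t|,", engine="python")
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        missing = [v for v in column_map.values() if v not in df.columns]
        if missing:
            raise ValueError(f"mapped column(s) not in file: {', '.join(missing)}")
        df = df.rename(columns=rename)
    if or_to_beta:
        df["BETA"] = np.log(pd.to_numeric(df["BETA"], errors="coerce"))
    if name is None:
        name = str(path)
    return SumstatsTable(df, name=name)


def standardize(t: SumstatsTable) -> SumstatsTable:
    """Convert effects to per-SD units: beta = Z / sqrt(N), se = 1 / sqrt(N).

    This discards the per-allele scale (which depends on allele frequency)
    while preserving Z and P exactly.
    """
    df = t.df.copy()
    df["SE"] = 1.0 / np.sqrt(df["N"])
    df["BETA"] = df["Z"] * df["SE"]
    return SumstatsTable(df, name=t.name, validate=False)


def qc_filter(t: SumstatsTable, info_min: float = 0.9, maf_min: float = 0.01) -> SumstatsTable:
    """Standard marker QC: imputation INFO > ``info_min``, MAF > ``maf_min``.

    Strict inequalities. Traits lacking an INFO or FRQ column skip that
    filter with a warning.
    """
    df = t.df
    keep = pd.Series(True, index=df.index)
    if "INFO" in df.columns and df["INFO"].notna().any():
        keep &= df["INFO"] > info_min
    else:
        logger.warning("%s: no INFO column, skipping imputation-quality filter", t.name)
    if "FRQ" in df.columns and df["FRQ"].notna().any():
        maf = np.minimum(df["FRQ"], 1.0 - df["FRQ"])
        keep &= maf > maf_min
    else:
        logger.warning("%s: no FRQ column, skipping allele-frequency filter", t.name)
    removed = int((~keep).sum())
    if removed:
        logger.info("%s: QC removed %d of %d SNPs", t.name, removed, len(df))
    return SumstatsTable(df.loc[keep].copy(), name=t.name, validate=False)


def effective_n(n_cases: float, n_controls: float) -> float:
    """Effective sample size of a case/control GWAS: 4 / (1/cases + 1/controls)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def _allele_key(df: pd.DataFrame) -> pd.Series:
    return df["A1"] + "/" + df["A2"]


def harmonize_panels(tables: list[SumstatsTable]) -> list[SumstatsTable]:
    """Align several tables on their SNP intersection and a shared allele frame.

    The first table sets the effect-allele convention. For the others, rows
    whose alleles match swapped get their BETA (and Z, FRQ) flipped; rows with
    any other allele mismatch are dropped. Strand-ambiguous palindromic SNPs
    (A/T, C/G) are dropped everywhere. All returned tables carry the same
    SNPs in the same order.
    """
    if len(tables) < 2:
        raise ValueError("harmonization needs at least two tables")
    ref = tables[0].df
    common = ref["SNP"]
    for t in tables[1:]:
        common = common[common.isin(t.df["SNP"])]
    if len(common) == 0:
        raise ValueError("empty SNP intersection across tables")

    ref = ref.set_index("SNP").loc[common].reset_index()
    pal = [(a, b) in PALINDROMES for a, b in zip(ref["A1"], ref["A2"])]
    pal = np.array(pal)
    if pal.any():
        logger.info("dropping %d palindromic SNP(s)", int(pal.sum()))
    keep_snps = ref.loc[~pal, "SNP"]
    ref = ref.set_index("SNP").loc[keep_snps]

    aligned = []
    for t in tables[1:]:
        df = t.df.set_index("SNP").loc[keep_snps]
        same = (df["A1"].values == ref["A1"].values) & (df["A2"].values == ref["A2"].values)
        swapped = (df["A1"].values == ref["A2"].values) & (df["A2"].values == ref["A1"].values)
        own_pal = np.array([(a, b) in PALINDROMES for a, b in zip(df["A1"], df["A2"])])
        ok = (same | swapped) & ~own_pal
        mism = int((~ok).sum())
        if mism:
            logger.info("%s: dropping %d allele-mismatched/palindromic SNP(s)", t.name, mism)
        df = df.copy()
        flip = swapped & ok
        df.loc[flip, "BETA"] = -df.loc[flip, "BETA"]
        if "Z" in df.columns:
            df.loc[flip, "Z"] = -df.loc[flip, "Z"]
        if "FRQ" in df.columns:
            df.loc[flip, "FRQ"] = 1.0 - df.loc[flip, "FRQ"]
        df.loc[flip, "A1"] = ref.loc[flip, "A1"]
        df.loc[flip, "A2"] = ref.loc[flip, "A2"]
        aligned.append((df, ok))

    # restrict every table (incl. reference) to rows every panel could align
    all_ok = np.logical_and.reduce([ok for _, ok in aligned]) if aligned else None
    final_snps = keep_snps[all_ok]
    if len(final_snps) == 0:
        raise ValueError("no SNPs survive harmonization")
    out = [SumstatsTable(ref.loc[final_snps].reset_index(), name=tables[0].name,
                         validate=False)]
    for (df, _), t in zip(aligned, tables[1:]):
        out.append(SumstatsTable(df.loc[final_snps].reset_index(), name=t.name,
                                 validate=False))
    return out


def power_gate(meta: TraitMeta, h2_min: float = 0.05, z_min: float = 2.0) -> dict:
    """Advisory statistical-power screen: SNP-h2 >= 5% and h2 z-score >= 2.

    Returns a report dict; it never raises, because published analyses retain
    individually informative traits (e.g. a very large GWAS with h2 just
    under the cut) at the analyst's discretion.
    """
    failures = []
    if meta.reported_h2 is None or meta.h2_z is None:
        failures.append("missing h2 or h2 z-score")
        ok = False
    else:
        if meta.reported_h2 < h2_min:
            failures.append(f"h2 {meta.reported_h2:.3f} below {h2_min}")
        if meta.h2_z < z_min:
            failures.append(f"h2 z-score {meta.h2_z:.2f} below {z_min}")
        ok = not failures
    return {"trait": meta.name, "pass": ok, "failures": failures}
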