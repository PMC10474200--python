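"""Gene signatures from differential-expression tables.

A DEG table has one row per gene with a signed log2 fold change, a raw
p-value and a Benjamini-Hochberg adjusted FDR.  A signature is the pair of
up- and down-regulated gene lists passing a symmetric |log2FC| cut and an
FDR cut; an oversized signature can be trimmed by automatically raising
the fold-change cut in 0.01 increments until it fits a target size
(causal-reasoning engines work best with query lists of ~1000 genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEG_COLUMNS = ("gene", "log2fc", "pvalue", "fdr")


def normalize_symbol(gene: str) -> str:
    return str(gene).strip().upper()


def validate_deg_table(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize gene symbols and enforce the DEG-table contract."""
    missing = [c for c in DEG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    table = table.copy()
    table["gene"] = table["gene"].map(normalize_symbol)
    if (table["gene"] == "").any():
        raise ValueError("empty gene symbol in DEG table")
    dupes = table["gene"][table["gene"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate gene symbols: {sorted(dupes)[:5]}")
    for col in ("pvalue", "fdr"):
        vals = table[col].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    return table


def read_deg_table(path: str | Path) -> pd.DataFrame:
    return validate_deg_table(pd.read_csv(path, sep="\t"))


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def compute_deg_table(
    matrix: pd.DataFrame,
    baseline: list[str],
    post: list[str],
) -> pd.DataFrame:
    """Paired differential expression on a log2 expression matrix.

    ``matrix`` holds genes on rows and samples on columns; ``baseline``
    and ``post`` name paired columns in matching order.  Per gene, the
    log2 fold change is the mean paired difference and the p-value comes
    from a two-sided paired t-test; FDR is Benjamini-Hochberg across all
    genes.  Genes whose paired differences have zero variance get p = 1
    with a warning (the t statistic is undefined there).
    """
    if len(baseline) != len(post):
        raise ValueError("baseline and post sample lists differ in length")
    if len(baseline) < 2:
        raise ValueError("need at least 2 paired samples")
    for col in (*baseline, *post):
        if col not in matrix.columns:
            raise ValueError(f"sample column not in matrix: {col!r}")

    b = matrix[list(baseline)].to_numpy(dtype=float)
    a = matrix[list(post)].to_numpy(dtype=float)
    diffs = a - b
    log2fc = diffs.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_rel(a, b, axis=1)
    zero_var = diffs.std(axis=1) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} gene(s) with zero-variance paired "
            "differences; p-value set to 1",
            stacklevel=2,
        )
        pvals = np.where(zero_var, 1.0, pvals)
    pvals = np.nan_to_num(pvals, nan=1.0)
    fdr = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": [normalize_symbol(g) for g in matrix.index],
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
        }
    )
    return validate_deg_table(table)


@dataclass(frozen=True)
class GeneSignature:
    """Thresholded up/down gene lists with the cuts that produced them."""

    name: str
    up: tuple[str, ...]
    down: tuple[str, ...]
    log2fc_cut: float
    fdr_cut: float
    provenance: str = ""

    def __post_init__(self):
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"genes in both up and down lists: {overlap}")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def genes(self) -> set[str]:
        return set(self.up) | set(self.down)

    def observed_signs(self) -> dict[str, int]:
        signs = {g: 1 for g in self.up}
        signs.update({g: -1 for g in self.down})
        return signs

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tdirection\n")
            for g in self.up:
                fh.write(f"{g}\tup\n")
            for g in self.down:
                fh.write(f"{g}\tdown\n")

    def to_gmt_lines(self) -> list[str]:
        up = "\t".join(self.up)
        dn = "\t".join(self.down)
        return [
            f"{self.name}_UP\t{self.provenance}\t{up}".rstrip("\t"),
            f"{self.name}_DN\t{self.provenance}\t{dn}".rstrip("\t"),
        ]


def build_signature(
    table: pd.DataFrame,
    log2fc_cut: float,
    fdr_cut: float,
    name: str,
) -> GeneSignature:
    """Select up/down genes at a symmetric fold-change and FDR threshold."""
    if log2fc_cut < 0:
        raise ValueError("log2fc_cut must be non-negative")
    if not 0 < fdr_cut <= 1:
        raise ValueError("fdr_cut must be in (0, 1]")
    table = validate_deg_table(table) if len(table) else table
    if len(table) == 0:
        return GeneSignature(name, (), (), log2fc_cut, fdr_cut)
    ok = table["fdr"] <= fdr_cut
    up = table.loc[ok & (table["log2fc"] >= log2fc_cut), "gene"]
    down = table.loc[ok & (table["log2fc"] <= -log2fc_cut), "gene"]
    if log2fc_cut == 0:
        # a zero cut would place log2fc == 0 genes on both sides
        up = table.loc[ok & (table["log2fc"] > 0), "gene"]
        down = table.loc[ok & (table["log2fc"] < 0), "gene"]
    return GeneSignature(
        name, tuple(sorted(up)), tuple(sorted(down)), log2fc_cut, fdr_cut
    )


def trim_signature(
    sig: GeneSignature,
    table: pd.DataFrame,
    target_n: int,
    increment: float = 0.01,
) -> GeneSignature:
    """Raise the symmetric |log2FC| cut until the signature fits target_n.

    The cut grows in fixed increments (default 0.01) and only removes
    genes, so the result is always a subset of the input signature.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    if len(sig) <= target_n:
        return sig
    table = validate_deg_table(table)
    members = table[table["gene"].isin(sig.genes())]
    fc = members.set_index("gene")["log2fc"]
    cut = sig.log2fc_cut
    up, down = set(sig.up), set(sig.down)
    while len(up) + len(down) > target_n:
        cut = round(cut + increment, 10)
        up = {g for g in up if fc[g] >= cut}
        down = {g for g in down if fc[g] <= -cut}
    return replace(
        sig, up=tuple(sorted(up)), down=tuple(sorted(down)), log2fc_cut=cut
    )
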