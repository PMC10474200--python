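"""Plain-text IO helpers: GMT gene sets, gene lists, rank matrices."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .signatures import normalize_symbol


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line, name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name = fields[0]
            sets[name] = {normalize_symbol(g) for g in fields[2:] if g.strip()}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(sets):
            desc = descriptions.get(name, "na")
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(normalize_symbol(line))
    return genes


def write_gene_list(genes: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_rank_matrix(path: str | Path) -> pd.DataFrame:
    """Gene-by-signature rank matrix TSV (genes on rows, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = pd.Index([normalize_symbol(g) for g in df.index], name="gene")
    return df.astype(int)


def write_rank_matrix(ranks: pd.DataFrame, path: str | Path) -> None:
    ranks.to_csv(path, sep="\t", index_label="gene")
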