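"""Venom-gland expression summaries over a two-replicate cpm table.

Activity classification follows the two rules used for venom-gland
libraries: a gene with 0 cpm in both replicates is *inactive*; a gene with
cpm >= 1 in both replicates is *counted-active* and enters gene counts and
expression shares.  Genes in between (sub-1 cpm in at least one replicate
but not zero in both) are flagged *ambiguous* and excluded from counts but
retained in the table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import InputError, NON_TOXIN

EXPRESSION_COLUMNS = ["gene_id", "family", "cpm_rep1", "cpm_rep2"]

ACTIVE, INACTIVE, AMBIGUOUS = "active", "inactive", "ambiguous"

#: Default case-insensitive keyword → family map for annotating description
#: strings (a stand-in for a published-family keyword search).
DEFAULT_KEYWORD_MAP = {
    "three-finger": "3FTx",
    "3ftx": "3FTx",
    "phospholipase a2": "PLA2",
    "pla2": "PLA2",
    "metalloprotein": "SVMP",
    "serine protease": "SVSP",
    "cysteine-rich secretory": "CRiSP",
    "crisp": "CRiSP",
    "l-amino acid oxidase": "LAAO",
    "natriuretic": "NP",
    "disintegrin": "DIS",
    "kunitz": "KUN",
    "c-type lectin": "CTL",
    "endonuclease": "endonuclease",
    "aminopeptidase": "aminopeptidase",
    "kazal": "kazal-type inhibitor",
    "insulin-like growth factor": "insulin-like growth factor",
    "endopeptidase": "endopeptidase",
    "acetylcholinesterase": "AChE",
    "peroxiredoxin": "peroxiredoxin",
    "aspartic protease": "aspartic protease",
    "sulfhydryl oxidase": "sulfhydryl oxidase",
    "glutaminyl cyclase": "glutaminyl cyclase",
    "prokineticin": "prokineticin",
    "nerve growth factor": "NGF",
}


def read_expression(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"expression table missing columns: {missing}")
    return table


def classify_active(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``status`` column: active / inactive / ambiguous.

    Counted-active requires cpm >= 1 in *both* replicates; inactive
    requires 0 in both.  Negative or non-finite cpm values are an error.
    """
    cpm = table[["cpm_rep1", "cpm_rep2"]].to_numpy(dtype=float)
    if not np.isfinite(cpm).all():
        raise InputError("cpm values must be finite")
    if (cpm < 0).any():
        raise InputError("cpm values must be non-negative")
    table = table.copy()
    both_ge1 = (cpm >= 1.0).all(axis=1)
    both_zero = (cpm == 0.0).all(axis=1)
    table["status"] = np.where(both_ge1, ACTIVE,
                               np.where(both_zero, INACTIVE, AMBIGUOUS))
    return table


def _require_status(table: pd.DataFrame) -> pd.DataFrame:
    if "status" not in table.columns:
        raise InputError("run classify_active first (no status column)")
    return table


def count_toxin_genes(table: pd.DataFrame) -> dict:
    """Counted-active gene counts per family and the toxin percentage.

    Returns per-family counts over counted-active genes, the toxin /
    non-toxin totals, the toxin percentage of all counted genes (unrounded
    and nearest-integer), and each family's share of toxin genes (percent,
    one decimal).
    """
    table = _require_status(table)
    active = table.loc[table["status"] == ACTIVE]
    is_toxin = active["family"] != NON_TOXIN
    n_toxin = int(is_toxin.sum())
    n_non = int((~is_toxin).sum())
    by_family = (
        active.loc[is_toxin].groupby("family").size().sort_values(ascending=False)
    )
    total = n_toxin + n_non
    pct = 100.0 * n_toxin / total if total else 0.0
    family_share = (
        (100.0 * by_family / n_toxin).round(1) if n_toxin else by_family.astype(float)
    )
    return {
        "counts_by_family": by_family,
        "family_share_percent": family_share,
        "n_toxin": n_toxin,
        "n_non_toxin": n_non,
        "toxin_percent_unrounded": pct,
        "toxin_percent": int(round(pct)),
    }


def expression_shares(table: pd.DataFrame) -> dict:
    """Expression shares over counted-active genes (mean cpm of the reps).

    Returns each toxin family's share of toxin expression (percent), and
    the toxin share of total expression (unrounded and nearest-integer).
    """
    table = _require_status(table)
    active = table.loc[table["status"] == ACTIVE].copy()
    active["cpm"] = active[["cpm_rep1", "cpm_rep2"]].mean(axis=1)
    total = float(active["cpm"].sum())
    if total <= 0:
        raise InputError("zero total expression among counted-active genes")
    is_toxin = active["family"] != NON_TOXIN
    toxin_cpm = float(active.loc[is_toxin, "cpm"].sum())
    by_family = (
        active.loc[is_toxin].groupby("family")["cpm"].sum().sort_values(
            ascending=False
        )
    )
    family_share = (
        100.0 * by_family / toxin_cpm if toxin_cpm else by_family
    )
    pct = 100.0 * toxin_cpm / total
    return {
        "family_share_percent": family_share,
        "toxin_cpm": toxin_cpm,
        "non_toxin_cpm": total - toxin_cpm,
        "toxin_percent_unrounded": pct,
        "toxin_percent": int(round(pct)),
    }


def annotation_rate(n_annotated_expanded: int, n_expressed: int) -> dict:
    """Percentage of expressed genes covered by functional annotation."""
    if n_expressed == 0:
        raise InputError("n_expressed must be positive")
    if not 0 <= n_annotated_expanded <= n_expressed:
        raise InputError("need 0 <= n_annotated_expanded <= n_expressed")
    pct = 100.0 * n_annotated_expanded / n_expressed
    return {"percent_unrounded": pct, "percent": int(round(pct))}


def assign_family_by_keyword(
    descriptions, keyword_map: dict | None = None
) -> list:
    """Classify description strings into families by keyword search.

    Case-insensitive substring matching against ``keyword_map`` (longest
    keyword wins on overlap); unmatched descriptions get ``non-toxin``.
    """
    kmap = keyword_map or DEFAULT_KEYWORD_MAP
    ordered = sorted(kmap, key=len, reverse=True)
    out = []
    for desc in descriptions:
        low = str(desc).lower()
        fam = next((kmap[k] for k in ordered if k.lower() in low), NON_TOXIN)
        out.append(fam)
    return out


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Combined per-family summary: counted-active genes and cpm shares."""
    table = classify_active(table) if "status" not in table.columns else table
    counts = count_toxin_genes(table)
    shares = expression_shares(table)
    fams = sorted(
        set(counts["counts_by_family"].index) | set(
            shares["family_share_percent"].index
        ),
        key=lambda f: -shares["family_share_percent"].get(f, 0.0),
    )
    return pd.DataFrame(
        {
            "family": fams,
            "n_genes": [int(counts["counts_by_family"].get(f, 0)) for f in fams],
            "gene_share_percent": [
                float(counts["family_share_percent"].get(f, 0.0)) for f in fams
            ],
            "expression_share_percent": [
                float(shares["family_share_percent"].get(f, 0.0)) for f in fams
            ],
        }
    )
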