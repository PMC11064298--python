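"""Term over-representation among expressed W genes.

One-sided hypergeometric test per term (upper tail: at least the observed
number of annotated genes in the set, given the background) with
Benjamini-Hochberg FDR across terms — the conventional over-representation
analysis behind FDR-reporting enrichment tables.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeometric_p(set_hits: int, set_size: int, bg_hits: int, bg_size: int) -> float:
    """Upper-tail P[X >= set_hits] for X ~ Hypergeometric(bg_size, bg_hits,
    set_size): the chance of at least the observed overlap when the set is
    drawn without replacement from the background."""
    if not (0 <= set_hits <= set_size <= bg_size):
        raise ValueError("need 0 <= set_hits <= set_size <= bg_size")
    if not (0 <= bg_hits <= bg_size):
        raise ValueError("need 0 <= bg_hits <= bg_size")
    if set_hits > bg_hits:
        raise ValueError("set_hits cannot exceed bg_hits")
    return float(hypergeom.sf(set_hits - 1, bg_size, bg_hits, set_size))


def bh_fdr(p_values) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = list(p_values)
    if not p:
        return []
    if any(not 0.0 <= x <= 1.0 for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def enrich(
    gene_set: set[str],
    annotation: pd.DataFrame,
    background: set[str],
) -> pd.DataFrame:
    """Enrichment of annotation terms in ``gene_set`` against ``background``.

    ``annotation`` needs columns gene_id and term_id (term_name and
    category are carried through when present).  Unannotated background
    genes still count in the totals.  Returns one row per term with at
    least one set hit, sorted by q then p.
    """
    if not background:
        raise ValueError("empty background gene set")
    stray = gene_set - background
    if stray:
        raise ValueError(f"gene set members missing from background: {sorted(stray)[:3]}")
    ann = annotation[annotation["gene_id"].isin(background)].drop_duplicates(
        subset=["gene_id", "term_id"]
    )
    meta_cols = [c for c in ("term_name", "category") if c in ann.columns]
    rows = []
    for term_id, sub in ann.groupby("term_id"):
        term_genes = set(sub["gene_id"])
        set_hits = len(term_genes & gene_set)
        if set_hits == 0:
            continue
        p = hypergeometric_p(set_hits, len(gene_set), len(term_genes), len(background))
        row = {
            "term_id": term_id,
            "set_hits": set_hits,
            "bg_hits": len(term_genes),
            "p_value": p,
        }
        for c in meta_cols:
            row[c] = sub[c].iloc[0]
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["term_id", *meta_cols, "set_hits", "bg_hits", "p_value", "fdr"]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"])
    out = out.sort_values(["fdr", "p_value", "term_id"], ignore_index=True)
    return out[["term_id", *meta_cols, "set_hits", "bg_hits", "p_value", "fdr"]]
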