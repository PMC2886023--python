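"""Hypergeometric over-representation of annotation terms in a DE gene set.

For a term annotating K of the N background genes, of which k fall in the
n-gene DE set, the enrichment p-value is the upper tail
P[X >= k] with X ~ Hypergeometric(N, K, n) — the chance of drawing at
least k term genes when n genes are sampled from the background without
replacement.  The background is the fixed set of genes that entered the
analysis, and the annotation is taken as flat gene -> term pairs (no
ontology-graph propagation).  Raw p-values at the chosen alpha mirror the
field's common reporting; a Benjamini-Hochberg column is emitted alongside.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats


def over_representation(
    de_genes: set[str],
    background: set[str],
    annotation: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Test every annotated term; results sorted by ascending p-value.

    ``annotation`` has columns gene_id, term_id and optionally term_name;
    pairs outside the background are ignored.  ``de_genes`` must be a
    subset of ``background``.  An empty DE set yields an empty result.
    """
    de_genes = set(de_genes)
    background = set(background)
    if not de_genes <= background:
        raise ValueError("DE genes must be a subset of the background")
    cols = ["term_id", "term_name", "k", "K", "n", "N", "p_value", "p_bh", "significant"]
    if not de_genes:
        return pd.DataFrame(columns=cols)

    ann = annotation[annotation["gene_id"].isin(background)].drop_duplicates(
        ["gene_id", "term_id"])
    if "term_name" not in ann.columns:
        ann = ann.assign(term_name=ann["term_id"])
    N, n = len(background), len(de_genes)
    rows = []
    for (term, name), genes in ann.groupby(["term_id", "term_name"])["gene_id"]:
        gset = set(genes)
        K = len(gset)
        k = len(gset & de_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=cols[:7])
    out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    out["p_bh"] = _benjamini_hochberg(out["p_value"])
    out["significant"] = out["p_value"] < alpha
    return out


def _benjamini_hochberg(p: pd.Series) -> pd.Series:
    m = len(p)
    if m == 0:
        return p
    order = p.to_numpy().argsort(kind="mergesort")
    adj = p.to_numpy()[order] * m / (pd.RangeIndex(1, m + 1).to_numpy())
    # enforce monotonicity from the largest p downwards
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = pd.Series(0.0, index=p.index)
    out.iloc[order] = adj.clip(max=1.0)
    return out
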