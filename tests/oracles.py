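"""Independent brute-force oracles used by the test suite.

Everything here is written as plain enumeration/loops, deliberately
independent of the package's vectorized implementations.
"""

from __future__ import annotations

import math


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def expression_conservation(ref_frac, tgt_frac, thr=0.05):
    """Rule-table enumeration: {(gene, cell_type): category}.

    ``ref_frac`` / ``tgt_frac``: dict cell_type -> dict gene -> fraction.
    """
    genes = sorted(
        set(g for d in ref_frac.values() for g in d)
        & set(g for d in tgt_frac.values() for g in d)
    )
    shared_types = sorted(set(ref_frac) & set(tgt_frac))
    calls = {}
    for g in genes:
        for ct in shared_types:
            r = ref_frac[ct][g] > thr
            t = tgt_frac[ct][g] > thr
            t_other = any(
                tgt_frac[c][g] > thr for c in tgt_frac if c != ct
            )
            if r and t:
                calls[(g, ct)] = "conserved"
            elif r and t_other:
                calls[(g, ct)] = "loss"
            elif r:
                calls[(g, ct)] = "absent"
            elif t:
                calls[(g, ct)] = "gain"
    return calls


def marker_conservation(ref_enriched, tgt_enriched, tgt_frac, thr=0.05):
    """Rule-table enumeration for reference-enriched (gene, cell_type) pairs.

    ``ref_enriched`` / ``tgt_enriched``: dict cell_type -> set of genes;
    ``tgt_frac``: dict cell_type -> dict gene -> fraction.
    """
    calls = {}
    tgt_genes = set(g for d in tgt_frac.values() for g in d)
    for ct, genes in ref_enriched.items():
        for g in genes:
            if g in tgt_enriched.get(ct, set()):
                calls[(g, ct)] = "conserved"
            elif any(g in tgt_enriched.get(c, set()) for c in tgt_enriched if c != ct):
                calls[(g, ct)] = "switch"
            elif g in tgt_genes and any(
                tgt_frac[c].get(g, 0.0) > thr for c in tgt_frac
            ):
                calls[(g, ct)] = "loss"
            else:
                calls[(g, ct)] = "absent"
    return calls


def resolve_pair(records, expr_a, expr_b):
    """Brute-force two-species ortholog resolution.

    ``records``: list of (a_id, b_id) with every id detected; returns the
    set of surviving records after keeping, for each duplicated id on
    either side, the partner with maximal expression (ties: smallest id).
    """
    surviving = set(records)
    for side, partner_expr in ((0, None), (1, None)):
        by_id = {}
        for rec in sorted(surviving):
            by_id.setdefault(rec[side], []).append(rec)
        for gid, recs in by_id.items():
            if len(recs) <= 1:
                continue
            other = 1 - side
            expr = expr_b if other == 1 else expr_a
            best = max(
                recs, key=lambda r: (expr[r[other]], -ord(r[other][0]) * 0)
            )
            best_val = expr[best[other]]
            tied = sorted(r for r in recs if expr[r[other]] == best_val)
            winner = tied[0]
            for r in recs:
                if r != winner:
                    surviving.discard(r)
    return surviving
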