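"""Methylation-expression integration and gene-set over-representation.

Promoter methylation generally represses transcription, so a convergent DEG
whose convergent promoter shifted in the opposite direction (up & hypo, or
down & hyper) is an inverse-consistent pair — the regulatory signature of
interest.  ``integrate`` joins the convergent DEG and convergent promoter
sets; ``ora`` is a generic hypergeometric over-representation test against a
user-supplied GMT collection with a configurable background (by default the
genes expressed in the focal species after filtering).
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .de import ConvergentDEGSet, bh_adjust
from .dmp import ConvergentPromoterSet
from .exceptions import AnalysisError

_log = logging.getLogger(__name__)


def integrate(
    degs: ConvergentDEGSet, promoters: ConvergentPromoterSet, tissue: str | None = None
) -> pd.DataFrame:
    """Join convergent DEGs with convergent promoters into inverse-consistency records.

    One row per gene present in both sets: expression direction (up/down),
    methylation direction (hypo/hyper) and whether the pair is inverse
    consistent ((up & hypo) or (down & hyper)).
    """
    expr = {g: "up" for g in degs.up_genes}
    expr.update({g: "down" for g in degs.down_genes})
    meth = {g: "hypo" for g in promoters.hypo_genes}
    meth.update({g: "hyper" for g in promoters.hyper_genes})
    shared = sorted(set(expr) & set(meth))
    rows = [
        {
            "gene_id": g,
            "tissue": tissue,
            "expression_direction": expr[g],
            "methylation_direction": meth[g],
            "inverse_consistent": (expr[g], meth[g]) in (("up", "hypo"), ("down", "hyper")),
        }
        for g in shared
    ]
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "tissue", "expression_direction", "methylation_direction", "inverse_consistent"],
    )
    n_inv = int(out["inverse_consistent"].sum()) if len(out) else 0
    _log.info(
        "integration (%s): %d shared genes, %d inverse-consistent (up&hypo=%d, down&hyper=%d)",
        tissue,
        len(out),
        n_inv,
        int(((out["expression_direction"] == "up") & out["inverse_consistent"]).sum()) if len(out) else 0,
        int(((out["expression_direction"] == "down") & out["inverse_consistent"]).sum()) if len(out) else 0,
    )
    return out


def ora(
    query: Sequence[str],
    sets: Mapping[str, Sequence[str]],
    background: Sequence[str],
    min_overlap: int = 0,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the background; the p-value is the upper tail
    P(overlap >= observed) of the hypergeometric law, BH-adjusted across sets.
    """
    bg = set(background)
    if not bg:
        raise AnalysisError("empty background")
    q = set(query) & bg
    if len(q) < len(set(query)):
        _log.warning("%d query genes outside the background were dropped", len(set(query)) - len(q))
    m = len(bg)
    rows = []
    for name, members in sets.items():
        s = set(members) & bg
        overlap = len(s & q)
        if overlap < min_overlap:
            continue
        # upper tail: P(X >= overlap), X ~ Hypergeom(M=m, n=|set|, N=|query|)
        p = float(scipy.stats.hypergeom.sf(overlap - 1, m, len(s), len(q)))
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": len(s),
                "query_size": len(q),
                "background_size": m,
                "p": min(1.0, p),
            }
        )
    out = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size", "background_size", "p"]
    )
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["padj"] = np.array([], dtype=float)
    return out.sort_values("p", kind="stable").reset_index(drop=True)
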