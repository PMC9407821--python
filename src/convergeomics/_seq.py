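"""Low-level sequence helpers shared by the format readers and methylation code.

Coordinates are 0-based half-open throughout; ``strand`` is ``'+'`` or ``'-'``.
"""
from __future__ import annotations

import logging
from typing import Mapping

_log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_context(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> str:
    """Classify a cytosine into CG / CHG / CHH (H = A, T or C).

    The base at ``pos`` on ``strand`` must be a cytosine: on the plus strand the
    reference base is ``C``, on the minus strand it is ``G`` (whose complement is C).
    The context reads 5'->3' along the given strand.  Sites within 2 bp of the
    chromosome end with an incomplete downstream context default to CHH.
    """
    seq = genome[chrom]
    if strand == "+":
        triplet = seq[pos : pos + 3].upper()
    elif strand == "-":
        triplet = revcomp(seq[max(0, pos - 2) : pos + 1]).upper()
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if not triplet or triplet[0] != "C":
        base = triplet[:1] or "<end>"
        raise ValueError(f"base at {chrom}:{pos}({strand}) is {base}, not C")
    if len(triplet) < 3:
        _log.debug("incomplete context at %s:%d(%s); defaulting to CHH", chrom, pos, strand)
        if len(triplet) == 2 and triplet[1] == "G":
            return "CG"
        return "CHH"
    if triplet[1] == "G":
        return "CG"
    if triplet[2] == "G":
        return "CHG"
    return "CHH"


def cytosine_sites(seq: str, cg_only: bool = False):
    """Return (positions, strands, contexts) numpy arrays for all cytosines in ``seq``.

    Plus-strand sites are reference ``C`` bases, minus-strand sites reference ``G``
    bases.  With ``cg_only`` only CpG-dinucleotide sites are reported (both strands
    of each CG).
    """
    import numpy as np

    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    is_c = arr == b"C"
    is_g = arr == b"G"
    n = len(arr)
    if cg_only:
        cg = np.flatnonzero(is_c[:-1] & is_g[1:])
        pos = np.concatenate([cg, cg + 1])
        strand = np.concatenate([np.full(len(cg), "+"), np.full(len(cg), "-")])
        ctx = np.full(len(pos), "CG")
        order = np.argsort(pos, kind="stable")
        return pos[order], strand[order], ctx[order]

    plus = np.flatnonzero(is_c)
    minus = np.flatnonzero(is_g)

    def _ctx_plus(p):
        nxt = np.full(len(p), b"N", dtype="S1")
        nxt2 = np.full(len(p), b"N", dtype="S1")
        ok1 = p + 1 < n
        ok2 = p + 2 < n
        nxt[ok1] = arr[p[ok1] + 1]
        nxt2[ok2] = arr[p[ok2] + 2]
        out = np.full(len(p), "CHH")
        out[nxt2 == b"G"] = "CHG"
        out[nxt == b"G"] = "CG"
        out[~ok2 & ~(ok1 & (nxt == b"G"))] = "CHH"  # incomplete context convention
        return out

    def _ctx_minus(p):
        # context on minus strand: complement of bases at p-1, p-2
        prv = np.full(len(p), b"N", dtype="S1")
        prv2 = np.full(len(p), b"N", dtype="S1")
        ok1 = p - 1 >= 0
        ok2 = p - 2 >= 0
        prv[ok1] = arr[p[ok1] - 1]
        prv2[ok2] = arr[p[ok2] - 2]
        out = np.full(len(p), "CHH")
        out[prv2 == b"C"] = "CHG"  # complement of C is G two bases downstream
        out[prv == b"C"] = "CG"
        out[~ok2 & ~(ok1 & (prv == b"C"))] = "CHH"
        return out

    pos = np.concatenate([plus, minus])
    strand = np.concatenate([np.full(len(plus), "+"), np.full(len(minus), "-")])
    ctx = np.concatenate([_ctx_plus(plus), _ctx_minus(minus)])
    order = np.argsort(pos, kind="stable")
    return pos[order], strand[order], ctx[order]
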