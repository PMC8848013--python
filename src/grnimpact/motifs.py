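"""Chain and feed-forward-loop motifs in directed networks.

Given genes X, Y, Z with edges X -> Y and Y -> Z, the ordered triple is a
*chain* when the shortcut X -> Z is absent and a *feed-forward loop* (ffl)
when it is present.  Confusing one for the other is the transitivity error
that network reconstruction methods are meant to avoid: the classification
below scores, over a predicted top-k network, whether a predicted chain is
really a chain in the reference (TP), a predicted chain is actually a loop
(FP), or a predicted loop is actually a chain (FN).  Triples whose backbone
(X -> Y and Y -> Z) is not present in the reference cannot be classified
either way and are reported separately rather than folded into the rates.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Collection, Iterable

from .core import MotifClassification, MotifInstance

__all__ = ["enumerate_motifs", "classify_motifs"]


def enumerate_motifs(edges: Collection[tuple]) -> list[MotifInstance]:
    """All chains and feed-forward loops of a directed edge set.

    Scans adjacent edge pairs (X -> Y, Y -> Z) with X, Y, Z distinct; each
    ordered triple is reported exactly once, as a chain when X -> Z is
    absent and as an ffl when present.
    """
    edge_set = set(edges)
    out: dict = defaultdict(list)
    for s, t in edge_set:
        if s == t:
            raise ValueError(f"self-loop {s}->{t} in motif enumeration input")
        out[s].append(t)
    motifs = []
    for x, y in edge_set:
        for z in out.get(y, ()):
            if z == x or z == y:
                continue
            kind = "ffl" if (x, z) in edge_set else "chain"
            motifs.append(MotifInstance(x, y, z, kind))
    return motifs


def classify_motifs(pred_edges: Collection[tuple],
                    ref_edges: Collection[tuple]) -> MotifClassification:
    """Score predicted chain/loop motifs against the reference network.

    For each predicted motif whose backbone edges X -> Y and Y -> Z both
    exist in the reference:

    * predicted chain, reference chain  -> TP
    * predicted chain, reference loop   -> FP
    * predicted loop,  reference chain  -> FN
    * predicted loop,  reference loop   -> correct loop (kept separately)

    Motifs with a backbone edge missing from the reference are
    unclassifiable.  TPR = TP/(TP+FN) and FDR = FP/(TP+FP); when a
    denominator is zero the rate is reported as missing (``None``), never 0.
    """
    ref_set = set(ref_edges)
    tp, fp, fn, tp_loops, unclassifiable = [], [], [], [], []
    for m in enumerate_motifs(pred_edges):
        if (m.x, m.y) not in ref_set or (m.y, m.z) not in ref_set:
            unclassifiable.append(m)
            continue
        ref_kind = "ffl" if (m.x, m.z) in ref_set else "chain"
        if m.kind == "chain" and ref_kind == "chain":
            tp.append(m)
        elif m.kind == "chain" and ref_kind == "ffl":
            fp.append(m)
        elif m.kind == "ffl" and ref_kind == "chain":
            fn.append(m)
        else:
            tp_loops.append(m)
    return MotifClassification(
        tp_chains=tp, fp_chains=fp, fn_chains=fn,
        tp_loops=tp_loops, unclassifiable=unclassifiable,
    )
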