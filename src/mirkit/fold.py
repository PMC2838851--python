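"""RNA secondary-structure prediction and fold-significance statistics.

The minimum-free-energy (MFE) fold of each candidate precursor is the
quantity every structural criterion downstream is computed on.  The
default engine is ViennaRNA's :func:`RNA.fold` (Turner nearest-neighbour
parameters, 37 degC, no pseudoknots); any callable with the same
``seq -> (dot_bracket, mfe)`` contract can be substituted.

Fold significance for exon-overlapping candidates is assessed against
dinucleotide-preserving shuffles (Altschul-Erickson Eulerian-walk
shuffle), with the add-one permutation p-value

    p = (1 + #{shuffles with MFE <= observed MFE}) / (n_shuffles + 1).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

_RNA_ALPHABET = set("ACGU")

FoldEngine = Callable[[str], tuple[str, float]]

_vienna = None


def _vienna_fold(seq: str) -> tuple[str, float]:
    global _vienna
    if _vienna is None:
        import RNA as _vienna_mod  # ViennaRNA python bindings

        _vienna = _vienna_mod
    structure, mfe = _vienna.fold(seq)
    return structure, float(mfe)


def fold(seq: str, engine: FoldEngine | None = None) -> tuple[str, float]:
    """MFE fold of an RNA sequence.

    Parameters
    ----------
    seq : RNA string over {A,C,G,U}.
    engine : optional replacement folding callable.

    Returns
    -------
    (dot_bracket, mfe_kcal_mol)
    """
    s = seq.upper()
    if not s:
        raise ValueError("cannot fold an empty sequence")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU characters in fold input: {sorted(bad)}")
    return (engine or _vienna_fold)(s)


def pair_table(structure: str) -> list[int]:
    """0-based pair table from a dot-bracket string; -1 marks unpaired."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"unexpected structure character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pt


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide composition (Altschul-Erickson).

    Builds the dinucleotide multigraph, draws a random last-edge
    arborescence rooted at the terminal vertex, shuffles the remaining
    out-edges per vertex and reads off the Eulerian walk from the first
    character.  First/last characters are preserved.
    """
    s = seq.upper()
    if len(s) < 4:
        raise ValueError("sequence too short to shuffle (< 4 nt)")
    if len(set(s)) == 1:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = list(edges)
    for _ in range(10_000):
        # Propose a last out-edge for every non-terminal vertex.
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last
        }
        # Accept if following last-edges from every vertex reaches `last`
        # (the chosen edges then form an arborescence into the sink).
        ok = True
        for v in last_edge:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - arborescence always found for real sequences
        raise RuntimeError("failed to sample a dinucleotide-shuffle arborescence")
    shuffled_edges: dict[str, list[str]] = {}
    for v, outs in edges.items():
        outs = list(outs)
        if v != last:
            outs.remove(last_edge[v])
        perm = rng.permutation(len(outs))
        outs = [outs[i] for i in perm]
        if v != last:
            outs.append(last_edge[v])
        shuffled_edges[v] = outs
    # Eulerian walk.
    out = [s[0]]
    idx = {v: 0 for v in edges}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled_edges[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def fold_pvalue(
    seq: str,
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
    engine: FoldEngine | None = None,
) -> float:
    """Permutation p-value of the observed MFE vs dinucleotide shuffles.

    ``p = (1 + #{MFE_shuffle <= MFE_obs}) / (n_shuffles + 1)``; with 99
    shuffles the minimum attainable p is exactly 0.01.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, mfe_obs = fold(seq, engine=engine)
    hits = 0
    for _ in range(n_shuffles):
        _, mfe_s = fold(dinucleotide_shuffle(seq, rng), engine=engine)
        if mfe_s <= mfe_obs:
            hits += 1
    return (1 + hits) / (n_shuffles + 1)


def count_dinucleotides(seq: str) -> dict[str, int]:
    """Dinucleotide census (used to verify the shuffle preserves it)."""
    out: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out
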