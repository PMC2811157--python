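"""Independent brute-force oracles used to cross-check the implementation.

These re-derive windows, scores and motif matches by direct column walks
over the raw alignment strings, on purpose sharing no code with the package.
"""

from __future__ import annotations

AA = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
UNK = "X"


def brute_window_score(seed_aln: str, orth_aln: str, column: int, flank: int = 5):
    """(status, score, central_conserved) by direct inspection of alignment
    strings; `column` must hold a seed residue."""
    seed_cols = [i for i, ch in enumerate(seed_aln) if ch != GAP]
    p = seed_cols.index(column)
    seed_c = seed_aln[column]
    orth_c = orth_aln[column]
    if orth_c == UNK:
        return ("Incomplete", None, None)
    if seed_c in AA and orth_c in AA and (seed_c == orth_c or (seed_c in "ST" and orth_c in "ST")):
        central = True
    else:
        central = False
    ident = comp = 0
    for d in list(range(-flank, 0)) + list(range(1, flank + 1)):
        q = p + d
        if q < 0 or q >= len(seed_cols):
            continue
        col = seed_cols[q]
        o = orth_aln[col]
        if o == UNK:
            continue
        comp += 1
        if o == seed_aln[col]:
            ident += 1
    if not central:
        return ("numeric", 0.0, False)
    if comp == 0:
        return ("Incomplete", None, None)
    return ("numeric", ident / comp, True)


def brute_match_motif(sequence: str, position: int, central_allowed, required) -> bool:
    """Slot-by-slot consensus check on an ungapped sequence (1-based)."""
    if sequence[position - 1] not in central_allowed:
        return False
    for off, allowed in required.items():
        j = position + off
        if j < 1 or j > len(sequence):
            return False
        if sequence[j - 1] not in allowed:
            return False
    return True
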