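"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms and data paths of the package:
MEMs are enumerated by scanning every diagonal; chains by exhaustive
subset search; gene sets by per-gene set comprehension.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def brute_force_mems(ref: str, qry: str, min_len: int) -> set[tuple[int, int, int, str]]:
    """All maximal exact matches >= min_len, by per-diagonal run scanning.

    Returns (ref_start, qry_start_forward, length, strand) tuples. N never
    matches, including N-vs-N.
    """
    out: set[tuple[int, int, int, str]] = set()
    for strand, q in (("+", qry), ("-", _rc(qry))):
        r_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
        q_arr = np.frombuffer(q.encode(), dtype=np.uint8)
        n_code = ord("N")
        for d in range(-(len(q) - 1), len(ref)):
            i0 = max(0, d)
            j0 = i0 - d
            n = min(len(ref) - i0, len(q) - j0)
            if n < min_len:
                continue
            rs = r_arr[i0 : i0 + n]
            qs = q_arr[j0 : j0 + n]
            eq = (rs == qs) & (rs != n_code)
            # maximal runs of equality
            k = 0
            while k < n:
                if not eq[k]:
                    k += 1
                    continue
                start = k
                while k < n and eq[k]:
                    k += 1
                length = k - start
                if length >= min_len:
                    ri = i0 + start
                    qi = j0 + start
                    if strand == "+":
                        out.add((ri, qi, length, "+"))
                    else:
                        out.add((ri, len(qry) - (qi + length), length, "-"))
    return out


def _link_ok(a, b, max_gap: int, slack: int = 25) -> bool:
    """Independent restatement of the chain gap rule: ordered on both
    sequences, neither gap above max_gap (small overlap tolerated)."""

    def qcoords(s):
        if s.strand == "+":
            return s.qry_start, s.qry_start + s.length
        return -(s.qry_start + s.length), -s.qry_start

    if b.ref_start <= a.ref_start:
        return False
    aq0, aq1 = qcoords(a)
    bq0, bq1 = qcoords(b)
    if bq0 <= aq0:
        return False
    rg = b.ref_start - (a.ref_start + a.length)
    qg = bq0 - aq1
    return -slack <= rg <= max_gap and -slack <= qg <= max_gap


def best_chain_weight_exhaustive(seeds, max_gap: int) -> int:
    """Maximum total seed length of any valid chain, by exhaustive subset
    enumeration (feasible for <= ~15 seeds)."""
    n = len(seeds)
    best = 0
    order = sorted(range(n), key=lambda i: (seeds[i].ref_start, seeds[i].qry_start))
    for size in range(1, n + 1):
        for combo in combinations(order, size):
            chain = sorted(combo, key=lambda i: (seeds[i].ref_start, seeds[i].qry_start))
            if all(
                _link_ok(seeds[a], seeds[b], max_gap)
                for a, b in zip(chain, chain[1:])
            ):
                w = sum(seeds[i].length for i in chain)
                best = max(best, w)
    return best


def gene_loss_oracle(cells, roles, which: str) -> set[str]:
    """Set-comprehension oracle for the two gene-loss definitions.

    ``cells`` is a dict gene -> dict strain -> bool; ``roles`` maps strain
    to focal/other_conspecific/outgroup.
    """
    focal = [s for s, r in roles.items() if r == "focal"]
    consp = [s for s, r in roles.items() if r == "other_conspecific"]
    outg = [s for s, r in roles.items() if r == "outgroup"]
    out = set()
    for gene, row in cells.items():
        in_focal = any(row[s] for s in focal)
        if which == "candidate":
            if any(row[s] for s in consp) and any(row[s] for s in outg) and not in_focal:
                out.add(gene)
        elif which == "core":
            if all(row[s] for s in consp) and not in_focal:
                out.add(gene)
        else:
            raise ValueError(which)
    return out
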