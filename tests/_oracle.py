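"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with mirtail: the adapter oracle scans
every alignment position naively, the isomiR oracle enumerates every
(arm, offset, split) decomposition and scores them all, and the
hypergeometric oracle enumerates draws combinatorially.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass


def oracle_find_adapter(seq: str, adapter: str, min_overlap: int = 10,
                        max_mismatch_rate: float = 0.1) -> int:
    """Naive leftmost adapter search.

    Internal positions require the full adapter; positions where the read
    ends inside the adapter align the available prefix (>= min_overlap).
    """
    n, alen = len(seq), len(adapter)
    for pos in range(n):
        window = n - pos
        if window >= alen:
            length = alen
        elif window >= min_overlap:
            length = window
        else:
            break
        allowed = int(max_mismatch_rate * length)
        mm = sum(1 for a, b in zip(seq[pos: pos + length], adapter[:length]) if a != b)
        if mm <= allowed:
            return pos
    return -1


@dataclass(frozen=True)
class OracleArm:
    mirna_id: str
    arm: str
    ctx: str  # hairpin + flank, T-alphabet
    mature_start: int
    mature_end: int


def _valid_split(insert: str, ctx: str, start: int, body_start: int, body_end: int,
                 t: int, max_mm: int) -> int | None:
    """Mismatch count if splitting at t is valid under the declared rules,
    else None. Rules: exact match in 5'/3' extension zones; <= max_mm body
    mismatches, each followed by a later matching base somewhere in the
    insert; template exhaustion is a mismatch."""
    L = len(insert)
    avail = len(ctx) - start
    body_start_idx = max(0, body_start - start)
    body_end_idx = body_end - start
    matches = [i < avail and insert[i] == ctx[start + i] for i in range(L)]
    last_match = max((i for i in range(L) if matches[i]), default=-1)
    mm = 0
    for i in range(t):
        if matches[i]:
            continue
        if i < body_start_idx:
            return None  # 5' extension zone
        if i >= body_end_idx:
            return None  # 3' extension zone
        if i >= last_match:
            return None  # trailing mismatch run is always tail
        mm += 1
    return mm if mm <= max_mm else None


def oracle_classify(insert: str, arms: list[OracleArm], max_offset5: int = 2,
                    max_mm: int = 1, max_tail: int = 6, max_trim3: int = 6):
    """All best-scoring decompositions of an insert, exhaustively.

    For every arm, offset and split point, keep the maximal-templated valid
    split; across candidates minimize (mismatches, |offset5|, tail length)
    lexicographically, breaking ties by (mirna_id, arm). Returns a list of
    dicts or [] when unassigned.
    """
    candidates = []
    for arm in arms:
        for off in range(-max_offset5, max_offset5 + 1):
            start = arm.mature_start + off
            if start < 0:
                continue
            body_end_idx = arm.mature_end - start
            best = None
            for t in range(len(insert), -1, -1):
                mm = _valid_split(insert, arm.ctx, start, arm.mature_start,
                                  arm.mature_end, t, max_mm)
                if mm is not None:
                    best = (t, mm)
                    break
            if best is None:
                continue
            t, mm = best
            tail = insert[t:]
            templated3 = t - body_end_idx
            if len(tail) > max_tail or templated3 < -max_trim3:
                continue
            candidates.append({
                "mirna_id": arm.mirna_id, "arm": arm.arm, "offset5": off,
                "templated3": templated3, "tail": tail.replace("T", "U"),
                "mm": mm,
            })
    if not candidates:
        return []
    key = lambda c: (c["mm"], abs(c["offset5"]), len(c["tail"]))
    best_key = min(key(c) for c in candidates)
    winners = sorted((c for c in candidates if key(c) == best_key),
                     key=lambda c: (c["mirna_id"], c["arm"]))
    for w in winners:
        w["weight"] = 1.0 / len(winners)
    return winners


def oracle_category(offset5: int, templated3: int, tail: str, mm: int) -> str:
    if tail:
        return "nta"
    if offset5 == 0 and templated3 == 0:
        return "snp_flagged" if mm else "exact"
    if offset5 == 0:
        return "lv3pE" if templated3 > 0 else "lv3pT"
    if templated3 == 0:
        return "lv5pE" if offset5 < 0 else "lv5pT"
    return "mv"


def oracle_hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exact enumeration over all C(N, n) draws (N small)."""
    universe = range(N)
    special = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total


def oracle_bh(pvals):
    """Textbook BH step-up: p_(i) * m / i with cumulative minimum."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = min(running, 1.0)
    return q
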