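"""isomiR assignment and 3' tail decomposition.

Each processed insert is aligned, without gaps, against every mature arm at
5' offsets within +-2 nt. The 3' end is then decomposed by the greedy
maximal-templated rule: the templated match is extended base-by-base along
the hairpin (and then an optional 3' genomic flank) for as long as the bases
agree, and the remaining suffix is the nontemplated tail. This is the most
conservative NTA call (minimal tail).

Up to one SNP-style mismatch inside the mature body is tolerated and
recorded, but only when it is followed by at least one matching base: a
trailing mismatch run is always a tail, never a SNP. Mismatches in the
templated 5'/3' extension zones are never tolerated.

Categories follow the standard isomiR taxonomy: canonical reads are
``exact``; reads whose only variation is a templated 3' extension or trim
are ``lv3pE``/``lv3pT``; likewise ``lv5pE``/``lv5pT`` at the 5' end;
``mv`` are multilength variants (both ends vary); any read with a
nontemplated tail is ``nta`` (tail presence dominates); ``snp_flagged``
marks otherwise-canonical reads with a body mismatch.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .reference import HairpinRecord

CATEGORIES = ("exact", "lv5pE", "lv5pT", "lv3pE", "lv3pT", "mv", "nta", "snp_flagged", "unassigned")
TAIL_TYPES = ("none", "A", "AA", "AU", "U", "UA", "UU", "polyA", "polyU", "G", "C", "other")

_SIMPLE_TAILS = {"", "A", "AA", "AU", "U", "UA", "UU", "G", "C"}

SEED_K = 12


def classify_tail(tail: str) -> str:
    """Map a nontemplated suffix to its tail type.

    Accepts U- or T-alphabet. Exact mono/di types map to their own labels;
    homopolymers of length >= 3 map to polyA/polyU; anything else (mixed
    tails, long G/C runs) is ``other`` — "any length" aggregations count
    homopolymeric tails only.
    """
    t = tail.upper().replace("T", "U")
    if set(t) - set("ACGU"):
        raise ValueError(f"tail contains non-nucleotide characters: {tail!r}")
    if t == "":
        return "none"
    if t in _SIMPLE_TAILS:
        return t
    if len(t) >= 3 and set(t) == {"A"}:
        return "polyA"
    if len(t) >= 3 and set(t) == {"U"}:
        return "polyU"
    return "other"


def classify_category(offset5: int, templated3: int, tail: str, internal_mismatches: int = 0) -> str:
    """isomiR taxonomy from the decomposed coordinates (tail dominates)."""
    if tail:
        return "nta"
    if offset5 == 0 and templated3 > 0:
        return "lv3pE"
    if offset5 == 0 and templated3 < 0:
        return "lv3pT"
    if templated3 == 0 and offset5 < 0:
        return "lv5pE"
    if templated3 == 0 and offset5 > 0:
        return "lv5pT"
    if offset5 != 0 and templated3 != 0:
        return "mv"
    return "snp_flagged" if internal_mismatches > 0 else "exact"


@dataclass(frozen=True)
class IsomiRCall:
    """One (possibly weight-split) assignment of a read to a mature arm."""

    mirna_id: str
    arm: str
    offset5: int
    templated3: int
    tail: str  # U-space
    internal_mismatches: int
    category: str
    tail_type: str
    weight: float = 1.0


_UNASSIGNED = (IsomiRCall("*", "*", 0, 0, "", 0, "unassigned", "none", 1.0),)


def decompose_3prime(insert: str, ctx: str, start: int, body_start: int, body_end: int,
                     max_internal_mm: int = 1) -> tuple[int, str, int] | None:
    """Greedy maximal-templated split of ``insert`` aligned at ctx[start:].

    ``body_start``/``body_end`` bound the mature arm on ctx (0-based,
    half-open). Returns (templated3, tail, internal_mismatches) or None when
    a 5'-extension base (before the mature start) mismatches: templated 5'
    extension must match exactly. Template exhaustion counts as mismatch, so
    extension past the flank is nontemplated.
    """
    L = len(insert)
    body_end_idx = body_end - start  # insert index one past the mature 3' end
    body_start_idx = max(0, body_start - start)
    avail = len(ctx) - start
    last_match = -1
    for i in range(L - 1, -1, -1):
        if i < avail and insert[i] == ctx[start + i]:
            last_match = i
            break
    mm = 0
    t = L
    for i in range(L):
        if i < avail and insert[i] == ctx[start + i]:
            continue
        if i < body_start_idx:
            return None  # mismatch in the 5'-templated-extension zone
        if i < body_end_idx and i < last_match and mm < max_internal_mm:
            mm += 1
            continue
        t = i
        break
    tail = insert[t:]
    return t - body_end_idx, tail, mm


@dataclass(frozen=True)
class _ArmRef:
    mirna_id: str
    arm: str
    ctx: str  # hairpin + flank
    mature_start: int
    mature_end: int


class ReferenceIndex:
    """Seed-indexed mature arms supporting offset-tolerant assignment.

    The first SEED_K bases of an insert are looked up against every arm at
    every allowed 5' offset; reads whose seed carries a sequencing error
    fall back to an exhaustive scan over all arms and offsets.
    """

    def __init__(self, records: Iterable[HairpinRecord], max_offset5: int = 2,
                 max_internal_mm: int = 1, flank_limit: int = 10,
                 max_tail: int = 6, max_trim3: int = 6,
                 multimap_mode: str = "split"):
        if multimap_mode not in ("split", "unique"):
            raise ValueError("multimap_mode must be 'split' or 'unique'")
        self.max_offset5 = max_offset5
        self.max_internal_mm = max_internal_mm
        self.max_tail = max_tail
        self.max_trim3 = max_trim3
        self.multimap_mode = multimap_mode
        self.arms: list[_ArmRef] = []
        self._seed: dict[str, list[tuple[int, int]]] = {}
        self._cache: dict[str, tuple[IsomiRCall, ...]] = {}
        for rec in records:
            for arm in ("5p", "3p"):
                iv = rec.arm_interval(arm)
                if iv is None:
                    continue
                ctx = rec.sequence + rec.flank3p[:flank_limit]
                ref = _ArmRef(rec.id, arm, ctx, iv[0], iv[1])
                idx = len(self.arms)
                self.arms.append(ref)
                for off in range(-max_offset5, max_offset5 + 1):
                    s = iv[0] + off
                    if s < 0 or s + SEED_K > len(ctx):
                        continue
                    self._seed.setdefault(ctx[s: s + SEED_K], []).append((idx, off))

    def _evaluate(self, insert: str, arm_idx: int, offset5: int):
        ref = self.arms[arm_idx]
        start = ref.mature_start + offset5
        if start < 0:
            return None
        decomp = decompose_3prime(insert, ref.ctx, start, ref.mature_start,
                                  ref.mature_end, self.max_internal_mm)
        if decomp is None:
            return None
        templated3, tail, mm = decomp
        if len(tail) > self.max_tail or templated3 < -self.max_trim3:
            return None
        return (mm, abs(offset5), len(tail), offset5, templated3, tail, arm_idx)

    def _candidates(self, insert: str) -> list:
        found = []
        seen = set()
        for arm_idx, off in self._seed.get(insert[:SEED_K], ()):  # seeded
            key = (arm_idx, off)
            if key in seen:
                continue
            seen.add(key)
            cand = self._evaluate(insert, arm_idx, off)
            if cand is not None:
                found.append(cand)
        if found:
            return found
        # exhaustive fallback (seed mismatch, e.g. a sequencing error)
        for arm_idx in range(len(self.arms)):
            for off in range(-self.max_offset5, self.max_offset5 + 1):
                cand = self._evaluate(insert, arm_idx, off)
                if cand is not None:
                    found.append(cand)
        return found

    def classify(self, insert: str) -> tuple[IsomiRCall, ...]:
        """All weighted calls for one insert (cached)."""
        hit = self._cache.get(insert)
        if hit is not None:
            return hit
        cands = self._candidates(insert)
        if not cands:
            calls = _UNASSIGNED
        else:
            best_key = min(c[:3] for c in cands)
            best = [c for c in cands if c[:3] == best_key]
            best.sort(key=lambda c: (self.arms[c[6]].mirna_id, self.arms[c[6]].arm))
            if self.multimap_mode == "unique":
                best = best[:1]
            w = 1.0 / len(best)
            calls = tuple(
                IsomiRCall(
                    mirna_id=self.arms[c[6]].mirna_id,
                    arm=self.arms[c[6]].arm,
                    offset5=c[3],
                    templated3=c[4],
                    tail=c[5].replace("T", "U"),
                    internal_mismatches=c[0],
                    category=classify_category(c[3], c[4], c[5], c[0]),
                    tail_type=classify_tail(c[5]),
                    weight=w,
                )
                for c in best
            )
        self._cache[insert] = calls
        return calls


def resolve_multimap(candidates: list[IsomiRCall], mode: str = "split") -> list[IsomiRCall]:
    """Keep candidates minimizing (mismatches, |offset5|, tail length) and
    split weight equally ('split') or keep the lexicographically smallest
    miRNA id ('unique')."""
    if not candidates:
        return []
    key = lambda c: (c.internal_mismatches, abs(c.offset5), len(c.tail))
    best_key = min(key(c) for c in candidates)
    best = sorted((c for c in candidates if key(c) == best_key), key=lambda c: (c.mirna_id, c.arm))
    if mode == "unique":
        best = best[:1]
    w = 1.0 / len(best)
    return [IsomiRCall(**{**c.__dict__, "weight": w}) for c in best]


def classify_reads(table: pd.DataFrame, index: ReferenceIndex) -> pd.DataFrame:
    """Per-read call table for a (id, insert) DataFrame."""
    rows = []
    for rid, insert in zip(table["id"], table["insert"]):
        for call in index.classify(insert):
            rows.append((rid, call.mirna_id, call.arm, call.offset5, call.templated3,
                         call.tail, call.internal_mismatches, call.category,
                         call.tail_type, call.weight))
    return pd.DataFrame(rows, columns=["read_id", "mirna", "arm", "offset5", "templated3",
                                       "tail", "internal_mismatches", "category",
                                       "tail_type", "weight"])


def build_cube(insert_counts: Mapping[str, Mapping[str, int] | Counter],
               index: ReferenceIndex) -> pd.DataFrame:
    """Aggregated call cube from per-sample insert multiplicities.

    Returns long-format counts: sample, mirna, arm, category, tail_type,
    count (weighted; multimapped reads contribute fractional weight).
    Unassigned reads are included under mirna='*' so that totals are
    auditable; downstream statistics drop them.
    """
    rows: dict[tuple, float] = {}
    for sample, counter in insert_counts.items():
        for insert, n in counter.items():
            for call in index.classify(insert):
                key = (sample, call.mirna_id, call.arm, call.category, call.tail_type)
                rows[key] = rows.get(key, 0.0) + call.weight * n
    cube = pd.DataFrame(
        [(s, m, a, c, t, w) for (s, m, a, c, t), w in rows.items()],
        columns=["sample", "mirna", "arm", "category", "tail_type", "count"],
    )
    return cube.sort_values(["sample", "mirna", "arm", "category", "tail_type"]).reset_index(drop=True)


def cube_from_processed(processed: Mapping[str, pd.DataFrame], index: ReferenceIndex) -> pd.DataFrame:
    """build_cube from per-sample preprocessed read tables (kept reads)."""
    counts = {sample: Counter(df["insert"]) for sample, df in processed.items()}
    return build_cube(counts, index)
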