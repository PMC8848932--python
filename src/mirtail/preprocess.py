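"""NEXTFlex-dialect read cleanup.

3' adapter trimming, removal of the 4-nt random bases (UMIs) flanking the
insert, UMI-based PCR-duplicate collapsing, and insert length filtering.

Adapter semantics follow cutadapt's 3'-adapter model: at an internal
position the full adapter must align (mismatch budget = rate x adapter
length); truncated adapter prefixes are only considered where the read ends
inside the adapter, and must still reach ``min_overlap``. The leftmost
acceptable position wins. Reads without an adapter have an ambiguous 3' UMI
boundary and are discarded by default.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

STATUSES = ("kept", "no_adapter", "too_short", "too_long")


@dataclass(frozen=True)
class ProcessedRead:
    id: str
    insert: str
    umi5: str
    umi3: str
    status: str


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality); transparently handles .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq, qual


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.writelines(f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq, qual in reads)


def _mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _pigeonhole_chunks(adapter: str, allowed: int) -> list[tuple[str, int]]:
    """Split the adapter into allowed+1 chunks: any alignment with <= allowed
    mismatches must contain at least one chunk exactly."""
    k = allowed + 1
    n = len(adapter)
    bounds = [round(i * n / k) for i in range(k + 1)]
    return [(adapter[bounds[i]: bounds[i + 1]], bounds[i]) for i in range(k)]


def find_adapter(seq: str, adapter: str, min_overlap: int = 10,
                 max_mismatch_rate: float = 0.1) -> int:
    """Leftmost start of an acceptable adapter alignment, or -1.

    Internal positions align the full adapter; positions within the last
    len(adapter)-1 bases align the prefix the read has room for, down to
    ``min_overlap`` bases.
    """
    alen = len(adapter)
    n = len(seq)
    best = -1
    full_allowed = int(max_mismatch_rate * alen)
    # full-length windows, exact-chunk pigeonhole prefilter (C-speed find)
    last_full = n - alen
    if last_full >= 0:
        candidates: set[int] = set()
        for chunk, off in _pigeonhole_chunks(adapter, full_allowed):
            start = 0
            while True:
                hit = seq.find(chunk, start)
                if hit < 0:
                    break
                pos = hit - off
                if 0 <= pos <= last_full:
                    candidates.add(pos)
                start = hit + 1
        for pos in sorted(candidates):
            if _mismatches(seq[pos: pos + alen], adapter, full_allowed) <= full_allowed:
                best = pos
                break
    if best == 0:
        return 0
    # truncated windows at the 3' terminus (read ends inside the adapter)
    lo = max(0, n - alen + 1)
    hi = n - min_overlap
    for pos in range(lo, hi + 1):
        if best != -1 and pos >= best:
            break
        window = n - pos
        allowed = int(max_mismatch_rate * window)
        if _mismatches(seq[pos:], adapter[:window], allowed) <= allowed:
            return pos
    return best


def trim_adapter(seq: str, adapter: str, min_overlap: int = 10,
                 max_mismatch_rate: float = 0.1) -> str | None:
    """Everything 5' of the adapter match, or None when no adapter is found."""
    pos = find_adapter(seq, adapter, min_overlap, max_mismatch_rate)
    return None if pos < 0 else seq[:pos]


def strip_umis(trimmed: str, umi_length: int = 4) -> tuple[str, str, str] | None:
    """(umi5, insert, umi3); None when the read is too short to contain both
    UMIs and a non-empty insert."""
    if umi_length == 0:
        return "", trimmed, ""
    if len(trimmed) <= 2 * umi_length:
        return None
    return trimmed[:umi_length], trimmed[umi_length:-umi_length], trimmed[-umi_length:]


def process_reads(reads: Iterable[tuple[str, str, str]] | str | Path,
                  adapter: str,
                  umi_length: int = 4,
                  min_len: int = 16,
                  max_len: int = 28,
                  min_overlap: int = 10,
                  max_mismatch_rate: float = 0.1,
                  discard_untrimmed: bool = True) -> tuple[pd.DataFrame, dict]:
    """Trim + UMI-strip + length-filter a read stream.

    Returns (table, report): table has columns id, umi5, insert, umi3,
    status; the report counts every input read by status (counts are
    conserved: kept + no_adapter + too_short + too_long = input).
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    ids, u5s, inserts, u3s, statuses = [], [], [], [], []
    for rid, seq, _qual in reads:
        umi5 = umi3 = insert = ""
        # fast path: exact full adapter (leftmost); falls back to the
        # mismatch-tolerant search only when that fails
        pos = seq.find(adapter)
        if pos < 0:
            pos = find_adapter(seq, adapter, min_overlap, max_mismatch_rate)
        if pos < 0:
            if discard_untrimmed:
                status = "no_adapter"
            else:
                status, insert = "kept", seq
                parts = strip_umis(seq, umi_length)
                if parts is None:
                    status = "too_short"
                else:
                    umi5, insert, umi3 = parts
        else:
            parts = strip_umis(seq[:pos], umi_length)
            if parts is None:
                status = "too_short"
            else:
                umi5, insert, umi3 = parts
                status = "kept"
        if status == "kept":
            if len(insert) < min_len:
                status, insert, umi5, umi3 = "too_short", "", "", ""
            elif len(insert) > max_len:
                status, insert, umi5, umi3 = "too_long", "", "", ""
        ids.append(rid)
        u5s.append(umi5)
        inserts.append(insert)
        u3s.append(umi3)
        statuses.append(status)
    table = pd.DataFrame({"id": ids, "umi5": u5s, "insert": inserts, "umi3": u3s, "status": statuses})
    report = {s: 0 for s in STATUSES}
    report.update(table["status"].value_counts().to_dict())
    report["input"] = len(table)
    return table, report


def dedup_umi(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Collapse reads with identical (umi5, insert, umi3) to the first seen.

    Exact string equality only (no edit-distance UMI clustering). Input must
    be kept-status reads; returns (deduplicated table, report).
    """
    if len(table) and not (table["status"] == "kept").all():
        table = table[table["status"] == "kept"]
    before = len(table)
    deduped = table.drop_duplicates(subset=["umi5", "insert", "umi3"], keep="first")
    after = len(deduped)
    rate = (before - after) / before if before else 0.0
    return deduped.reset_index(drop=True), {"input": before, "kept": after, "duplication_rate": rate}


def length_filter(table: pd.DataFrame, min_len: int = 16, max_len: int = 28) -> pd.DataFrame:
    """Re-filter kept reads by insert length (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    lengths = table["insert"].str.len()
    out = table.copy()
    kept = out["status"] == "kept"
    out.loc[kept & (lengths < min_len), "status"] = "too_short"
    out.loc[kept & (lengths > max_len), "status"] = "too_long"
    return out[out["status"] == "kept"].reset_index(drop=True)


def preprocess_sample(fastq: str | Path | Iterable[tuple[str, str, str]],
                      adapter: str, **kwargs) -> tuple[pd.DataFrame, dict]:
    """process_reads + dedup_umi; returns (deduplicated kept reads, report)."""
    table, report = process_reads(fastq, adapter, **kwargs)
    deduped, dedup_report = dedup_umi(table[table["status"] == "kept"])
    report["dedup"] = dedup_report
    return deduped, report
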