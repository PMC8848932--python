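"""miRNA hairpin reference handling.

A pre-miRNA hairpin carries up to two mature arms: a 5p mature miRNA on the
5' strand and a 3p mature miRNA on the 3' strand, separated by the terminal
loop. Coordinates in the on-disk table are 1-based inclusive (miRBase GFF
convention); internally everything is 0-based half-open. Sequences are
normalized to a single DNA alphabet (U -> T) so that references and
sequencing reads live in the same space.

Also provides classification of let-7-like precursors along two independent
axes: Group I vs II (2-nt vs 1-nt 3' overhang after Drosha processing,
annotation-supplied because the overhang cannot be derived from sequence
alone) and CSD+/- (presence of the (U)GAU motif bound by the cold-shock
domain of LIN28A, scanned in the loop by default).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

Interval = tuple[int, int]  # 0-based, half-open

ARMS = ("5p", "3p")

# (U)GAU: the leading U is conventionally optional, so presence of GAU
# (GAT in DNA space) is what is actually tested.
CSD_MOTIF = re.compile("T?GAT")

_VALID_BASES = set("ACGTN")


class ReferenceError(ValueError):
    """Invalid reference input (missing ids, bad intervals, bad alphabet)."""


def normalize_seq(seq: str) -> str:
    """Uppercase and map U->T; reject characters outside {A,C,G,T,U,N}."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_BASES
    if bad:
        raise ReferenceError(f"invalid characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class HairpinRecord:
    """A miRNA precursor with optional mature-arm intervals.

    ``flank3p`` is downstream genomic sequence used to distinguish templated
    3' extension from nontemplated tailing past the hairpin end.
    """

    id: str
    sequence: str
    mature5p: Interval | None = None
    mature3p: Interval | None = None
    mature5p_id: str | None = None
    mature3p_id: str | None = None
    flank3p: str = ""
    family: str = ""

    @property
    def loop(self) -> Interval | None:
        """Region between the two arms; None unless both arms are present."""
        if self.mature5p is None or self.mature3p is None:
            return None
        return (self.mature5p[1], self.mature3p[0])

    def loop_seq(self) -> str | None:
        lp = self.loop
        if lp is None:
            return None
        return self.sequence[lp[0]: lp[1]]

    def arm_interval(self, arm: str) -> Interval | None:
        if arm == "5p":
            return self.mature5p
        if arm == "3p":
            return self.mature3p
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")

    def mature_seq(self, arm: str) -> str | None:
        iv = self.arm_interval(arm)
        if iv is None:
            return None
        return self.sequence[iv[0]: iv[1]]

    def mature_name(self, arm: str) -> str:
        explicit = self.mature5p_id if arm == "5p" else self.mature3p_id
        return explicit or f"{self.id}-{arm}"


@dataclass(frozen=True)
class Let7Annotation:
    """Group I/II (overhang) and CSD+/- (LIN28A motif) annotation."""

    mirna_id: str
    group: str  # "I" | "II"
    csd: str = "unknown"  # "plus" | "minus" | "unknown"

    def __post_init__(self):
        if self.group not in ("I", "II"):
            raise ReferenceError(f"group must be I or II, got {self.group!r}")
        if self.csd not in ("plus", "minus", "unknown"):
            raise ReferenceError(f"csd must be plus/minus/unknown, got {self.csd!r}")


def _validate_interval(hairpin_id: str, arm: str, start: int, end: int, seqlen: int) -> Interval:
    # start/end arrive 1-based inclusive
    if start < 1 or end < start:
        raise ReferenceError(f"{hairpin_id}/{arm}: interval [{start},{end}] does not parse as a positive 1-based interval")
    if end > seqlen:
        raise ReferenceError(f"{hairpin_id}/{arm}: interval [{start},{end}] out of bounds for length {seqlen}")
    return (start - 1, end)


def load_reference(hairpin_fasta: str | Path, coords_table: str | Path) -> list[HairpinRecord]:
    """Load hairpins (FASTA) plus a mature-arm coordinate table (TSV).

    Table columns: hairpin_id, arm (5p|3p), start, end [, mature_id, family,
    flank3p]. Coordinates are 1-based inclusive. Records with neither arm are
    skipped (logged); a table row naming an unknown hairpin, or an interval
    outside the sequence, is a hard error.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(hairpin_fasta), "fasta"):
        seqs[rec.id] = normalize_seq(str(rec.seq))

    table = pd.read_csv(coords_table, sep="\t", dtype={"hairpin_id": str})
    required = {"hairpin_id", "arm", "start", "end"}
    missing = required - set(table.columns)
    if missing:
        raise ReferenceError(f"coordinate table missing columns: {sorted(missing)}")

    per_hairpin: dict[str, dict] = {hid: {} for hid in seqs}
    for row in table.itertuples(index=False):
        hid = str(row.hairpin_id)
        if hid not in seqs:
            raise ReferenceError(f"coordinate table references unknown hairpin id {hid!r}")
        arm = str(row.arm)
        if arm not in ARMS:
            raise ReferenceError(f"{hid}: arm must be 5p or 3p, got {arm!r}")
        iv = _validate_interval(hid, arm, int(row.start), int(row.end), len(seqs[hid]))
        info = per_hairpin[hid]
        info[f"mature{arm}"] = iv
        mature_id = getattr(row, "mature_id", None)
        if mature_id is not None and not pd.isna(mature_id):
            info[f"mature{arm}_id"] = str(mature_id)
        fam = getattr(row, "family", None)
        if fam is not None and not pd.isna(fam):
            info["family"] = str(fam)
        flank = getattr(row, "flank3p", None)
        if flank is not None and not pd.isna(flank) and str(flank):
            info["flank3p"] = normalize_seq(str(flank))

    records: list[HairpinRecord] = []
    skipped: list[str] = []
    for hid, seq in seqs.items():
        info = per_hairpin[hid]
        m5, m3 = info.get("mature5p"), info.get("mature3p")
        if m5 is None and m3 is None:
            skipped.append(hid)
            continue
        if m5 is not None and m3 is not None:
            if not m5[1] <= m3[0] - 1:
                raise ReferenceError(f"{hid}: 5p arm must end before 3p arm starts (loop must be non-empty)")
        records.append(
            HairpinRecord(
                id=hid,
                sequence=seq,
                mature5p=m5,
                mature3p=m3,
                mature5p_id=info.get("mature5p_id"),
                mature3p_id=info.get("mature3p_id"),
                flank3p=info.get("flank3p", ""),
                family=info.get("family", ""),
            )
        )
    if skipped:
        log.warning("skipped %d hairpins with no annotated mature arm: %s", len(skipped), ", ".join(skipped))
    return records


def write_reference(records: list[HairpinRecord], hairpin_fasta: str | Path, coords_table: str | Path) -> None:
    """Inverse of load_reference (round-trips exactly)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(hairpin_fasta), "fasta")
    rows = []
    for r in records:
        for arm in ARMS:
            iv = r.arm_interval(arm)
            if iv is None:
                continue
            rows.append(
                {
                    "hairpin_id": r.id,
                    "arm": arm,
                    "start": iv[0] + 1,
                    "end": iv[1],
                    "mature_id": r.mature_name(arm),
                    "family": r.family,
                    "flank3p": r.flank3p,
                }
            )
    pd.DataFrame(rows).to_csv(coords_table, sep="\t", index=False)


def scan_csd_motif(record: HairpinRecord, region: str = "loop") -> str:
    """Scan for the LIN28A cold-shock-domain (U)GAU motif.

    Returns "plus"/"minus"; "unknown" when region="loop" and the loop cannot
    be derived (single-arm record). region="precursor" scans the whole
    hairpin instead.
    """
    if region == "precursor":
        target = record.sequence
    elif region == "loop":
        target = record.loop_seq()
        if target is None:
            return "unknown"
    else:
        raise ValueError("region must be 'loop' or 'precursor'")
    return "plus" if CSD_MOTIF.search(target) else "minus"


def classify_let7(record: HairpinRecord, annotation: Let7Annotation | None) -> str | None:
    """Joint Group {I,II} x CSD {+,-} class label, e.g. "Group II / CSD+".

    The motif scan fills in csd only when the annotation leaves it unknown.
    Returns None (unclassified) when no annotation is available.
    """
    if annotation is None:
        log.info("no let-7 annotation for %s; unclassified", record.id)
        return None
    csd = annotation.csd
    if csd == "unknown":
        csd = scan_csd_motif(record)
    if csd == "unknown":
        return None
    sign = "+" if csd == "plus" else "-"
    return f"Group {annotation.group} / CSD{sign}"


def load_let7_annotations(path: str | Path) -> dict[str, Let7Annotation]:
    """TSV with columns mirna_id, group, csd."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for row in table.itertuples(index=False):
        ann = Let7Annotation(mirna_id=str(row.mirna_id), group=str(row.group), csd=str(getattr(row, "csd", "unknown")))
        out[ann.mirna_id] = ann
    return out


def write_let7_annotations(annotations: dict[str, Let7Annotation], path: str | Path) -> None:
    rows = [{"mirna_id": a.mirna_id, "group": a.group, "csd": a.csd} for a in annotations.values()]
    pd.DataFrame(rows, columns=["mirna_id", "group", "csd"]).to_csv(path, sep="\t", index=False)
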