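"""Barcode extraction and error-correction from FASTQ reads.

Turns raw sequencing reads of the semi-random barcode amplicon into clean
per-sample barcode count tables.  A read is accepted when

1. both fixed flanks match at their anchored positions with at most one
   mismatch each (no indels: the library architecture is fixed-length);
2. the 30-nt barcode contains no N;
3. every barcode base has quality >= ``min_quality`` (default Q20);
4. the barcode obeys the weak/strong pattern (weak positions A/T, strong
   positions C/G).

Rejections are tagged ``flank_miss``, ``N_base``, ``low_quality`` or
``pattern_violation`` (checked in that order) and counted, so that accepted
plus rejected reads always equal the input reads.

Sequencing errors surviving the pattern filter are removed by a greedy
abundance-ordered collapse: barcodes within Hamming distance ``max_hamming``
(default 2) of an already-accepted, more abundant barcode are merged into
it, conserving total counts.
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .synth_assets import ReadSpec

__all__ = [
    "ReadRecord",
    "BarcodeCountTable",
    "read_fastq",
    "extract_barcode",
    "collapse",
    "build_count_table",
    "write_count_tables",
    "read_count_tables",
]

REJECT_REASONS = ("flank_miss", "N_base", "low_quality", "pattern_violation")


@dataclass
class ReadRecord:
    """One sequencing read: id, bases and per-base Phred scores."""

    id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class BarcodeCountTable:
    """Per-sample barcode read counts with gate/timepoint metadata."""

    sample_id: str
    day: float
    gate: str                      # 'H', 'L' or 'presort'
    replicate: int
    counts: pd.Series              # barcode string -> read count
    n_reads_in: int = 0
    n_rejected: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gate not in ("H", "L", "presort"):
            raise ValueError(f"invalid gate {self.gate!r}")
        self.counts = self.counts.astype(np.int64)
        if (self.counts <= 0).any():
            raise ValueError("counts must be positive integers")
        accepted = int(self.counts.sum())
        rejected = int(sum(self.n_rejected.values()))
        if self.n_reads_in and accepted + rejected != self.n_reads_in:
            raise ValueError("accepted + rejected reads must equal input reads")


def read_fastq(path) -> list[ReadRecord]:
    """Load a FASTQ file (gzip transparent) into ReadRecords."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    out = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            out.append(ReadRecord(rec.id, str(rec.seq),
                                  np.array(rec.letter_annotations["phred_quality"])))
    return out


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_barcode(
    read: ReadRecord,
    spec: ReadSpec,
    min_quality: int = 20,
) -> tuple[str | None, str | None]:
    """Extract the barcode from one read, or reject it with a reason.

    Returns ``(barcode, None)`` on acceptance or ``(None, reason)`` with
    reason in ``REJECT_REASONS``.
    """
    seq = read.sequence.upper()
    f5, f3 = spec.flank_5prime, spec.flank_3prime
    start = spec.barcode_start
    end = start + spec.barcode_length
    if len(seq) < end + len(f3):
        return None, "flank_miss"
    if _mismatches(seq[:len(f5)], f5) > 1 or _mismatches(seq[end:end + len(f3)], f3) > 1:
        return None, "flank_miss"

    bc = seq[start:end]
    if "N" in bc:
        return None, "N_base"
    if read.qualities[start:end].min() < min_quality:
        return None, "low_quality"
    for base, cls in zip(bc, spec.ws_pattern):
        if base not in ("AT" if cls == "W" else "CG"):
            return None, "pattern_violation"
    return bc, None


# ---------------------------------------------------------------------------
# Error-correction collapse
# ---------------------------------------------------------------------------


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def collapse(raw_counts: pd.Series, max_hamming: int = 2) -> pd.Series:
    """Greedy abundance-ordered merge of near-duplicate barcodes.

    Barcodes are visited in descending count (ties broken lexicographically).
    A barcode within Hamming distance ``max_hamming`` of an already-accepted
    barcode is merged into the most abundant such acceptor (ties again
    lexicographic); otherwise it is accepted itself.  Total count is
    conserved exactly and the output barcodes are mutually more than
    ``max_hamming`` apart, which makes the operation idempotent.

    Candidate acceptors are found with a pigeonhole index: the barcode is cut
    into ``max_hamming + 1`` segments, and any barcode within the radius
    must match at least one segment exactly.
    """
    raw_counts = raw_counts[raw_counts > 0]
    if len(raw_counts) == 0:
        return raw_counts.astype(np.int64)
    lengths = {len(b) for b in raw_counts.index}
    if len(lengths) != 1:
        raise ValueError(f"mixed barcode lengths: {sorted(lengths)}")
    (bc_len,) = lengths

    order = sorted(raw_counts.index, key=lambda b: (-raw_counts[b], b))
    enc = {b: np.frombuffer(b.encode(), dtype=np.uint8) for b in order}

    n_seg = max_hamming + 1
    bounds = np.linspace(0, bc_len, n_seg + 1, dtype=int)
    seg_index: list[dict[bytes, list[str]]] = [defaultdict(list) for _ in range(n_seg)]

    merged: dict[str, int] = {}
    original = raw_counts.to_dict()
    for b in order:
        cand: set[str] = set()
        for s in range(n_seg):
            key = b[bounds[s]:bounds[s + 1]].encode()
            cand.update(seg_index[s][key])
        hits = [a for a in cand if _hamming(enc[b], enc[a]) <= max_hamming]
        if hits:
            acceptor = min(hits, key=lambda a: (-original[a], a))
            merged[acceptor] += original[b]
        else:
            merged[b] = original[b]
            for s in range(n_seg):
                seg_index[s][b[bounds[s]:bounds[s + 1]].encode()].append(b)

    out = pd.Series(merged, dtype=np.int64).sort_index()
    assert int(out.sum()) == int(raw_counts.sum())
    return out


# ---------------------------------------------------------------------------
# Per-sample tables
# ---------------------------------------------------------------------------


def build_count_table(
    manifest: pd.DataFrame,
    spec: ReadSpec | None = None,
    min_quality: int = 20,
    max_hamming: int = 2,
    reads_by_file: dict[str, list[ReadRecord]] | None = None,
) -> list[BarcodeCountTable]:
    """Extract and collapse barcodes for every sample in a manifest.

    ``manifest`` needs columns file, sample_id, day, gate, replicate.  Reads
    are taken from FASTQ files on disk, or from ``reads_by_file`` (keyed by
    the manifest 'file' value) when running in-memory.
    """
    spec = spec or ReadSpec()
    required = {"file", "sample_id", "day", "gate", "replicate"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if reads_by_file is None:
        absent = [f for f in manifest["file"] if not Path(f).exists()]
        if absent:
            raise FileNotFoundError(f"manifest FASTQ files not found: {absent}")

    tables = []
    for row in manifest.itertuples(index=False):
        reads = (reads_by_file[row.file] if reads_by_file is not None
                 else read_fastq(row.file))
        counts: dict[str, int] = defaultdict(int)
        rejected = dict.fromkeys(REJECT_REASONS, 0)
        for r in reads:
            bc, reason = extract_barcode(r, spec, min_quality)
            if bc is None:
                rejected[reason] += 1
            else:
                counts[bc] += 1
        raw = pd.Series(counts, dtype=np.int64)
        collapsed = collapse(raw, max_hamming) if len(raw) else raw
        tables.append(BarcodeCountTable(
            sample_id=str(row.sample_id), day=float(row.day), gate=str(row.gate),
            replicate=int(row.replicate), counts=collapsed,
            n_reads_in=len(reads), n_rejected=rejected,
        ))
    return tables


def write_count_tables(tables: list[BarcodeCountTable], path) -> None:
    """Write tables in the long CSV dialect.

    Columns: sample_id, day, gate, replicate, barcode, count.
    """
    rows = []
    for t in tables:
        for bc, c in t.counts.items():
            rows.append((t.sample_id, t.day, t.gate, t.replicate, bc, int(c)))
    pd.DataFrame(rows, columns=["sample_id", "day", "gate", "replicate",
                                "barcode", "count"]).to_csv(path, index=False)


def read_count_tables(path) -> list[BarcodeCountTable]:
    """Read the long CSV dialect back into per-sample tables."""
    df = pd.read_csv(path, dtype={"barcode": str})
    tables = []
    keys = ["sample_id", "day", "gate", "replicate"]
    for (sid, day, gate, rep), grp in df.groupby(keys, sort=True):
        counts = pd.Series(grp["count"].to_numpy(np.int64),
                           index=grp["barcode"].to_numpy())
        tables.append(BarcodeCountTable(str(sid), float(day), str(gate),
                                        int(rep), counts))
    return tables
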