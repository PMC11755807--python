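"""piRNA quantification from small-RNA reads under strict matching rules.

The stage chain is: adapter trimming with UMI extraction, insert length
filter (24-34 nt inclusive), exact full-length matching against a piRNA
reference (100% identity, identical length, no reverse complement), and
UMI deduplication with the directional network method.  Counts are keyed
by unique reference sequence: identifiers sharing a sequence (a common
redundancy in piRNA databases) are reported together under a
lexicographically smallest representative, so one molecule is never
counted against several duplicate database entries.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from piwiflow.containers import IntegrityError, PiwiflowError
from piwiflow.synthcohort import DEFAULT_ADAPTER, DEFAULT_UMI_LEN

MIN_INSERT_LEN = 24
MAX_INSERT_LEN = 34

STAGES = ("input", "trimmed", "length_pass", "matched", "deduplicated")


class FastqParseError(PiwiflowError):
    """Malformed FASTQ; the message carries the record index."""


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


class PiRNAReference:
    """piRNA reference with U->T normalization and sequence-level grouping.

    Parameters
    ----------
    sequences
        Mapping from piRNA identifier to nucleotide sequence (A/C/G/T/U).
    """

    def __init__(self, sequences: dict[str, str]):
        if len(sequences) == 0:
            raise IntegrityError("empty piRNA reference")
        self.id_to_seq: dict[str, str] = {}
        for pid, seq in sequences.items():
            if not seq:
                raise IntegrityError(f"empty sequence for reference identifier {pid!r}")
            self.id_to_seq[pid] = _normalize(seq)
        if len(self.id_to_seq) != len(sequences):
            raise IntegrityError("duplicate identifiers in piRNA reference")
        self.seq_to_ids: dict[str, list[str]] = {}
        for pid, seq in self.id_to_seq.items():
            self.seq_to_ids.setdefault(seq, []).append(pid)
        for seq in self.seq_to_ids:
            self.seq_to_ids[seq].sort()

    @classmethod
    def from_fasta(cls, path: str | Path) -> "PiRNAReference":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
        return cls(seqs)

    def representative(self, seq: str) -> str:
        return self.seq_to_ids[seq][0]

    def __len__(self) -> int:
        return len(self.id_to_seq)


@dataclass
class SmallRNARead:
    read_id: str
    raw: str
    insert: str | None = None
    umi: str | None = None
    trimmed_ok: bool = False
    length_ok: bool = False
    matched_seq: str | None = None


@dataclass
class PiRNACounts:
    """Per-unique-sequence raw and deduplicated counts plus stage attrition."""

    entries: dict[str, dict] = field(default_factory=dict)
    attrition: dict[str, int] = field(default_factory=lambda: {s: 0 for s in STAGES})

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "representative_id": e["representative_id"],
                "all_ids": ",".join(e["all_ids"]),
                "sequence": seq,
                "raw_count": e["raw_count"],
                "dedup_count": e["dedup_count"],
            }
            for seq, e in sorted(self.entries.items(), key=lambda kv: kv[1]["representative_id"])
        ]
        return pd.DataFrame(rows, columns=["representative_id", "all_ids", "sequence", "raw_count", "dedup_count"])


def trim_and_extract(
    read_id: str, raw: str, adapter: str = DEFAULT_ADAPTER, umi_len: int = DEFAULT_UMI_LEN
) -> SmallRNARead:
    """Locate the leftmost adapter occurrence; insert = bases before it,
    UMI = the ``umi_len`` bases immediately after it.  Extraction fails
    (flagged, not raised) if the adapter is absent or fewer than
    ``umi_len`` bases follow it."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    raw = _normalize(raw)
    read = SmallRNARead(read_id=read_id, raw=raw)
    pos = raw.find(_normalize(adapter))
    if pos < 0:
        return read
    tail = raw[pos + len(adapter):]
    if len(tail) < umi_len:
        return read
    read.insert = raw[:pos]
    read.umi = tail[:umi_len]
    read.trimmed_ok = True
    return read


def length_filter(read: SmallRNARead, min_len: int = MIN_INSERT_LEN, max_len: int = MAX_INSERT_LEN) -> bool:
    """Inclusive insert-length filter (default 24-34 nt)."""
    if read.insert is None:
        raise ValueError("length_filter requires a read with a defined insert")
    read.length_ok = min_len <= len(read.insert) <= max_len
    return read.length_ok


def exact_match(insert: str, reference: PiRNAReference) -> str | None:
    """Return the unique reference sequence equal to the insert
    character-for-character and length-for-length (after U->T
    normalization), or None.  Inserts with any non-ACGT character never
    match; reverse complements are not considered."""
    insert = _normalize(insert)
    if not insert or any(c not in "ACGT" for c in insert):
        return None
    return insert if insert in reference.seq_to_ids else None


def _hamming1(a: str, b: str) -> bool:
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def umi_dedup(umis: Iterable[str], method: str = "directional") -> int:
    """Collapse UMIs of one sequence group into molecule counts.

    ``directional`` builds the directed network with an edge a -> b when
    Hamming(a, b) = 1 and count(a) >= 2*count(b) - 1, then counts cluster
    roots (the UMI-tools default).  ``unique`` counts distinct UMIs.
    """
    counts = Counter(umis)
    if not counts:
        return 0
    lens = {len(u) for u in counts}
    if len(lens) != 1:
        raise IntegrityError(f"mixed UMI lengths within one sequence group: {sorted(lens)}")
    if method == "unique":
        return len(counts)
    if method != "directional":
        raise ValueError(f"unknown dedup method {method!r}")
    # adjacency under the directional rule
    umis_sorted = sorted(counts, key=lambda u: (-counts[u], u))
    children: dict[str, list[str]] = {u: [] for u in umis_sorted}
    for a in umis_sorted:
        for b in umis_sorted:
            if a != b and counts[a] >= 2 * counts[b] - 1 and _hamming1(a, b):
                children[a].append(b)
    visited: set[str] = set()
    n_clusters = 0
    for root in umis_sorted:  # descending count: larger nodes claim clusters first
        if root in visited:
            continue
        n_clusters += 1
        stack = [root]
        visited.add(root)
        while stack:
            u = stack.pop()
            for v in children[u]:
                if v not in visited:
                    visited.add(v)
                    stack.append(v)
    return n_clusters


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    opener = gzip.open if str(path).endswith(".gz") else open
    idx = 0
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, _qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ record at index {idx} in {path}: {exc}") from exc
            yield title.split()[0], seq
            idx += 1


def quantify(
    fastq: str | Path,
    reference: PiRNAReference | str | Path,
    adapter: str = DEFAULT_ADAPTER,
    umi_len: int = DEFAULT_UMI_LEN,
    min_len: int = MIN_INSERT_LEN,
    max_len: int = MAX_INSERT_LEN,
    dedup_method: str = "directional",
) -> PiRNACounts:
    """Run the full stage chain on one FASTQ and return per-sequence counts
    with the per-stage read-attrition tally."""
    if not isinstance(reference, PiRNAReference):
        reference = PiRNAReference.from_fasta(reference)
    result = PiRNACounts()
    att = result.attrition
    umis_by_seq: dict[str, list[str]] = {}
    for read_id, raw in _iter_fastq(fastq):
        att["input"] += 1
        read = trim_and_extract(read_id, raw, adapter=adapter, umi_len=umi_len)
        if not read.trimmed_ok:
            continue
        att["trimmed"] += 1
        if not length_filter(read, min_len=min_len, max_len=max_len):
            continue
        att["length_pass"] += 1
        hit = exact_match(read.insert, reference)
        if hit is None:
            continue
        att["matched"] += 1
        umis_by_seq.setdefault(hit, []).append(read.umi)
    for seq, umis in umis_by_seq.items():
        dedup = umi_dedup(umis, method=dedup_method)
        result.entries[seq] = {
            "representative_id": reference.representative(seq),
            "all_ids": reference.seq_to_ids[seq],
            "raw_count": len(umis),
            "dedup_count": dedup,
        }
        att["deduplicated"] += dedup
    return result
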