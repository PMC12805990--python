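"""Barcode-variant association from paired-end plasmid sequencing.

The association amplicon covers both the variant window and the barcode.
Read pairs are merged on their overlap, the window and barcode are read off
by exact anchor matching (any mismatch in fixed sequence rejects the read),
and a barcode -> variant dictionary is built after three filters:

1. (barcode, variant) pairs observed fewer than ``min_pair_reads`` times
   (default 10) are excluded;
2. barcodes still observed with two or more distinct variants are discarded
   (a dictionary keyed by barcode cannot hold two variants; discarding is
   the conservative choice);
3. variants left with fewer than ``min_barcodes_per_variant`` (default 5)
   distinct barcodes are dropped.
"""

from __future__ import annotations

import gzip
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .designs import (
    ConstructTemplate,
    DEFAULT_TEMPLATE,
    LibraryDesign,
    WindowMismatchError,
    BARCODE_LENGTH,
    is_valid_barcode,
    reverse_complement,
    variant_key,
)

__all__ = [
    "merge_pairs",
    "extract_pair",
    "build_barcode_map",
    "associate_fastq",
    "BarcodeMap",
    "MIN_OVERLAP",
    "MAX_MISMATCH_FRAC",
]

MIN_OVERLAP = 6
MAX_MISMATCH_FRAC = 0.08


def _open_text(path):
    if os.fspath(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality) records from FASTQ(.gz)."""
    with _open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def merge_pairs(read1: tuple[str, str], read2: tuple[str, str],
                min_overlap: int = MIN_OVERLAP,
                max_mismatch_frac: float = MAX_MISMATCH_FRAC) -> str | None:
    """Join an overlapping read pair into one sequence, or return None.

    ``read2`` is reverse-complemented, then the longest 3'(R1)/5'(R2)
    overlap of at least ``min_overlap`` bases with a mismatch fraction at
    most ``max_mismatch_frac`` is taken.  At disagreeing overlap positions
    the base with the higher quality wins (R1 on ties).
    """
    seq1, qual1 = read1
    seq2, qual2 = read2
    seq2 = reverse_complement(seq2)
    qual2 = qual2[::-1]
    n1, n2 = len(seq1), len(seq2)
    arr1 = np.frombuffer(seq1.encode(), dtype=np.uint8)
    arr2 = np.frombuffer(seq2.encode(), dtype=np.uint8)
    for ov in range(min(n1, n2), min_overlap - 1, -1):
        mismatches = int((arr1[n1 - ov:] != arr2[:ov]).sum())
        if mismatches <= max_mismatch_frac * ov:
            a = seq1[n1 - ov:]
            b = seq2[:ov]
            if mismatches == 0:
                overlap = a
            else:
                qa = qual1[n1 - ov:]
                qb = qual2[:ov]
                overlap = "".join(
                    x if (x == y or qx >= qy) else y
                    for x, y, qx, qy in zip(a, b, qa, qb))
            return seq1[:n1 - ov] + overlap + seq2[ov:]
    return None


def extract_pair(merged: str, design: LibraryDesign,
                 template: ConstructTemplate = DEFAULT_TEMPLATE,
                 ) -> tuple[tuple[str, str] | None, str]:
    """Read (variant key, barcode) off a merged read by exact matching.

    Locates the promoter fragment by its sequence upstream of the variant
    window, then requires every fixed base of the construct — the rest of
    the promoter fragment, the minimal promoter + synJ + ATG spacer and the
    start of the reporter ORF — to match exactly.  Returns
    ``((key, barcode), "ok")`` or ``(None, reason)`` with reason one of
    ``"anchor"``, ``"window"``, ``"barcode"``.
    """
    ws = design.window_start
    upstream = design.context[:ws]
    i = merged.find(upstream)
    if i < 0:
        return None, "anchor"
    prom = i  # construct start
    window = merged[prom + ws: prom + ws + 10]
    bc_off = prom + template.barcode_offset
    anchor3_end = bc_off + BARCODE_LENGTH + len(template.rna_anchor3)
    if len(merged) < anchor3_end or len(window) < 10:
        return None, "anchor"
    # fixed context downstream of the window, then the spacer segment
    if merged[prom + ws + 10: prom + 50] != design.context[ws + 10:]:
        return None, "anchor"
    if merged[prom + 50: prom + 50 + len(template.fixed_spacer)] != \
            template.fixed_spacer:
        return None, "anchor"
    if merged[bc_off + BARCODE_LENGTH: anchor3_end] != template.rna_anchor3:
        return None, "anchor"
    try:
        key = variant_key(window, design)
    except WindowMismatchError:
        return None, "window"
    except Exception:
        return None, "window"
    barcode = merged[bc_off: bc_off + BARCODE_LENGTH]
    if not is_valid_barcode(barcode):
        return None, "barcode"
    return (key, barcode), "ok"


@dataclass
class BarcodeMap:
    """Validated barcode -> variant assignments with association counts.

    ``entries`` has one row per retained barcode with columns ``barcode``,
    ``key`` and ``n_reads`` (association read count, used later as the
    input-DNA abundance).  ``report`` carries the accounting numbers.
    """

    entries: pd.DataFrame
    min_pair_reads: int
    min_barcodes_per_variant: int
    report: dict = field(default_factory=dict)

    @property
    def barcode_to_key(self) -> dict[str, str]:
        return dict(zip(self.entries["barcode"], self.entries["key"]))

    @property
    def variants(self) -> list[str]:
        return sorted(self.entries["key"].unique())

    @property
    def n_barcodes(self) -> int:
        return len(self.entries)

    def barcodes_of(self, key: str) -> list[str]:
        return self.entries.loc[self.entries["key"] == key, "barcode"].tolist()

    def write(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, min_pair_reads: int = 10,
             min_barcodes_per_variant: int = 5) -> "BarcodeMap":
        entries = pd.read_csv(path, sep="\t",
                              dtype={"barcode": str, "key": str})
        return cls(entries=entries, min_pair_reads=min_pair_reads,
                   min_barcodes_per_variant=min_barcodes_per_variant)


def build_barcode_map(pairs: Iterable[tuple[str, str]],
                      min_pair_reads: int = 10,
                      min_barcodes: int = 5) -> BarcodeMap:
    """Count (variant, barcode) observations and apply the three filters.

    ``pairs`` is a stream of (variant key, barcode) observations, e.g. from
    :func:`extract_pair`.  Filter order: pair read-count filter, then
    collision removal, then the per-variant barcode-count filter.
    """
    counts = Counter(pairs)
    n_pairs_observed = len(counts)
    kept = {pair: n for pair, n in counts.items() if n >= min_pair_reads}

    by_barcode: dict[str, list[tuple[str, int]]] = {}
    for (key, barcode), n in kept.items():
        by_barcode.setdefault(barcode, []).append((key, n))
    unique = {bc: kv[0] for bc, kv in by_barcode.items() if len(kv) == 1}
    n_collisions = sum(1 for kv in by_barcode.values() if len(kv) > 1)

    per_variant: dict[str, list[tuple[str, int]]] = {}
    for bc, (key, n) in unique.items():
        per_variant.setdefault(key, []).append((bc, n))
    retained = {key: bcs for key, bcs in per_variant.items()
                if len(bcs) >= min_barcodes}

    rows = [(bc, key, n)
            for key in sorted(retained)
            for bc, n in sorted(retained[key])]
    entries = pd.DataFrame(rows, columns=["barcode", "key", "n_reads"])
    report = {
        "pairs_observed": n_pairs_observed,
        "pairs_passing_read_filter": len(kept),
        "barcode_collisions_removed": n_collisions,
        "barcodes_detected": len(entries),
        "variants_associated": len(retained),
    }
    return BarcodeMap(entries=entries, min_pair_reads=min_pair_reads,
                      min_barcodes_per_variant=min_barcodes, report=report)


def associate_fastq(r1_path, r2_path, design: LibraryDesign,
                    template: ConstructTemplate = DEFAULT_TEMPLATE,
                    min_pair_reads: int = 10, min_barcodes: int = 5,
                    min_overlap: int = MIN_OVERLAP,
                    max_mismatch_frac: float = MAX_MISMATCH_FRAC) -> BarcodeMap:
    """Full association stage: merge pairs, extract, filter, map.

    Reads failing merge or extraction are tallied by reason in the map's
    report so the library accounting stays auditable.
    """
    tally = Counter()
    observations: list[tuple[str, str]] = []
    # sequencing duplicates dominate amplicon data; cache merge+extract
    cache: dict[tuple, tuple] = {}
    for (n1, s1, q1), (n2, s2, q2) in zip(read_fastq(r1_path),
                                          read_fastq(r2_path)):
        item = (s1, q1, s2, q2)
        result = cache.get(item)
        if result is None:
            merged = merge_pairs((s1, q1), (s2, q2), min_overlap=min_overlap,
                                 max_mismatch_frac=max_mismatch_frac)
            if merged is None:
                result = (None, "merge_failed")
            else:
                result = extract_pair(merged, design, template)
            cache[item] = result
        pair, reason = result
        if pair is None:
            tally["merge_failed" if reason == "merge_failed"
                  else f"reject_{reason}"] += 1
            continue
        tally["extracted"] += 1
        observations.append(pair)
    bc_map = build_barcode_map(observations, min_pair_reads=min_pair_reads,
                               min_barcodes=min_barcodes)
    bc_map.report.update(tally)
    return bc_map
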