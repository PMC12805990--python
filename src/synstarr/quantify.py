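"""Barcode counting and per-variant transcriptional strength.

Transcriptional strength of a variant in an RNA sample is

    log2( (sum of its barcodes' RNA CPM + 1) / (sum of its barcodes' DNA CPM + 1) )

where CPM is counts per million within a sample, the input-DNA abundance is
the association-sequencing read count of each barcode, and the +1
pseudocount keeps strengths finite.  Variants with mean control strength
above 0 are classed ``high``, the rest ``low``.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import BarcodeMap, read_fastq
from .designs import ConstructTemplate, DEFAULT_TEMPLATE, is_valid_barcode
from .simulate import DNA_SAMPLE

__all__ = [
    "extract_rna_barcodes",
    "count_rna_barcodes",
    "attach_dna_column",
    "apply_min_reads",
    "variant_strength",
    "replicate_pcc",
    "classify_and_rank",
    "condition_of",
]


def condition_of(sample: str) -> str:
    """Condition label of an RNA sample column named ``<condition>_<rep>``."""
    return sample.rsplit("_", 1)[0]


def extract_rna_barcodes(fastq_path,
                         template: ConstructTemplate = DEFAULT_TEMPLATE,
                         ) -> Counter:
    """Count barcodes in one RNA sample by exact anchor matching.

    The barcode is the 12-mer between the synJ/ATG junction and the start
    of the reporter ORF; reads whose anchors or barcode pattern do not
    match exactly are counted under ``None``.
    """
    a5, a3 = template.rna_anchor5, template.rna_anchor3
    counts: Counter = Counter()
    for _, seq, _ in read_fastq(fastq_path):
        i = seq.find(a5)
        if i < 0:
            counts[None] += 1
            continue
        start = i + len(a5)
        barcode = seq[start:start + 12]
        tail = seq[start + 12:start + 12 + len(a3)]
        if tail != a3 or not is_valid_barcode(barcode):
            counts[None] += 1
            continue
        counts[barcode] += 1
    return counts


def count_rna_barcodes(sample_fastqs: dict[str, object], bc_map: BarcodeMap,
                       min_reads: int = 5,
                       template: ConstructTemplate = DEFAULT_TEMPLATE,
                       ) -> pd.DataFrame:
    """Build the barcode x sample RNA count matrix from FASTQ files.

    ``sample_fastqs`` maps sample name (``ctrl_1`` ... ``aba_n``) to a FASTQ
    path.  Cells with fewer than ``min_reads`` reads are zeroed; barcodes
    absent from the map are excluded but tallied in ``df.attrs``.
    """
    barcodes = bc_map.entries["barcode"].tolist()
    index = pd.Index(barcodes, name="barcode")
    known = set(barcodes)
    data = {}
    unmatched = {}
    for sample, path in sample_fastqs.items():
        counts = extract_rna_barcodes(path, template)
        unmatched[sample] = sum(n for bc, n in counts.items()
                                if bc is None or bc not in known)
        col = pd.Series({bc: counts.get(bc, 0) for bc in barcodes},
                        dtype=np.int64).reindex(index, fill_value=0)
        col[col < min_reads] = 0
        if col.sum() == 0:
            warnings.warn(f"sample {sample}: no extractable known barcodes")
        data[sample] = col
    df = pd.DataFrame(data, index=index)
    df.attrs["unmatched"] = unmatched
    df.attrs["min_reads"] = min_reads
    return df


def attach_dna_column(rna_counts: pd.DataFrame,
                      bc_map: BarcodeMap) -> pd.DataFrame:
    """Prepend the input-DNA column (association read counts) to the matrix."""
    dna = bc_map.entries.set_index("barcode")["n_reads"]
    out = rna_counts.copy()
    out.insert(0, DNA_SAMPLE, dna.reindex(out.index).fillna(0).astype(np.int64))
    out.attrs = dict(rna_counts.attrs)
    return out


def apply_min_reads(counts: pd.DataFrame, min_reads: int = 5) -> pd.DataFrame:
    """Zero RNA cells below the read-count floor (DNA column untouched)."""
    out = counts.copy()
    rna_cols = [c for c in out.columns if c != DNA_SAMPLE]
    out[rna_cols] = out[rna_cols].where(out[rna_cols] >= min_reads, 0)
    return out


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=0).astype(float)
    safe = totals.replace(0, np.nan)
    return counts.div(safe, axis=1).fillna(0.0) * 1e6


def variant_strength(counts: pd.DataFrame, bc_map: BarcodeMap,
                     pseudocount: float = 1.0,
                     aggregate: str = "sum") -> pd.DataFrame:
    """Per-variant, per-sample log2(RNA/DNA) strengths.

    ``counts`` must contain the DNA column plus RNA sample columns (see
    :func:`attach_dna_column`).  With ``aggregate="sum"`` barcode CPMs are
    summed within a variant before the ratio; ``"median"`` instead takes
    the median of per-barcode log2 ratios.  Variants with no RNA-detected
    barcode in any sample are flagged ``detected=False`` and excluded from
    ranking.
    """
    if DNA_SAMPLE not in counts.columns:
        raise ValueError("count matrix lacks the input-DNA column")
    if float(counts[DNA_SAMPLE].sum()) <= 0:
        raise ValueError("input-DNA column has zero total count")
    missing = set(bc_map.entries["barcode"]) - set(counts.index)
    if missing:
        raise ValueError(f"{len(missing)} mapped barcodes absent from matrix")

    rna_cols = [c for c in counts.columns if c != DNA_SAMPLE]
    cpm = _cpm(counts)
    key_of = bc_map.entries.set_index("barcode")["key"]
    groups = cpm.groupby(key_of.reindex(cpm.index))

    if aggregate == "sum":
        sums = groups.sum()
        strengths = np.log2(
            (sums[rna_cols] + pseudocount).div(
                sums[DNA_SAMPLE] + pseudocount, axis=0))
    elif aggregate == "median":
        ratios = np.log2((cpm[rna_cols] + pseudocount).div(
            cpm[DNA_SAMPLE] + pseudocount, axis=0))
        strengths = ratios.groupby(key_of.reindex(cpm.index)).median()
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")

    detected = counts[rna_cols].groupby(key_of.reindex(counts.index)) \
                               .sum().sum(axis=1) > 0
    table = strengths.copy()
    table.index.name = "key"
    conditions = sorted({condition_of(c) for c in rna_cols})
    for cond in conditions:
        cols = [c for c in rna_cols if condition_of(c) == cond]
        table[f"mean_{cond}"] = strengths[cols].mean(axis=1)
    table["detected"] = detected
    return table


def replicate_pcc(table: pd.DataFrame, condition: str = "ctrl") -> pd.DataFrame:
    """Pairwise Pearson correlation of replicate strengths within a condition.

    Only variants detected in the table are used; a pair with fewer than 3
    shared variants gets NaN.
    """
    cols = [c for c in table.columns
            if c not in ("detected",) and not c.startswith("mean_")
            and condition_of(c) == condition]
    if len(cols) < 2:
        raise ValueError(f"need >=2 replicates for condition {condition!r}")
    sub = table.loc[table["detected"], cols]
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            xy = sub[[ci, cj]].dropna()
            if len(xy) < 3:
                r = np.nan
            else:
                r = stats.pearsonr(xy[ci], xy[cj]).statistic
            out.loc[ci, cj] = out.loc[cj, ci] = r
    return out


def classify_and_rank(table: pd.DataFrame,
                      reference_strength: float | None = None,
                      by: str = "mean_ctrl") -> pd.DataFrame:
    """Rank detected variants by mean control strength and class them.

    Class is ``high`` for strength strictly above 0, ``low`` otherwise
    (a strength of exactly 0 is low).  If ``reference_strength`` is given
    (e.g. the 35S enhancer's strength), the number of variants exceeding it
    is stored in ``df.attrs["n_above_reference"]``.
    """
    out = table.copy()
    detected = out["detected"]
    ranks = out.loc[detected, by].rank(ascending=False, method="first")
    out["rank"] = ranks.reindex(out.index)
    out["activity_class"] = np.where(out[by] > 0, "high", "low")
    out.loc[~detected, "activity_class"] = "undetected"
    out.attrs = dict(table.attrs)
    if reference_strength is not None:
        out.attrs["n_above_reference"] = int(
            (out.loc[detected, by] > reference_strength).sum())
        out.attrs["reference_strength"] = float(reference_strength)
    return out
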