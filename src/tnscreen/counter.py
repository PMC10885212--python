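"""Quantify barcode abundance per sample and merge samples into a count matrix.

Counting reads the barcode amplicon FASTQ of one sample, tallies every
extracted barcode, and (optionally) merges barcodes that differ only by
sequencing errors — guided by a library map when one exists, or greedily by
abundance otherwise.  Per-sample tables join into a barcodes × samples count
matrix; column-normalised frequencies support lineage-tracking experiments
where no library map exists at all.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .construct import ConstructSpec, extract_from_read, iter_fastq
from .mapper import DEFAULT_MAX_EDIT_DISTANCE, levenshtein

logger = logging.getLogger(__name__)

__all__ = [
    "BarcodeCounts",
    "count_reads",
    "merge_similar",
    "merge_samples",
    "frequencies",
]


@dataclass
class BarcodeCounts:
    """Barcode tallies for one sample."""

    sample_id: str
    counts: pd.Series  # index: barcode, values: int counts >= 1
    stats: dict = field(default_factory=dict)

    def to_frame(self, annotation: Optional[pd.Series] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"barcode": self.counts.index, "barcode_count": self.counts.values}
        )
        if annotation is not None:
            df["annotation"] = df["barcode"].map(annotation).fillna("")
        return df

    def write_csv(self, output_dir: str, annotation: Optional[pd.Series] = None) -> str:
        os.makedirs(output_dir, exist_ok=True)
        path = os.path.join(output_dir, f"{self.sample_id}_counts.csv")
        self.to_frame(annotation).to_csv(path, index=False)
        return path


def count_reads(reads: str, spec: ConstructSpec, sample_id: Optional[str] = None) -> BarcodeCounts:
    """Tally every barcode extracted from a sample's amplicon reads.

    Reads without a recognisable anchor (or with an N in the barcode)
    contribute to run statistics only.
    """
    if sample_id is None:
        base = os.path.basename(reads)
        for suffix in (".gz", ".fastq", ".fq"):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
        sample_id = base
    tally: dict[str, int] = {}
    scanned = no_barcode = 0
    for read_id, seq in iter_fastq(reads):
        scanned += 1
        ex = extract_from_read(read_id, seq, spec, want_host=False)
        if ex.barcode is None or "N" in ex.barcode:
            no_barcode += 1
            continue
        tally[ex.barcode] = tally.get(ex.barcode, 0) + 1
    counts = pd.Series(tally, dtype=int).sort_index()
    counts.index.name = "barcode"
    return BarcodeCounts(
        sample_id=sample_id,
        counts=counts,
        stats={"reads_scanned": scanned, "reads_without_barcode": no_barcode},
    )


def merge_similar(
    counts: BarcodeCounts,
    library_map: Optional[Iterable[str]] = None,
    max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE,
) -> BarcodeCounts:
    """Absorb sequencing-error barcodes into their parent barcode.

    With a library map: a counted barcode absent from the map is absorbed
    into a mapped barcode when exactly one mapped barcode lies within
    Levenshtein distance strictly below ``max_edit_distance``; several
    candidates leave it untouched (never misassign reads between real
    strains).  Without a map: greedy merge in descending abundance with
    lexicographic tie-break.  Total counts are conserved; 0 disables merging.
    """
    if max_edit_distance <= 0 or counts.counts.empty:
        return counts
    tally = counts.counts.to_dict()
    if library_map is not None:
        mapped = sorted(set(library_map))
        merged: dict[str, int] = {}
        for bc, n in tally.items():
            if bc in mapped:
                merged[bc] = merged.get(bc, 0) + n
                continue
            targets = [m for m in mapped if levenshtein(bc, m) < max_edit_distance]
            if len(targets) == 1:
                merged[targets[0]] = merged.get(targets[0], 0) + n
            else:
                if len(targets) > 1:
                    logger.info(
                        "barcode %s within distance of %d mapped barcodes; left unmerged",
                        bc, len(targets),
                    )
                merged[bc] = merged.get(bc, 0) + n
    else:
        merged = {}
        accepted: list[str] = []
        for bc in sorted(tally, key=lambda b: (-tally[b], b)):
            target = None
            for acc in accepted:
                if levenshtein(bc, acc) < max_edit_distance:
                    target = acc
                    break
            if target is None:
                accepted.append(bc)
                merged[bc] = tally[bc]
            else:
                merged[target] += tally[bc]
    series = pd.Series(merged, dtype=int).sort_index()
    series.index.name = "barcode"
    return BarcodeCounts(sample_id=counts.sample_id, counts=series, stats=dict(counts.stats))


def merge_samples(
    tables: Sequence[BarcodeCounts],
    annotation: Optional[pd.Series] = None,
    annotation_column: str = "annotation",
) -> pd.DataFrame:
    """Full outer join of per-sample tallies into a barcodes × samples matrix.

    Missing entries are 0.  When a barcode → feature mapping is supplied
    (e.g. the first attribute column of the library map), it is carried as a
    per-barcode annotation column; unmapped barcodes keep an empty value.
    """
    if not tables:
        raise ValueError("at least one count table required")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample_id among {ids}")
    mat = pd.concat(
        {t.sample_id: t.counts for t in tables}, axis=1
    ).fillna(0).astype(int)
    mat.index.name = "barcode"
    mat = mat.sort_index()
    if annotation is not None:
        ann = mat.index.to_series().map(annotation).fillna("")
        mat.insert(0, annotation_column, ann)
    return mat


def frequencies(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative barcode frequencies (columns sum to one).

    Non-numeric columns (annotation) pass through untouched.
    """
    out = matrix.copy()
    num_cols = out.select_dtypes("number").columns
    for col in num_cols:
        total = out[col].sum()
        if total <= 0:
            raise ValueError(f"sample {col!r} has zero total counts")
        out[col] = out[col] / total
    return out
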