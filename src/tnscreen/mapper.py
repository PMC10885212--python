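"""Build the library map: genomic site and annotation of every barcoded insertion.

The mapping stage takes junction reads (barcode + construct end + host flank),
localises each host flank on the reference, resolves one primary insertion
site per barcode, removes multimapped barcodes (<75% of reads at the primary
site), merges near-identical barcodes at the same site (sequencing-error
twins), and annotates each insertion with its closest genomic feature and the
insertion percentile within that feature.
"""

from __future__ import annotations

import json
import logging
import os
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .construct import ConstructSpec, Extraction, extract_from_read, iter_fastq, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "collect_host_sequences",
    "align_hosts",
    "resolve_locations",
    "merge_nearby_barcodes",
    "annotate_insertions",
    "map_library",
    "ExactAligner",
    "BlastAligner",
    "levenshtein",
]

DEFAULT_MIN_HOST_LEN = 20
DEFAULT_PRIMARY_FRACTION = 0.75
DEFAULT_MAX_EDIT_DISTANCE = 2
DEFAULT_POSITION_TOLERANCE = 5

ANNOTATED_COLUMNS = [
    "barcode",
    "number_of_reads",
    "insertion_site",
    "chr",
    "strand",
    "distance_to_feature",
    "percentile",
]


def levenshtein(a: str, b: str) -> int:
    """Edit distance (substitutions, insertions, deletions) via edlib."""
    return edlib.align(a, b, task="distance")["editDistance"]


# ---------------------------------------------------------------------------
# host collection
# ---------------------------------------------------------------------------

def collect_host_sequences(
    extractions: Iterable[Extraction],
    min_host_len: int = DEFAULT_MIN_HOST_LEN,
) -> pd.DataFrame:
    """Tabulate (barcode, host) pairs with multiplicities.

    Keeps records with a barcode and a host flank of at least ``min_host_len``
    nucleotides; barcodes containing N are discarded (an ambiguous base breaks
    edit-distance merging).  Identical (barcode, host) pairs collapse to one
    row carrying their read multiplicity.
    """
    tally: dict[tuple[str, str], int] = {}
    for ex in extractions:
        if ex.barcode is None or "N" in ex.barcode:
            continue
        if len(ex.host) < min_host_len:
            continue
        key = (ex.barcode, ex.host)
        tally[key] = tally.get(key, 0) + 1
    if not tally:
        logger.warning("no (barcode, host) pairs passed filtering; map will be empty")
        return pd.DataFrame(columns=["barcode", "host", "multiplicity"])
    rows = [(b, h, m) for (b, h), m in tally.items()]
    return pd.DataFrame(rows, columns=["barcode", "host", "multiplicity"])


# ---------------------------------------------------------------------------
# alignment engines
# ---------------------------------------------------------------------------

HIT_COLUMNS = ["barcode", "host", "multiplicity", "chrom", "position", "strand", "bitscore", "n_locations"]


def _load_genome(genome: "str | dict[str, str]") -> dict[str, str]:
    if isinstance(genome, dict):
        return genome
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(genome, "fasta")}


@dataclass
class ExactAligner:
    """Exact-substring search aligner.

    Locates each host flank as a perfect substring of the reference (both
    strands).  All occurrences score equally, so repeat-region hosts come out
    ambiguous exactly as tied best-score hits would.  Junction convention:
    1-based position of the first host base; for minus-strand placements that
    is the rightmost reference coordinate of the match.
    """

    genome: "str | dict[str, str]"

    def __post_init__(self) -> None:
        self._seqs = _load_genome(self.genome)

    def locate(self, host: str) -> list[tuple[str, int, str, float]]:
        hits = []
        score = 2.0 * len(host)  # nominal perfect-match bitscore
        for chrom, seq in self._seqs.items():
            start = seq.find(host)
            while start != -1:
                hits.append((chrom, start + 1, "+", score))
                start = seq.find(host, start + 1)
            rc = reverse_complement(host)
            start = seq.find(rc)
            while start != -1:
                hits.append((chrom, start + len(host), "-", score))
                start = seq.find(rc, start + 1)
        return hits


@dataclass
class BlastAligner:
    """blastn-based aligner emitting junction coordinates from tabular hits.

    Builds a temporary nucleotide database, runs ``blastn`` (outfmt 6) on the
    host flanks, keeps per query only the hits sharing the maximal bitscore,
    and converts each to a junction coordinate: the reference position of the
    first host base, extrapolated through any query-start clipping
    (plus strand: sstart - (qstart-1); minus strand: sstart + (qstart-1)).
    """

    genome: str
    word_size: int = 11
    evalue: float = 1e-3

    def __post_init__(self) -> None:
        for exe in ("makeblastdb", "blastn"):
            if shutil.which(exe) is None:
                raise FileNotFoundError(
                    f"required executable {exe!r} not found on PATH; "
                    "install BLAST+ or use the built-in ExactAligner"
                )

    def locate_all(self, hosts: Sequence[str]) -> dict[str, list[tuple[str, int, str, float]]]:
        with tempfile.TemporaryDirectory() as tmp:
            db = os.path.join(tmp, "genome")
            subprocess.run(
                ["makeblastdb", "-in", self.genome, "-dbtype", "nucl", "-out", db],
                check=True, capture_output=True,
            )
            qpath = os.path.join(tmp, "hosts.fa")
            with open(qpath, "w") as fh:
                for i, h in enumerate(hosts):
                    fh.write(f">q{i}\n{h}\n")
            out = subprocess.run(
                [
                    "blastn", "-query", qpath, "-db", db,
                    "-outfmt", "6 qseqid sseqid bitscore qstart qend sstart send",
                    "-word_size", str(self.word_size),
                    "-evalue", str(self.evalue),
                    "-dust", "no",
                ],
                check=True, capture_output=True, text=True,
            ).stdout
        per_query: dict[int, list[tuple[str, int, str, float]]] = {}
        best: dict[int, float] = {}
        parsed: dict[int, list[tuple[float, str, int, str]]] = {}
        for line in out.splitlines():
            qid, sid, bits, qstart, _qend, sstart, send = line.split("\t")
            qi = int(qid[1:])
            bits_f = float(bits)
            qstart_i, sstart_i, send_i = int(qstart), int(sstart), int(send)
            if sstart_i <= send_i:
                pos, strand = sstart_i - (qstart_i - 1), "+"
            else:
                pos, strand = sstart_i + (qstart_i - 1), "-"
            parsed.setdefault(qi, []).append((bits_f, sid, pos, strand))
            if bits_f > best.get(qi, -1.0):
                best[qi] = bits_f
        for qi, rows in parsed.items():
            per_query[qi] = [
                (sid, pos, strand, bits_f)
                for bits_f, sid, pos, strand in rows
                if bits_f >= best[qi]
            ]
        return {hosts[qi]: hits for qi, hits in per_query.items()}


def align_hosts(hosts: pd.DataFrame, genome, aligner=None) -> pd.DataFrame:
    """Align host flanks to the reference and keep only best-bitscore hits.

    Returns one row per surviving (host, location); ``n_locations`` > 1 marks
    the host ambiguous (ties among maximal-bitscore placements, typically
    repeats).  Hosts with no hit at all are dropped.
    """
    if hosts.empty:
        return pd.DataFrame(columns=HIT_COLUMNS)
    if aligner is None:
        aligner = ExactAligner(genome)

    unique_hosts = hosts["host"].unique().tolist()
    if isinstance(aligner, BlastAligner):
        located = aligner.locate_all(unique_hosts)
    else:
        located = {h: aligner.locate(h) for h in unique_hosts}
        # deduplicate tied placements at identical coordinates
    rows = []
    for rec in hosts.itertuples(index=False):
        hits = located.get(rec.host, [])
        # collapse duplicate (chrom, pos, strand) placements
        uniq = {}
        for chrom, pos, strand, bits in hits:
            key = (chrom, pos, strand)
            if key not in uniq or bits > uniq[key]:
                uniq[key] = bits
        if not uniq:
            continue
        n_loc = len(uniq)
        for (chrom, pos, strand), bits in uniq.items():
            rows.append((rec.barcode, rec.host, rec.multiplicity, chrom, pos, strand, bits, n_loc))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# location resolution and barcode merging
# ---------------------------------------------------------------------------

def _collapse_positions(
    sites: list[tuple[tuple[str, str, int], int]],
    tolerance: int,
) -> dict[tuple[str, str, int], int]:
    """Greedy position collapse: sites within ±tolerance bp (same chrom and
    strand) absorb into the most-supported position."""
    out: dict[tuple[str, str, int], int] = {}
    for (chrom, strand, pos), reads in sorted(
        sites, key=lambda kv: (-kv[1], kv[0])
    ):
        target = None
        for (c2, s2, p2) in out:
            if c2 == chrom and s2 == strand and abs(p2 - pos) <= tolerance:
                target = (c2, s2, p2)
                break
        if target is None:
            out[(chrom, strand, pos)] = reads
        else:
            out[target] += reads
    return out


def resolve_locations(
    hits: pd.DataFrame,
    primary_fraction: float = DEFAULT_PRIMARY_FRACTION,
    position_tolerance: int = DEFAULT_POSITION_TOLERANCE,
) -> pd.DataFrame:
    """Resolve one primary insertion site per barcode; drop multimapped ones.

    Reads from ambiguous hosts (ties among best-score placements) count only
    in the denominator of the primary fraction, so an insertion sitting in a
    perfect repeat is removed rather than arbitrarily placed.  A barcode is
    kept iff primary_fraction >= 0.75 (boundary inclusive).
    """
    cols = ["barcode", "chrom", "position", "strand", "total_reads", "primary_fraction", "status"]
    if hits.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for barcode, grp in hits.groupby("barcode", sort=True):
        per_host = grp.drop_duplicates(subset=["host"])[["host", "multiplicity"]]
        denom = int(per_host["multiplicity"].sum())
        unamb = grp[grp["n_locations"] == 1]
        support: dict[tuple[str, str, int], int] = {}
        for rec in unamb.itertuples(index=False):
            key = (rec.chrom, rec.strand, int(rec.position))
            support[key] = support.get(key, 0) + int(rec.multiplicity)
        collapsed = _collapse_positions(list(support.items()), position_tolerance)
        if collapsed:
            (chrom, strand, pos), primary_reads = max(
                collapsed.items(), key=lambda kv: (kv[1], kv[0][0], -kv[0][2])
            )
            frac = primary_reads / denom
        else:
            chrom, strand, pos, frac = "", "", 0, 0.0
        if frac >= primary_fraction:
            status = "kept"
        else:
            status = "removed_multimapped"
        rows.append((barcode, chrom, pos, strand, denom, frac, status))
    return pd.DataFrame(rows, columns=cols)


def merge_nearby_barcodes(
    locations: pd.DataFrame,
    max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE,
    position_tolerance: int = DEFAULT_POSITION_TOLERANCE,
) -> pd.DataFrame:
    """Merge sequencing-error twin barcodes mapped to the same position.

    Among kept barcodes whose sites collapse to the same position (±tolerance
    bp, same chrom/strand), a barcode within Levenshtein distance strictly
    below ``max_edit_distance`` of a more abundant one is absorbed into it.
    Processing is in descending abundance with lexicographic tie-break, which
    makes the outcome order-independent and conserves total reads.
    """
    out = locations.copy()
    kept = out[out["status"] == "kept"]
    if kept.empty or max_edit_distance <= 0:
        return out

    # collapse kept-barcode sites across barcodes so jittered twins group together
    site_items = [
        ((r.chrom, r.strand, int(r.position)), int(r.total_reads))
        for r in kept.itertuples(index=False)
    ]
    centers = list(_collapse_positions(site_items, position_tolerance).keys())

    def site_of(chrom: str, strand: str, pos: int) -> tuple:
        for c in centers:
            if c[0] == chrom and c[1] == strand and abs(c[2] - pos) <= position_tolerance:
                return c
        return (chrom, strand, pos)

    out["_site"] = [
        site_of(r.chrom, r.strand, int(r.position)) if r.status == "kept" else None
        for r in out.itertuples(index=False)
    ]
    merged_reads: dict[str, int] = {}
    for _site, grp in out[out["status"] == "kept"].groupby("_site", sort=False):
        order = grp.sort_values(
            ["total_reads", "barcode"], ascending=[False, True]
        )
        accepted: list[tuple[str, int]] = []  # (barcode, row index)
        for idx, rec in order.iterrows():
            target = None
            for acc_bc, acc_idx in accepted:
                if levenshtein(rec["barcode"], acc_bc) < max_edit_distance:
                    target = (acc_bc, acc_idx)
                    break
            if target is None:
                accepted.append((rec["barcode"], idx))
            else:
                acc_bc, acc_idx = target
                merged_reads[acc_bc] = merged_reads.get(acc_bc, 0) + int(rec["total_reads"])
                out.at[idx, "status"] = f"merged_into:{acc_bc}"
    for bc, extra in merged_reads.items():
        sel = out["barcode"] == bc
        out.loc[sel, "total_reads"] = out.loc[sel, "total_reads"] + extra
    return out.drop(columns=["_site"])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _read_features(gff_path: str, feature_type: str, attributes: Sequence[str]) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        gff_path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type(feature_type):
        attrs = []
        for key in attributes:
            vals = feat.attributes.get(key)
            if vals is None:
                warnings.warn(f"attribute {key!r} missing for feature at "
                              f"{feat.seqid}:{feat.start}; emitting empty string")
                attrs.append("")
            else:
                attrs.append(vals[0])
        rows.append((feat.seqid, feat.start, feat.end, feat.strand, *attrs))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", *attributes])


def annotate_insertions(
    locations: pd.DataFrame,
    annotation: str,
    feature_type: str = "gene",
    attributes: Sequence[str] = ("ID", "Name", "locus_tag"),
) -> pd.DataFrame:
    """Annotate kept insertions with their overlapping or nearest feature.

    Overlap gives distance 0 plus an insertion percentile — the position of
    the insertion along the feature from its 5' end, as a percent of feature
    length.  Intergenic insertions report the nearest feature and a signed bp
    gap (negative when the insertion lies 5' of the feature start in genome
    coordinates); percentile stays absent.
    """
    attributes = list(attributes)
    feats = _read_features(annotation, feature_type, attributes)
    kept = locations[locations["status"] == "kept"]
    rows = []
    by_chrom = {c: g.reset_index(drop=True) for c, g in feats.groupby("chrom")} if not feats.empty else {}
    for rec in kept.itertuples(index=False):
        site = int(rec.position)
        sub = by_chrom.get(rec.chrom)
        dist: "float | int" = np.nan
        pct = np.nan
        attr_vals = [""] * len(attributes)
        if sub is not None and len(sub):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            d = np.where(site < starts, site - starts, np.where(site > ends, site - ends, 0))
            i = int(np.lexsort((starts, np.abs(d)))[0])
            dist = int(d[i])
            frow = sub.iloc[i]
            if dist == 0:
                length = frow["end"] - frow["start"] + 1
                if frow["strand"] == "-":
                    pct = 100.0 * (frow["end"] - site + 1) / length
                else:
                    pct = 100.0 * (site - frow["start"] + 1) / length
            attr_vals = [frow[a] for a in attributes]
        rows.append(
            (rec.barcode, int(rec.total_reads), site, rec.chrom, rec.strand, dist, pct, *attr_vals)
        )
    return pd.DataFrame(rows, columns=ANNOTATED_COLUMNS + attributes)


# ---------------------------------------------------------------------------
# full mapping pipeline
# ---------------------------------------------------------------------------

@dataclass
class MapResult:
    library_map: pd.DataFrame
    stats: dict = field(default_factory=dict)


def map_library(
    reads: str,
    genome: str,
    annotation: Optional[str],
    spec: ConstructSpec,
    name: str = "library",
    output_dir: Optional[str] = None,
    min_host_len: int = DEFAULT_MIN_HOST_LEN,
    primary_fraction: float = DEFAULT_PRIMARY_FRACTION,
    max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE,
    feature_type: str = "gene",
    attributes: Sequence[str] = ("ID", "Name", "locus_tag"),
    aligner=None,
) -> MapResult:
    """Run the full mapping pipeline and optionally write the annotated map."""
    stats: dict[str, int] = {
        "reads_scanned": 0,
        "reads_with_barcode": 0,
        "hosts_min_length": 0,
    }

    def extractions():
        for read_id, seq in iter_fastq(reads):
            stats["reads_scanned"] += 1
            ex = extract_from_read(read_id, seq, spec, want_host=True)
            if ex.barcode is not None:
                stats["reads_with_barcode"] += 1
                if len(ex.host) >= min_host_len:
                    stats["hosts_min_length"] += 1
            yield ex

    hosts = collect_host_sequences(extractions(), min_host_len=min_host_len)
    hits = align_hosts(hosts, genome, aligner=aligner)
    locations = resolve_locations(hits, primary_fraction=primary_fraction)
    stats["barcodes_before_filtering"] = len(locations)
    locations = merge_nearby_barcodes(locations, max_edit_distance=max_edit_distance)
    stats["barcodes_removed_multimapped"] = int((locations["status"] == "removed_multimapped").sum()) if len(locations) else 0
    stats["barcodes_merged"] = int(locations["status"].str.startswith("merged_into").sum()) if len(locations) else 0
    stats["barcodes_final"] = int((locations["status"] == "kept").sum()) if len(locations) else 0

    if annotation is not None:
        library_map = annotate_insertions(
            locations, annotation, feature_type=feature_type, attributes=attributes
        )
        attr_cols = list(attributes)
    else:
        kept = locations[locations["status"] == "kept"] if len(locations) else locations
        library_map = pd.DataFrame(
            {
                "barcode": kept["barcode"] if len(kept) else [],
                "number_of_reads": kept["total_reads"] if len(kept) else [],
                "insertion_site": kept["position"] if len(kept) else [],
                "chr": kept["chrom"] if len(kept) else [],
                "strand": kept["strand"] if len(kept) else [],
                "distance_to_feature": np.nan,
                "percentile": np.nan,
            }
        )
        attr_cols = []

    stats["unique_insertion_sites"] = (
        int(library_map[["chr", "insertion_site", "strand"]].drop_duplicates().shape[0])
        if len(library_map) else 0
    )
    if attr_cols and len(library_map):
        hit_genes = library_map.loc[library_map["distance_to_feature"] == 0, attr_cols[0]]
        stats["genes_hit"] = int(hit_genes[hit_genes != ""].nunique())
        in_core = library_map[
            (library_map["distance_to_feature"] == 0)
            & (library_map["percentile"] >= 5)
            & (library_map["percentile"] <= 95)
        ][attr_cols[0]]
        stats["genes_hit_percentile_5_95"] = int(in_core[in_core != ""].nunique())
    else:
        stats["genes_hit"] = 0
        stats["genes_hit_percentile_5_95"] = 0

    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        out_csv = os.path.join(output_dir, f"{name}.annotated.csv")
        library_map.to_csv(out_csv, index=False)
        with open(os.path.join(output_dir, f"{name}.map_stats.json"), "w") as fh:
            json.dump(stats, fh, indent=2, sort_keys=True)
    return MapResult(library_map=library_map, stats=stats)
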