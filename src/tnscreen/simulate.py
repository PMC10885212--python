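"""Synthetic genomes, insertion libraries, reads and screens with known truth.

Every pipeline stage can be exercised against ground truth generated here:
a random genome with non-overlapping gene features, a barcoded insertion
library at uniform random sites, junction reads (barcode + construct end +
host flank) with substitution errors, barcode amplicon count tables drawn
from a negative-binomial noise model with spiked gene-level fitness effects,
and wild-type control strains at a dilution series.  The default scales
mirror a small Tn5 screen: ~2000 insertions on a few-Mb genome for mapping,
1000 genes x 3 barcodes at 1e6 reads per sample for selection screens.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .construct import ConstructSpec, reverse_complement

__all__ = [
    "SimGenome",
    "SimLibrary",
    "ScreenTruth",
    "sim_genome",
    "sim_library",
    "sim_mapping_reads",
    "sim_screen",
]

BASES = np.array(list("ACGT"))

# screen study conditions: 1000 genes x 3 barcodes, 3v3 replicates at 1e6
# depth, NB dispersion 0.1, 20 genes spiked at LFC -2 with sd-0.2 jitter
DEFAULT_N_GENES = 1000
DEFAULT_BARCODES_PER_GENE = 3
DEFAULT_REPLICATES = 3
DEFAULT_DEPTH = 1_000_000
DEFAULT_DISPERSION = 0.1
DEFAULT_N_SPIKED = 20
DEFAULT_SPIKE_LFC = -2.0
DEFAULT_LFC_JITTER_SD = 0.2
# two-fold wild-type spike-in dilution series, 3 barcodes per level, 5% mass:
# keeps every control quantifiable even through a bottleneck while spanning
# enough range for the dilution-series QC regression
DEFAULT_CONTROL_CONCENTRATIONS = (1.0, 0.5, 0.25, 0.125)
DEFAULT_CONTROL_BARCODES_PER_CONC = 3


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class SimGenome:
    chrom: str
    sequence: str
    features: pd.DataFrame  # chrom, start, end, strand, ID, Name, locus_tag

    def write_fasta(self, path: str) -> str:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            seq = self.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
        return path

    def write_gff3(self, path: str) -> str:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.chrom} 1 {len(self.sequence)}\n")
            for rec in self.features.itertuples(index=False):
                attrs = f"ID={rec.ID};Name={rec.Name};locus_tag={rec.locus_tag}"
                fh.write(
                    f"{rec.chrom}\tsim\tgene\t{rec.start}\t{rec.end}\t.\t{rec.strand}\t.\t{attrs}\n"
                )
        return path


def sim_genome(
    seed: int,
    length_bp: int = 200_000,
    n_genes: int = 80,
    mean_gene_length: int = 900,
    repeat_copies: int = 0,
    repeat_length: int = 1000,
    chrom: str = "chr1",
) -> SimGenome:
    """Random genome with non-overlapping gene features on both strands.

    ``repeat_copies=2`` plants two identical segments so multimapping
    insertions can be simulated.
    """
    rng = np.random.default_rng(seed)
    if n_genes * mean_gene_length >= length_bp:
        raise ValueError(
            f"cannot pack {n_genes} genes of ~{mean_gene_length} bp into {length_bp} bp"
        )
    seq = list(_random_dna(rng, length_bp))
    if repeat_copies > 1:
        unit = _random_dna(rng, repeat_length)
        # place copies in the final 10% of the genome, clear of genes below
        tail_start = int(length_bp * 0.9)
        gap = (length_bp - tail_start) // repeat_copies
        if gap < repeat_length:
            raise ValueError("genome too short for requested repeat copies")
        for c in range(repeat_copies):
            pos = tail_start + c * gap
            seq[pos : pos + repeat_length] = unit
        gene_space = tail_start
    else:
        gene_space = length_bp
    sequence = "".join(seq)

    rows = []
    # evenly spaced slots with jitter keep features non-overlapping
    slot = gene_space // max(n_genes, 1) if n_genes else gene_space
    for i in range(n_genes):
        glen = int(np.clip(rng.normal(mean_gene_length, mean_gene_length / 5), 200, slot - 10))
        offset = int(rng.integers(0, max(slot - glen - 1, 1)))
        start = i * slot + offset + 1  # 1-based
        end = start + glen - 1
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            (chrom, start, end, strand, f"gene-{i:04d}", f"name{i:04d}", f"LOC_{i:04d}")
        )
    features = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "ID", "Name", "locus_tag"]
    )
    return SimGenome(chrom=chrom, sequence=sequence, features=features)


# ---------------------------------------------------------------------------
# insertion library
# ---------------------------------------------------------------------------

@dataclass
class SimLibrary:
    genome: SimGenome
    truth: pd.DataFrame  # barcode, chrom, site, strand, gene

    def write_truth(self, path: str) -> str:
        self.truth.to_csv(path, index=False)
        return path


def _gene_at(features: pd.DataFrame, site: int) -> str:
    hit = features[(features["start"] <= site) & (site <= features["end"])]
    return hit.iloc[0]["ID"] if len(hit) else ""


def sim_library(
    genome: SimGenome,
    n_insertions: int = 200,
    barcode_length: int = 17,
    seed: int = 0,
    min_pairwise_distance: int = 3,
    collision_pairs: int = 0,
    sites_in_repeat: int = 0,
    repeat_region: Optional[tuple[int, int]] = None,
) -> SimLibrary:
    """Uniform random insertion sites with unique random barcodes.

    Barcodes are rejected until pairwise Levenshtein distance >=
    ``min_pairwise_distance`` so downstream merging cannot collapse distinct
    strains.  ``collision_pairs`` deliberately injects near-duplicate
    barcodes (distance 1, same site) expected to merge downstream;
    ``sites_in_repeat`` places insertions inside ``repeat_region`` to create
    multimapping barcodes.
    """
    import edlib

    rng = np.random.default_rng(seed)
    glen = len(genome.sequence)
    barcodes: list[str] = []
    while len(barcodes) < n_insertions:
        cand = _random_dna(rng, barcode_length)
        ok = all(
            edlib.align(cand, b, task="distance", k=min_pairwise_distance - 1)["editDistance"] == -1
            for b in barcodes
        )
        if ok:
            barcodes.append(cand)
    margin = 150  # keep flanks inside the genome
    sites = rng.integers(margin, glen - margin, size=n_insertions)
    strands = np.where(rng.random(n_insertions) < 0.5, "+", "-")
    rows = []
    for bc, site, strand in zip(barcodes, sites, strands):
        site = int(site)
        rows.append((bc, genome.chrom, site, strand, _gene_at(genome.features, site)))
    if sites_in_repeat:
        if repeat_region is None:
            raise ValueError("sites_in_repeat requires repeat_region=(start, end)")
        lo, hi = repeat_region
        if hi - lo < 300:
            raise ValueError("repeat_region must span >= 300 bp to hold junction flanks")
        for i in range(min(sites_in_repeat, len(rows))):
            bc, chrom, _site, strand, _g = rows[i]
            # keep the whole host flank inside the repeat so it truly multimaps
            site = int(rng.integers(lo + 120, hi - 120))
            rows[i] = (bc, chrom, site, strand, _gene_at(genome.features, site))
    truth = pd.DataFrame(rows, columns=["barcode", "chrom", "site", "strand", "gene"])
    if collision_pairs:
        extra = []
        for i in range(min(collision_pairs, len(truth))):
            parent = truth.iloc[i]
            bc = list(parent["barcode"])
            j = int(rng.integers(0, len(bc)))
            bc[j] = str(rng.choice([x for x in "ACGT" if x != bc[j]]))
            extra.append(("".join(bc), parent["chrom"], parent["site"], parent["strand"], parent["gene"]))
        truth = pd.concat([truth, pd.DataFrame(extra, columns=truth.columns)], ignore_index=True)
    return SimLibrary(genome=genome, truth=truth)


# ---------------------------------------------------------------------------
# mapping reads
# ---------------------------------------------------------------------------

def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    n_err = rng.binomial(len(arr), error_rate)
    for pos in rng.choice(len(arr), size=n_err, replace=False):
        arr[pos] = str(rng.choice([b for b in "ACGT" if b != arr[pos]]))
    return "".join(arr)


def sim_mapping_reads(
    library: SimLibrary,
    spec: ConstructSpec,
    depth_per_barcode: int = 50,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    out_fastq: Optional[str] = None,
) -> list[str]:
    """Junction reads barcode + spacer + end-sequence + host flank.

    The host flank is taken strand-aware at the insertion junction (for a
    minus-strand insertion the flank runs leftward and is reverse
    complemented), substitution errors are applied at ``error_rate``, and
    each read is emitted in a random orientation.  Returns FASTQ lines, and
    writes them when ``out_fastq`` is given.
    """
    prefix_len = spec.barcode_length + spec.spacer_length + len(spec.end_sequence)
    if read_len <= prefix_len + 20:
        raise ValueError("read_len must exceed barcode + spacer + anchor by > 20 bp")
    rng = np.random.default_rng(seed)
    genome_seq = library.genome.sequence
    host_len = read_len - prefix_len
    lines: list[str] = []
    n = 0
    for rec in library.truth.itertuples(index=False):
        site = int(rec.site)
        if rec.strand == "+":
            host = genome_seq[site - 1 : site - 1 + host_len]
        else:
            host = reverse_complement(genome_seq[site - host_len : site])
        spacer = _random_dna(rng, spec.spacer_length) if spec.spacer_length else ""
        template = rec.barcode + spacer + spec.end_sequence + host
        for _ in range(depth_per_barcode):
            read = _mutate(template, rng, error_rate)
            if rng.random() < 0.5:
                read = reverse_complement(read)
            n += 1
            lines.append(f"@sim_{n}")
            lines.append(read)
            lines.append("+")
            lines.append("I" * len(read))
    if out_fastq is not None:
        with open(out_fastq, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    return lines


# ---------------------------------------------------------------------------
# selection screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenTruth:
    counts: pd.DataFrame        # barcode index, gene column + sample columns
    gene_lfc: pd.Series         # per-gene true fitness LFC
    barcode_lfc: pd.Series      # per-barcode effect incl. jitter
    design: pd.Series           # sample -> condition
    controls: Optional[pd.DataFrame] = None
    spiked_genes: list = field(default_factory=list)

    def write(self, output_dir: str, name: str = "sim_screen") -> dict[str, str]:
        os.makedirs(output_dir, exist_ok=True)
        paths = {
            "counts": os.path.join(output_dir, f"{name}_counts.csv"),
            "design": os.path.join(output_dir, f"{name}_design.csv"),
            "truth": os.path.join(output_dir, f"{name}_truth.csv"),
        }
        self.counts.to_csv(paths["counts"])
        self.design.rename("condition").rename_axis("sample_id").reset_index().to_csv(
            paths["design"], index=False
        )
        self.gene_lfc.rename("true_lfc").rename_axis("gene").reset_index().to_csv(
            paths["truth"], index=False
        )
        if self.controls is not None:
            paths["controls"] = os.path.join(output_dir, f"{name}_controls.csv")
            self.controls.to_csv(paths["controls"], index=False)
        return paths


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB counts with variance mu + dispersion * mu^2 (Poisson if 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    # gamma-Poisson mixture
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def sim_screen(
    n_genes: int = DEFAULT_N_GENES,
    barcodes_per_gene: int = DEFAULT_BARCODES_PER_GENE,
    n_control: int = DEFAULT_REPLICATES,
    n_treatment: int = DEFAULT_REPLICATES,
    depth: int = DEFAULT_DEPTH,
    dispersion: float = DEFAULT_DISPERSION,
    n_spiked: int = DEFAULT_N_SPIKED,
    spike_lfc: float = DEFAULT_SPIKE_LFC,
    lfc_jitter_sd: float = DEFAULT_LFC_JITTER_SD,
    bottleneck_size: Optional[int] = None,
    control_concentrations: Optional[Sequence[float]] = None,
    n_control_barcodes_per_conc: int = DEFAULT_CONTROL_BARCODES_PER_CONC,
    barcode_length: int = 17,
    seed: int = 0,
) -> ScreenTruth:
    """Simulate a two-condition barcode selection screen with known effects.

    Baseline lineage abundances are Dirichlet-uniform; treatment abundances
    are scaled by 2^(gene LFC + per-barcode jitter) and renormalised.  An
    optional multinomial bottleneck thins each sample's population before
    sequencing, and counts are drawn negative-binomially with variance
    mu + dispersion * mu^2.  Wild-type control barcodes can be spiked at a
    stated dilution series (constant across conditions — they are
    fitness-neutral).
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene{g:04d}" for g in range(n_genes)]
    barcode_gene = {}
    barcodes = []
    seen = set()
    for g in genes:
        for _ in range(barcodes_per_gene):
            bc = _random_dna(rng, barcode_length)
            while bc in seen:
                bc = _random_dna(rng, barcode_length)
            seen.add(bc)
            barcodes.append(bc)
            barcode_gene[bc] = g

    gene_lfc = pd.Series(0.0, index=genes)
    spiked = list(rng.choice(genes, size=n_spiked, replace=False)) if n_spiked else []
    gene_lfc[spiked] = spike_lfc
    per_bc_lfc = np.array(
        [gene_lfc[barcode_gene[bc]] for bc in barcodes]
    ) + np.where(
        [gene_lfc[barcode_gene[bc]] != 0 for bc in barcodes],
        rng.normal(0.0, lfc_jitter_sd, size=len(barcodes)),
        0.0,
    )
    barcode_lfc = pd.Series(per_bc_lfc, index=barcodes)

    base = rng.dirichlet(np.ones(len(barcodes)))
    treat = base * np.power(2.0, per_bc_lfc)
    treat = treat / treat.sum()

    # spiked-in wild-type controls at a dilution series, neutral fitness
    controls_df = None
    ctrl_barcodes: list[str] = []
    ctrl_fracs = np.array([])
    if control_concentrations is not None:
        conc_rows = []
        for conc in control_concentrations:
            for _ in range(n_control_barcodes_per_conc):
                bc = _random_dna(rng, barcode_length)
                while bc in seen:
                    bc = _random_dna(rng, barcode_length)
                seen.add(bc)
                ctrl_barcodes.append(bc)
                conc_rows.append((bc, "wt", float(conc)))
        controls_df = pd.DataFrame(conc_rows, columns=["barcode", "genotype", "concentration"])
        conc = controls_df["concentration"].to_numpy()
        spike_total = 0.05  # controls take 5% of each sample
        ctrl_fracs = spike_total * conc / conc.sum()

    def sample_counts(freq: np.ndarray) -> np.ndarray:
        f = freq
        if ctrl_barcodes:
            f = np.concatenate([freq * (1.0 - ctrl_fracs.sum()), ctrl_fracs])
        if bottleneck_size is not None:
            surv = rng.multinomial(bottleneck_size, f)
            total = surv.sum()
            if total == 0:
                raise ValueError("bottleneck extinguished the population")
            f = surv / total
        return _nb_draw(rng, depth * f, dispersion)

    data = {}
    design = {}
    for j in range(n_control):
        sid = f"control_{j + 1}"
        data[sid] = sample_counts(base)
        design[sid] = "control"
    for j in range(n_treatment):
        sid = f"treatment_{j + 1}"
        data[sid] = sample_counts(treat)
        design[sid] = "treatment"

    all_barcodes = barcodes + ctrl_barcodes
    counts = pd.DataFrame(data, index=pd.Index(all_barcodes, name="barcode"))
    gene_col = [barcode_gene.get(bc, "") for bc in all_barcodes]
    counts.insert(0, "gene", gene_col)
    return ScreenTruth(
        counts=counts,
        gene_lfc=gene_lfc,
        barcode_lfc=barcode_lfc,
        design=pd.Series(design),
        controls=controls_df,
        spiked_genes=list(spiked),
    )
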