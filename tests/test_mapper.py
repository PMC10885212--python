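import numpy as np
import pandas as pd
import pytest

from tnscreen import (
    ExactAligner,
    annotate_insertions,
    collect_host_sequences,
    map_library,
    merge_nearby_barcodes,
    resolve_locations,
)
from tnscreen.construct import Extraction
from tnscreen.mapper import align_hosts, levenshtein
from tnscreen.simulate import sim_genome, sim_library, sim_mapping_reads

from conftest import brute_force_merge, dp_levenshtein, random_barcode_tally


def ex(barcode, host, rid="r"):
    return Extraction(read_id=rid, barcode=barcode, host=host, anchor_start=0)


class TestCollectHosts:
    def test_host_length_boundary(self):
        out = collect_host_sequences([ex("ACGT", "A" * 19), ex("ACGT", "C" * 20)])
        assert out["host"].tolist() == ["C" * 20]

    def test_deduplication_multiplicity(self):
        out = collect_host_sequences([ex("ACGT", "A" * 25)] * 3)
        assert out["multiplicity"].tolist() == [3]

    def test_n_barcode_discarded(self):
        out = collect_host_sequences([ex("ACNT", "A" * 25)])
        assert out.empty


class TestExactAligner:
    GENOME = {"c1": "A" * 50 + "GATTACAGATTACAGATTACAGATT" + "C" * 50}

    def test_forward_junction(self):
        hits = ExactAligner(self.GENOME).locate("GATTACAGATTACAGATTACAGATT")
        assert hits == [("c1", 51, "+", 50.0)]

    def test_reverse_junction_is_rightmost_coordinate(self):
        host = "GATTACAGATTACAGATTACAGATT"
        rc_hits = ExactAligner(self.GENOME).locate(
            host.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        )
        assert rc_hits == [("c1", 75, "-", 50.0)]

    def test_repeat_gives_two_locations(self):
        genome = {"c1": "T" * 30 + "ACGTACGTACGTACGTACGTGG" + "T" * 30 + "ACGTACGTACGTACGTACGTGG" + "T" * 30}
        hits = ExactAligner(genome).locate("ACGTACGTACGTACGTACGTGG")
        assert len(hits) == 2


class TestResolveLocations:
    def _hits(self, rows):
        return pd.DataFrame(
            rows, columns=["barcode", "host", "multiplicity", "chrom", "position", "strand", "bitscore", "n_locations"]
        )

    @pytest.mark.parametrize(
        "primary,secondary,status",
        [(80, 20, "kept"), (75, 25, "kept"), (70, 30, "removed_multimapped")],
    )
    def test_primary_fraction_boundary(self, primary, secondary, status):
        hits = self._hits(
            [("B1", "h1", primary, "c1", 100, "+", 40.0, 1),
             ("B1", "h2", secondary, "c1", 5000, "+", 40.0, 1)]
        )
        loc = resolve_locations(hits)
        assert loc.loc[0, "status"] == status
        assert loc.loc[0, "primary_fraction"] == pytest.approx(primary / 100)

    def test_all_ambiguous_removed(self):
        hits = self._hits(
            [("B1", "h1", 50, "c1", 100, "+", 40.0, 2),
             ("B1", "h1", 50, "c1", 900, "+", 40.0, 2)]
        )
        loc = resolve_locations(hits)
        assert loc.loc[0, "status"] == "removed_multimapped"
        assert loc.loc[0, "primary_fraction"] == 0.0
        assert loc.loc[0, "total_reads"] == 50  # counted once, denominator only

    def test_position_jitter_collapses(self):
        hits = self._hits(
            [("B1", "h1", 60, "c1", 100, "+", 40.0, 1),
             ("B1", "h2", 40, "c1", 103, "+", 38.0, 1)]
        )
        loc = resolve_locations(hits)
        assert loc.loc[0, "status"] == "kept"
        assert loc.loc[0, "position"] == 100
        assert loc.loc[0, "primary_fraction"] == 1.0

    def test_read_conservation(self):
        rng = np.random.default_rng(5)
        rows = []
        total = 0
        for b in range(10):
            for h in range(3):
                mult = int(rng.integers(1, 50))
                total += mult
                rows.append((f"B{b}", f"h{b}_{h}", mult, "c1", int(rng.integers(1, 10_000)), "+", 40.0, 1))
        loc = resolve_locations(self._hits(rows))
        assert loc["total_reads"].sum() == total


class TestMergeNearbyBarcodes:
    def _loc(self, rows):
        return pd.DataFrame(
            rows, columns=["barcode", "chrom", "position", "strand", "total_reads", "primary_fraction", "status"]
        )

    def test_distance_one_merges_into_more_abundant(self):
        loc = self._loc([("ACGT", "c1", 100, "+", 30, 1.0, "kept"),
                         ("ACGA", "c1", 100, "+", 2, 1.0, "kept")])
        out = merge_nearby_barcodes(loc, max_edit_distance=2)
        kept = out[out["status"] == "kept"]
        assert kept["barcode"].tolist() == ["ACGT"]
        assert kept["total_reads"].tolist() == [32]
        assert out.loc[out["barcode"] == "ACGA", "status"].item() == "merged_into:ACGT"

    def test_distance_two_not_merged(self):
        assert dp_levenshtein("ACGT", "ATGA") == 2  # oracle confirms the boundary case
        loc = self._loc([("ACGT", "c1", 100, "+", 30, 1.0, "kept"),
                         ("ATGA", "c1", 100, "+", 2, 1.0, "kept")])
        out = merge_nearby_barcodes(loc, max_edit_distance=2)
        assert (out["status"] == "kept").sum() == 2

    def test_different_sites_not_merged(self):
        loc = self._loc([("ACGT", "c1", 100, "+", 30, 1.0, "kept"),
                         ("ACGA", "c1", 5000, "+", 2, 1.0, "kept")])
        out = merge_nearby_barcodes(loc, max_edit_distance=2)
        assert (out["status"] == "kept").sum() == 2

    def test_reads_conserved_and_oracle_equivalence(self):
        """Greedy same-site merge equals brute-force all-pairs DP clustering."""
        rng = np.random.default_rng(11)
        for trial in range(30):
            tally = random_barcode_tally(rng, int(rng.integers(2, 21)))
            loc = self._loc([(bc, "c1", 500, "+", n, 1.0, "kept") for bc, n in tally.items()])
            out = merge_nearby_barcodes(loc, max_edit_distance=2)
            kept = out[out["status"] == "kept"]
            expected = brute_force_merge(tally, 2)
            assert dict(zip(kept["barcode"], kept["total_reads"])) == expected
            assert kept["total_reads"].sum() == sum(tally.values())


class TestAnnotate:
    def _gff(self, tmp_path, strand):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            f"c1\tsrc\tgene\t1001\t2000\t.\t{strand}\t.\tID=gene1;locus_tag=LOC1\n"
        )
        return str(p)

    def _loc(self, pos):
        return pd.DataFrame(
            [("ACGT", "c1", pos, "+", 10, 1.0, "kept")],
            columns=["barcode", "chrom", "position", "strand", "total_reads", "primary_fraction", "status"],
        )

    def test_percentile_plus_strand(self, tmp_path):
        out = annotate_insertions(self._loc(1100), self._gff(tmp_path, "+"), attributes=["ID"])
        assert out.loc[0, "percentile"] == pytest.approx(10.0)
        assert out.loc[0, "distance_to_feature"] == 0

    def test_percentile_minus_strand(self, tmp_path):
        out = annotate_insertions(self._loc(1100), self._gff(tmp_path, "-"), attributes=["ID"])
        assert out.loc[0, "percentile"] == pytest.approx(90.1)

    def test_intergenic_signed_distance(self, tmp_path):
        out = annotate_insertions(self._loc(950), self._gff(tmp_path, "+"), attributes=["ID"])
        assert out.loc[0, "distance_to_feature"] == -51
        assert np.isnan(out.loc[0, "percentile"])

    def test_unknown_attribute_warns_empty(self, tmp_path):
        with pytest.warns(UserWarning):
            out = annotate_insertions(self._loc(1100), self._gff(tmp_path, "+"), attributes=["Name"])
        assert out.loc[0, "Name"] == ""


class TestMapLibrary:
    def test_roundtrip_error_free(self, tmp_path, small_genome, small_library, tn5_spec):
        fa = small_genome.write_fasta(str(tmp_path / "g.fna"))
        gff = small_genome.write_gff3(str(tmp_path / "g.gff3"))
        fq = str(tmp_path / "reads.fastq")
        sim_mapping_reads(small_library, tn5_spec, depth_per_barcode=10, seed=3, out_fastq=fq)
        res = map_library(fq, fa, gff, tn5_spec, output_dir=str(tmp_path), aligner=ExactAligner(fa))
        merged = small_library.truth.merge(res.library_map, on="barcode", how="outer", indicator=True)
        assert (merged["_merge"] == "both").all()
        assert (merged["site"] == merged["insertion_site"]).all()
        assert (merged["strand_x"] == merged["strand_y"]).all()
        assert (tmp_path / "library.annotated.csv").exists()

    def test_repeat_insertion_removed_multimapped(self, tmp_path, tn5_spec):
        genome = sim_genome(seed=4, length_bp=120_000, n_genes=40, repeat_copies=2)
        tail = int(120_000 * 0.9)
        lib = sim_library(
            genome, n_insertions=20, seed=5, sites_in_repeat=1,
            repeat_region=(tail + 1, tail + 1000),
        )
        fq = str(tmp_path / "r.fastq")
        sim_mapping_reads(lib, tn5_spec, depth_per_barcode=10, seed=6, out_fastq=fq)
        fa = genome.write_fasta(str(tmp_path / "g.fna"))
        res = map_library(fq, fa, None, tn5_spec, aligner=ExactAligner(fa))
        repeat_bc = lib.truth.iloc[0]["barcode"]
        assert repeat_bc not in set(res.library_map["barcode"])
        assert res.stats["barcodes_removed_multimapped"] >= 1

    def test_empty_fastq(self, tmp_path, small_genome, tn5_spec):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        fa = small_genome.write_fasta(str(tmp_path / "g.fna"))
        res = map_library(str(fq), fa, None, tn5_spec, aligner=ExactAligner(fa))
        assert res.library_map.empty
        assert res.stats["reads_scanned"] == 0
        assert res.stats["barcodes_final"] == 0


class TestBlastAgreement:
    def test_blast_matches_builtin_on_fixture(self, tmp_path, small_genome, small_library, tn5_spec):
        """blastn and the exact-substring engine place the same junctions."""
        pytest.importorskip("shutil")
        import shutil as _sh

        if _sh.which("blastn") is None or _sh.which("makeblastdb") is None:
            pytest.skip("BLAST+ not on PATH")
        from tnscreen import BlastAligner
        from tnscreen.construct import extract_from_read, iter_fastq

        fa = small_genome.write_fasta(str(tmp_path / "g.fna"))
        fq = str(tmp_path / "reads.fastq")
        sub = sim_library(small_genome, n_insertions=15, seed=9)
        sim_mapping_reads(sub, tn5_spec, depth_per_barcode=3, seed=9, out_fastq=fq)
        exts = [extract_from_read(rid, seq, tn5_spec, want_host=True) for rid, seq in iter_fastq(fq)]
        hosts = collect_host_sequences(exts)
        exact = align_hosts(hosts, fa, aligner=ExactAligner(fa))
        blast = align_hosts(hosts, fa, aligner=BlastAligner(fa))
        key = ["barcode", "host", "chrom", "position", "strand"]
        e = exact[exact["n_locations"] == 1][key].sort_values(key).reset_index(drop=True)
        b = blast[blast["n_locations"] == 1][key].sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(e, b)


def test_levenshtein_matches_dp_oracle():
    rng = np.random.default_rng(3)
    bases = np.array(list("ACGT"))
    for _ in range(200):
        a = "".join(rng.choice(bases, size=int(rng.integers(1, 12))))
        b = "".join(rng.choice(bases, size=int(rng.integers(1, 12))))
        assert levenshtein(a, b) == dp_levenshtein(a, b)
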