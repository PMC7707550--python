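import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainwss import (
    DepthTrack,
    SampleProfile,
    VariantCall,
    merge_profiles,
    qc_filter,
    read_depth,
    read_reference_catalog,
    read_variant_profiles,
)
from strainwss.errors import (
    CatalogError,
    CoordinateError,
    FormatError,
    InputError,
    MergeError,
)

from conftest import build_profile, build_reference


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_species_table(path, rows, header="species_id\tsequence_id\tcutoff"):
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


class TestReadReferenceCatalog:
    def test_single_record_readback(self, tmp_path):
        write_fasta(tmp_path / "r.fa", [("seq1", "ACGT" * 2500)])
        write_species_table(tmp_path / "t.tsv", [("sp1", "seq1", 0.80)])
        catalog = read_reference_catalog(tmp_path / "r.fa", tmp_path / "t.tsv")
        assert len(catalog) == 1
        genome = catalog[0]
        assert genome.species_id == "sp1"
        assert genome.length == 10_000
        assert genome.cutoff == 0.80

    def test_catalog_of_93(self, tmp_path):
        rng = np.random.default_rng(0)
        rows, records = [], []
        for i in range(93):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
            records.append((f"seq{i}", seq))
            rows.append((f"sp{i}", f"seq{i}", 0.5))
        write_fasta(tmp_path / "r.fa", records)
        write_species_table(tmp_path / "t.tsv", rows)
        catalog = read_reference_catalog(tmp_path / "r.fa", tmp_path / "t.tsv")
        assert len(catalog) == 93

    @pytest.mark.parametrize("sentinel", ["NA", "CO:NA"])
    def test_na_cutoff_absent(self, tmp_path, sentinel):
        write_fasta(tmp_path / "r.fa", [("seq1", "ACGT")])
        write_species_table(tmp_path / "t.tsv", [("sp1", "seq1", sentinel)])
        catalog = read_reference_catalog(tmp_path / "r.fa", tmp_path / "t.tsv")
        assert catalog[0].cutoff is None

    def test_cutoff_column_optional(self, tmp_path):
        write_fasta(tmp_path / "r.fa", [("seq1", "ACGT")])
        write_species_table(
            tmp_path / "t.tsv", [("sp1", "seq1")], header="species_id\tsequence_id"
        )
        catalog = read_reference_catalog(tmp_path / "r.fa", tmp_path / "t.tsv")
        assert catalog[0].cutoff is None

    def test_duplicate_sequence_id(self, tmp_path):
        write_fasta(tmp_path / "r.fa", [("seq1", "ACGT")])
        write_species_table(
            tmp_path / "t.tsv", [("sp1", "seq1", 0.5), ("sp2", "seq1", 0.5)]
        )
        with pytest.raises(CatalogError):
            read_reference_catalog(tmp_path / "r.fa", tmp_path / "t.tsv")

    def test_missing_sequence(self, tmp_path):
        write_fasta(tmp_path / "r.fa", [("seq1", "ACGT")])
        write_species_table(tmp_path / "t.tsv", [("sp1", "other", 0.5)])
        with pytest.raises(CatalogError):
            read_reference_catalog(tmp_path / "r.fa", tmp_path / "t.tsv")

    def test_empty_fasta(self, tmp_path):
        (tmp_path / "r.fa").write_text("")
        write_species_table(tmp_path / "t.tsv", [("sp1", "seq1", 0.5)])
        with pytest.raises(InputError):
            read_reference_catalog(tmp_path / "r.fa", tmp_path / "t.tsv")


class TestReadDepth:
    def test_direct_mapping(self, tmp_path):
        ref = build_reference(length=3, sequence_id="s")
        (tmp_path / "d.tsv").write_text("s\t1\t5\ns\t3\t7\n")
        track = read_depth(tmp_path / "d.tsv", ref)
        assert track.depth.tolist() == [5, 0, 7]

    def test_empty_file_all_zero(self, tmp_path):
        ref = build_reference(length=4, sequence_id="s")
        (tmp_path / "d.tsv").write_text("")
        assert read_depth(tmp_path / "d.tsv", ref).depth.tolist() == [0, 0, 0, 0]

    def test_out_of_bounds_position(self, tmp_path):
        ref = build_reference(length=3, sequence_id="s")
        (tmp_path / "d.tsv").write_text("s\t4\t2\n")
        with pytest.raises(CoordinateError):
            read_depth(tmp_path / "d.tsv", ref)

    def test_negative_depth(self, tmp_path):
        ref = build_reference(length=3, sequence_id="s")
        (tmp_path / "d.tsv").write_text("s\t1\t-1\n")
        with pytest.raises(FormatError):
            read_depth(tmp_path / "d.tsv", ref)

    def test_other_chrom_rows_ignored_and_sum_matches(self, tmp_path):
        ref = build_reference(length=10, sequence_id="s")
        rng = np.random.default_rng(3)
        rows, expected = [], 0
        for chrom in ("s", "other"):
            for pos in range(1, 11):
                d = int(rng.integers(0, 30))
                rows.append(f"{chrom}\t{pos}\t{d}")
                if chrom == "s":
                    expected += d
        (tmp_path / "d.tsv").write_text("\n".join(rows) + "\n")
        track = read_depth(tmp_path / "d.tsv", ref)
        assert int(track.depth.sum()) == expected


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=ref1,length=1000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
)


class TestReadVariantProfiles:
    def _read(self, tmp_path, body):
        ref = build_reference(length=1000, sequence_id="ref1")
        vcf = tmp_path / "v.vcf"
        vcf.write_text(VCF_HEADER + body)
        depth = np.full(1000, 10, dtype=np.int64)
        depths = {
            "A": DepthTrack(reference=ref, depth=depth.copy()),
            "B": DepthTrack(reference=ref, depth=depth.copy()),
        }
        return read_variant_profiles(vcf, ref, depths)

    def test_genotype_semantics(self, tmp_path):
        profiles = self._read(
            tmp_path, "ref1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t0/0\n"
        )
        a, b = profiles
        assert set(a.calls) == {100}
        assert a.calls[100].genotype_state == 1
        assert a.calls[100].alt_allele == "C"
        assert a.calls[100].depth_at_site == 10
        assert b.calls == {}

    def test_multiallelic_states(self, tmp_path):
        profiles = self._read(
            tmp_path, "ref1\t100\t.\tA\tC,G\t.\tPASS\t.\tGT\t1/1\t2/2\n"
        )
        a, b = profiles
        assert a.calls[100].genotype_state == 1
        assert a.calls[100].alt_allele == "C"
        assert b.calls[100].genotype_state == 2
        assert b.calls[100].alt_allele == "G"

    def test_indel_records_skipped(self, tmp_path):
        profiles = self._read(
            tmp_path,
            "ref1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t0/0\n"
            "ref1\t200\t.\tAT\tA\t.\tPASS\t.\tGT\t1/1\t1/1\n"
            "ref1\t300\t.\tA\tACG\t.\tPASS\t.\tGT\t1/1\t1/1\n",
        )
        a, b = profiles
        assert set(a.calls) == {100}
        assert b.calls == {}

    def test_missing_genotype_is_no_call(self, tmp_path):
        profiles = self._read(
            tmp_path, "ref1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t./.\t1/1\n"
        )
        a, b = profiles
        assert a.calls == {}
        assert set(b.calls) == {100}

    def test_chrom_mismatch(self, tmp_path):
        with pytest.raises(InputError):
            self._read(tmp_path, "chrX\t100\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t0/0\n")

    def test_breadth_and_mean_depth_from_track(self, tmp_path):
        profiles = self._read(
            tmp_path, "ref1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t0/0\n"
        )
        for p in profiles:
            assert p.breadth == 1.0
            assert p.mean_depth == 10.0


class TestQCFilter:
    def _profile_with(self, breadth, mean_depth):
        # `breadth` fraction of 1000 bases covered, total depth = 1000*mean
        ref = build_reference(length=1000)
        covered = int(round(breadth * 1000))
        depth = np.zeros(1000, dtype=np.int64)
        if covered:
            total = int(round(mean_depth * 1000))
            per_base = total // covered
            depth[:covered] = per_base
            depth[0] += total - per_base * covered
        return build_profile(ref, states={}, depth=depth)

    def test_low_breadth_fails_with_reason(self):
        profile = self._profile_with(breadth=0.29, mean_depth=10)
        decision = qc_filter(profile)
        assert not decision.passed
        assert [r["metric"] for r in decision.reasons] == ["coverage"]

    def test_exact_boundaries_pass(self):
        profile = self._profile_with(breadth=0.30, mean_depth=3.5)
        assert profile.breadth == 0.30
        assert profile.mean_depth == 3.5
        assert qc_filter(profile).passed

    def test_low_depth_fails_with_reason(self):
        profile = self._profile_with(breadth=0.90, mean_depth=3.4)
        decision = qc_filter(profile)
        assert not decision.passed
        assert [r["metric"] for r in decision.reasons] == ["depth"]

    def test_both_failures_reported(self):
        profile = self._profile_with(breadth=0.10, mean_depth=1.0)
        decision = qc_filter(profile)
        assert {r["metric"] for r in decision.reasons} == {"coverage", "depth"}

    def test_depth_over_covered_flag(self):
        # 29% covered at depth 12: genome-wide mean 3.48 fails, covered mean passes
        profile = self._profile_with(breadth=0.29, mean_depth=3.48)
        assert not qc_filter(profile, breadth_min=0.2).passed
        assert qc_filter(profile, breadth_min=0.2, depth_over_covered=True).passed

    @given(
        covered=st.integers(min_value=0, max_value=50),
        extra=st.integers(min_value=0, max_value=50),
        per_base=st.integers(min_value=1, max_value=12),
        boost=st.integers(min_value=0, max_value=10),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_coverage_and_depth(self, covered, extra, per_base, boost):
        """Raising breadth or depth never flips passed -> failed."""
        ref = build_reference(length=50)
        depth = np.zeros(50, dtype=np.int64)
        depth[:covered] = per_base
        base = build_profile(ref, depth=depth)
        richer_depth = depth.copy() + boost
        richer_depth[: min(covered + extra, 50)] = np.maximum(
            richer_depth[: min(covered + extra, 50)], per_base + boost
        )
        richer = build_profile(ref, depth=richer_depth)
        if qc_filter(base).passed:
            assert qc_filter(richer).passed


class TestMergeProfiles:
    def test_identical_profiles_double_depth(self):
        ref = build_reference()
        p = build_profile(ref, states={100: 1, 200: 2}, depth=10)
        merged = merge_profiles([p, p])
        assert set(merged.calls) == {100, 200}
        assert merged.calls[100].genotype_state == 1
        assert (merged.depth.depth == 20).all()
        assert merged.mean_depth == 20.0

    def test_depth_weighted_majority(self):
        ref = build_reference()
        depth_a = np.full(1000, 10, dtype=np.int64)
        depth_b = np.full(1000, 2, dtype=np.int64)
        a = build_profile(ref, states={100: 1}, depth=depth_a, sample_id="a", individual_id="I")
        b = build_profile(ref, states={}, depth=depth_b, sample_id="b", individual_id="I")
        merged = merge_profiles([a, b])
        assert merged.calls[100].genotype_state == 1

    def test_reference_majority_drops_call(self):
        ref = build_reference()
        a = build_profile(ref, states={100: 1}, depth=2, sample_id="a", individual_id="I")
        b = build_profile(ref, states={}, depth=10, sample_id="b", individual_id="I")
        merged = merge_profiles([a, b])
        assert 100 not in merged.calls

    def test_tie_broken_by_larger_site_depth(self):
        ref = build_reference()
        # equal summed weight per state (10 vs 10), but b's single-site depth wins
        a1 = build_profile(ref, states={100: 1}, depth=5, sample_id="a1", individual_id="I")
        a2 = build_profile(ref, states={100: 1}, depth=5, sample_id="a2", individual_id="I")
        b = build_profile(ref, states={100: 2}, depth=10, sample_id="b", individual_id="I")
        merged = merge_profiles([a1, a2, b])
        assert merged.calls[100].genotype_state == 2

    def test_remaining_tie_prefers_lower_allele_index(self):
        ref = build_reference()
        a = build_profile(ref, states={100: 2}, depth=10, sample_id="a", individual_id="I")
        b = build_profile(ref, states={100: 1}, depth=10, sample_id="b", individual_id="I")
        merged = merge_profiles([a, b])
        assert merged.calls[100].genotype_state == 1

    def test_single_profile_identity(self):
        ref = build_reference()
        p = build_profile(ref, states={5: 1}, depth=7)
        merged = merge_profiles([p])
        assert merged.calls == p.calls
        assert (merged.depth.depth == p.depth.depth).all()
        assert merged.breadth == p.breadth

    def test_commutative(self):
        ref = build_reference()
        a = build_profile(ref, states={100: 1, 300: 2}, depth=4, sample_id="a", individual_id="I")
        b = build_profile(ref, states={100: 2, 200: 1}, depth=9, sample_id="b", individual_id="I")
        c = build_profile(ref, states={300: 2}, depth=6, sample_id="c", individual_id="I")
        forward = merge_profiles([a, b, c], sample_id="m")
        backward = merge_profiles([c, b, a], sample_id="m")
        assert forward.calls == backward.calls
        assert (forward.depth.depth == backward.depth.depth).all()

    def test_mixed_references_rejected(self):
        a = build_profile(build_reference(sequence_id="r1"), sample_id="x")
        b = build_profile(build_reference(sequence_id="r2"), sample_id="x")
        with pytest.raises(MergeError):
            merge_profiles([a, b])

    def test_metrics_recomputed_after_merge(self):
        ref = build_reference(length=10)
        depth_a = np.array([0, 0, 3, 3, 0, 0, 0, 0, 0, 0])
        depth_b = np.array([1, 0, 0, 0, 0, 2, 0, 0, 0, 0])
        a = build_profile(ref, depth=depth_a, sample_id="a", individual_id="I")
        b = build_profile(ref, depth=depth_b, sample_id="b", individual_id="I")
        merged = merge_profiles([a, b])
        assert merged.breadth == 4 / 10
        assert merged.mean_depth == 9 / 10
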