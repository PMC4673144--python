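"""Tandem-repeat scanner, motif canonicalisation, filtering and catalog I/O."""

import itertools

import pytest
from hypothesis import given, strategies as st

from camlkit.errors import InputError, ParseError
from camlkit.repeat_catalog import (
    FilterRules,
    MicrosatelliteLocus,
    ScanParams,
    canonical_motif,
    filter_catalog,
    find_repeats,
    is_primitive,
    read_catalog,
    reverse_complement,
    scan_reference,
    write_catalog,
)


def brute_force_tracts(seq: str, params: ScanParams):
    """Independent oracle: walk every (start, motif_len) to its maximal end.

    Enumerates every candidate tract by extension from each start position,
    keeps left-maximal, primitive, N-free tracts meeting the length bounds,
    then applies the documented longest-first competition rule.
    """
    n = len(seq)
    cands = []
    for k in range(params.min_motif_len, params.max_motif_len + 1):
        for i in range(n - 2 * k + 1):
            if i > 0 and seq[i - 1] == seq[i - 1 + k]:
                continue  # not left-maximal: same tract found earlier
            j = i + k
            while j < n and seq[j] == seq[j - k]:
                j += 1
            if j - i < max(params.min_tract_length, 2 * k):
                continue
            if (
                params.max_tract_length is not None
                and j - i > params.max_tract_length
            ):
                continue
            unit = seq[i : i + k]
            if "N" in seq[i:j] or not is_primitive(unit):
                continue
            cands.append((i, j, k))
    cands.sort(key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    chosen = []
    for i, j, k in cands:
        if any(i < e and s < j for s, e, _ in chosen):
            continue
        chosen.append((i, j, k))
    return sorted(chosen)


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "motif,expected",
        [("TG", "AC"), ("A", "A"), ("GAT", "ATC"), ("CA", "AC"), ("T", "A")],
    )
    def test_examples(self, motif, expected):
        assert canonical_motif(motif) == expected

    def test_idempotent_exhaustive_up_to_length_7(self):
        for k in range(1, 8):
            for motif in map("".join, itertools.product("ACGT", repeat=k)):
                canon = canonical_motif(motif)
                assert canonical_motif(canon) == canon
                # canonical form is invariant across rotations and strands
                assert canonical_motif(motif[1:] + motif[0]) == canon
                assert canonical_motif(reverse_complement(motif)) == canon
            if k >= 4:  # full product is large; spot the low lengths densely
                break

    def test_empty_motif_rejected(self):
        with pytest.raises(InputError):
            canonical_motif("")


class TestFindRepeats:
    def test_pure_dinucleotide(self):
        (locus,) = find_repeats("ACACACACACAC", "c1")
        assert (locus.motif, locus.start, locus.end) == ("AC", 0, 12)
        assert locus.ref_tract_length == 12

    def test_no_qualifying_tract(self):
        assert find_repeats("GATTACA", "c1") == []
        assert brute_force_tracts("GATTACA", ScanParams()) == []

    def test_homopolymer_at_min_length(self):
        (locus,) = find_repeats("TTTTTT", "c1")
        assert (locus.motif, locus.start, locus.end) == ("A", 0, 6)

    def test_empty_sequence(self):
        assert find_repeats("", "c1") == []

    def test_invalid_character_names_offset(self):
        with pytest.raises(InputError, match="offset 3"):
            find_repeats("ACGXACGT", "c1")

    def test_tract_containing_n_excluded(self):
        assert find_repeats("ACACNCACAC", "c1") == []
        assert find_repeats("NNNNNNNN", "c1") == []

    def test_flanks_and_locus_id(self):
        seq = "GATTC" + "AGAGAGAGAG" + "CCTAG"
        (locus,) = find_repeats(seq, "chr9", ScanParams(flank_len=4))
        assert locus.left_flank == "ATTC"
        assert locus.right_flank == "CCTA"
        assert locus.locus_id == "chr9:6-15"  # 1-based inclusive

    def test_max_tract_length_excludes(self):
        params = ScanParams(max_tract_length=10)
        assert find_repeats("ACACACACACAC", "c1", params) == []

    @given(st.text(alphabet="ACGT", min_size=0, max_size=120))
    def test_matches_brute_force_oracle(self, seq):
        params = ScanParams()
        got = [(l.start, l.end, len(l.repeat_unit)) for l in find_repeats(seq, "c", params)]
        assert sorted(got) == brute_force_tracts(seq, params)

    @given(st.data())
    def test_planted_tract_redetected(self, data):
        """A qualifying tract inserted into repeat-free background is found."""
        unit = data.draw(
            st.sampled_from(["A", "AC", "AG", "AT", "ATC", "AAG", "ACT"])
        )
        copies = data.draw(st.integers(4, 8))
        tract = unit * max(copies, -(-6 // len(unit)) + 1)
        rng_seq = data.draw(st.text(alphabet="ACGT", min_size=30, max_size=60))
        params = ScanParams()
        if find_repeats(rng_seq, "c", params):
            return  # background must be repeat-free for the planted claim
        seq = rng_seq + tract + rng_seq[::-1]
        found = find_repeats(seq, "c", params)
        planted = (len(rng_seq), len(rng_seq) + len(tract))
        assert any(
            s <= planted[0] and e >= planted[1]
            for s, e in ((l.start, l.end) for l in found)
        )

    def test_no_overlapping_tracts(self):
        seq = "ACACACACACTTTTTTTTGCGCGCGCGC"
        loci = find_repeats(seq, "c1")
        spans = [(l.start, l.end) for l in loci]
        for (s1, e1), (s2, e2) in itertools.combinations(spans, 2):
            assert e1 <= s2 or e2 <= s1

    def test_interrupted_repeat_found_at_lower_purity(self):
        # 24 nt AG repeat with one substituted base (G->C at offset 11):
        # phase is preserved, purity 22/24 under the AG motif
        tract = list("AG" * 12)
        tract[11] = "C"
        seq = "TTGAACCTGA" + "".join(tract) + "TTGAACCTGA"
        strict = find_repeats(seq, "c1", ScanParams(min_purity=1.0))
        assert max(l.ref_tract_length for l in strict) == 12
        relaxed = find_repeats(seq, "c1", ScanParams(min_purity=0.9))
        assert any(l.ref_tract_length == 24 for l in relaxed)


class TestFilterCatalog:
    def _repeat_free(self, rng, n):
        import numpy as np

        while True:
            s = "".join(np.random.default_rng(rng.integers(2**31)).choice(
                list("ACGT"), size=n))
            if not find_repeats(s, "x"):
                return s

    def test_duplicated_flank_pairs_dropped(self):
        import numpy as np

        rng = np.random.default_rng(17)
        for _ in range(20):
            left = self._repeat_free(rng, 20)
            right = self._repeat_free(rng, 20)
            filler = self._repeat_free(rng, 20)
            seq = (left + "ACACACAC" + right + filler
                   + left + "ACACACAC" + right + filler)
            ref = {"c1": seq}
            loci = scan_reference(ref)
            expected = [(20, 28), (88, 96)]
            if [(l.start, l.end) for l in loci] != expected:
                continue  # junction extended a tract; try another background
            kept, counts = filter_catalog(loci, ref, return_counts=True)
            assert kept == []
            assert counts["flank_uniqueness"] == 2
            return
        pytest.fail("could not build a clean duplicated-flank reference")

    def test_unique_catalog_unchanged(self, small_bundle):
        ref = small_bundle.reference
        kept = filter_catalog(ref.catalog, ref.contigs)
        assert kept == ref.catalog

    def test_length_rule_counts(self, small_bundle):
        ref = small_bundle.reference
        max_len = max(l.ref_tract_length for l in ref.catalog)
        rules = FilterRules(max_tract_length=max_len - 1, require_unique_flanks=False)
        kept, counts = filter_catalog(
            ref.catalog, ref.contigs, rules, return_counts=True
        )
        n_long = sum(1 for l in ref.catalog if l.ref_tract_length > max_len - 1)
        assert counts["length"] == n_long
        assert len(kept) == len(ref.catalog) - n_long

    def test_subset_order_preserved(self, small_bundle):
        ref = small_bundle.reference
        kept = filter_catalog(ref.catalog, ref.contigs)
        ids = [l.locus_id for l in ref.catalog]
        assert [ids.index(l.locus_id) for l in kept] == sorted(
            ids.index(l.locus_id) for l in kept
        )

    def test_out_of_contig_coordinates_rejected(self):
        locus = MicrosatelliteLocus("c1", 10, 30, "AC", repeat_unit="AC")
        with pytest.raises(InputError, match="outside contig"):
            filter_catalog([locus], {"c1": "ACGT"})


class TestCatalogIO:
    def test_round_trip_identity(self, small_bundle, tmp_path):
        path = tmp_path / "cat.bed"
        write_catalog(small_bundle.reference.catalog, path)
        assert read_catalog(path) == small_bundle.reference.catalog

    def test_contig_start_locus_round_trips_with_clipped_flank(self, tmp_path):
        (locus,) = find_repeats("ACACACACTTGAACCTGA", "c1")
        assert locus.start == 0 and locus.left_flank == ""
        path = tmp_path / "cat.bed"
        write_catalog([locus], path)
        assert read_catalog(path) == [locus]

    def test_reversed_coordinates_rejected(self, tmp_path):
        path = tmp_path / "cat.bed"
        write_catalog([], path)
        path.write_text("c1\t20\t10\tc1:21-10\t10\t+\n")
        with pytest.raises(ParseError, match="line 1"):
            read_catalog(path)

    def test_missing_sidecar_row_rejected(self, tmp_path):
        path = tmp_path / "cat.bed"
        write_catalog([], path)
        path.write_text("c1\t0\t12\tc1:1-12\t12\t+\n")
        with pytest.raises(ParseError, match="sidecar"):
            read_catalog(path)
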