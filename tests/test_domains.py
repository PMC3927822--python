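"""Domain splitting, HIGH-motif scanning and Yqey detection."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glxrs import domains
from glxrs.domains import AlignedSet
from glxrs.simulate import AA_ALPHABET, _mutate_str, p_distance_to_branch, random_protein

HIGH_VARIANTS = {
    f"H{phi}G{x}" for phi in "IVL" for x in "GNSTLM"
}


def brute_force_motif(seq: str, window: int) -> tuple[int, str] | None:
    """Independent oracle: scan every 4-mer against the explicit variant set."""
    for i in range(min(window, len(seq) - 3)):
        if seq[i : i + 4] in HIGH_VARIANTS:
            return i + 1, seq[i : i + 4]
    return None


class TestSplitDomains:
    def test_ungapped_reference_468_splits_322_146(self, rng):
        ref = random_protein(468, rng)
        aln = AlignedSet(ids=["tt"], rows=[ref], reference_id="tt")
        (split,) = domains.split_domains(aln)
        assert len(split.n_domain) == 322
        assert len(split.c_domain) == 146
        assert split.split_column == 322

    def test_split_conservation_with_gaps(self, rng):
        ref = random_protein(30, rng)
        q = random_protein(10, rng)
        rows = [ref, "---" + q + "-" * (len(ref) - 13)]
        aln = AlignedSet(ids=["ref", "q"], rows=rows, reference_id="ref")
        for split in domains.split_domains(aln, boundary_residue=20):
            original = aln.row(split.id).replace("-", "")
            assert split.n_domain + split.c_domain == original

    def test_degenerate_row_flagged(self, rng):
        ref = random_protein(20, rng)
        q = random_protein(10, rng) + "-" * 10
        aln = AlignedSet(ids=["ref", "q"], rows=[ref, q], reference_id="ref")
        splits = {s.id: s for s in domains.split_domains(aln, boundary_residue=10)}
        assert splits["q"].c_domain == ""
        assert "empty_c_domain" in splits["q"].flags

    def test_simulated_fusion_point_recovered(self, rng):
        # fused sequence built as a 300-residue N + 150-residue C part,
        # aligned exactly to a same-coordinate reference
        n_part, c_part = random_protein(300, rng), random_protein(150, rng)
        ref = random_protein(450, rng)
        aln = AlignedSet(
            ids=["ref", "fused"], rows=[ref, n_part + c_part], reference_id="ref"
        )
        splits = {s.id: s for s in domains.split_domains(aln, boundary_residue=300)}
        assert splits["fused"].n_domain == n_part
        assert splits["fused"].c_domain == c_part

    def test_reference_errors(self, rng):
        short = AlignedSet(
            ids=["r"], rows=[random_protein(100, rng)], reference_id="r"
        )
        with pytest.raises(ValueError, match="100 residues"):
            domains.split_domains(short, boundary_residue=322)
        no_ref = AlignedSet(ids=["a"], rows=["ACDE"])
        with pytest.raises(ValueError, match="reference"):
            domains.split_domains(no_ref)


class TestHighMotif:
    @pytest.mark.parametrize(
        "prefix, variant, collapsed",
        [
            ("A" * 11, "HIGG", "HϕGG"),
            ("A" * 5, "HVGN", "HϕGN"),
            ("A" * 5, "HVGT", "HϕGT"),
            ("A" * 5, "HLGM", "HϕGM"),
        ],
    )
    def test_variants_found_and_collapsed(self, prefix, variant, collapsed):
        call = domains.find_high_motif(prefix + variant + "A" * 20)
        assert call.status == "found"
        assert call.variant == variant
        assert call.position == len(prefix) + 1
        assert domains.collapse_variant(call.variant) == collapsed

    def test_poly_alanine_absent(self):
        assert domains.find_high_motif("A" * 80).status == "absent"

    def test_window_limits_search(self):
        seq = "A" * 70 + "HIGG" + "A" * 10
        assert domains.find_high_motif(seq, window=60).status == "absent"
        assert domains.find_high_motif(seq, window=80).status == "found"

    def test_first_match_wins_and_all_hits_kept(self):
        seq = "A" * 5 + "HIGG" + "A" * 5 + "HVGN" + "A" * 40
        call = domains.find_high_motif(seq)
        assert call.variant == "HIGG" and call.position == 6
        assert call.all_hits == ((6, "HIGG"), (15, "HVGN"))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            domains.find_high_motif("")

    @settings(max_examples=300, derandomize=True)
    @given(
        st.text(alphabet=AA_ALPHABET, min_size=4, max_size=120),
        st.integers(min_value=4, max_value=80),
    )
    def test_regex_equals_brute_force_4mer_scan(self, seq, window):
        call = domains.find_high_motif(seq, window=window)
        expected = brute_force_motif(seq, window)
        if expected is None:
            assert call.status == "absent"
        else:
            assert (call.position, call.variant) == expected


class TestMotifCensus:
    def test_direct_counts(self):
        calls = [
            domains.find_high_motif("A" * 5 + v + "A" * 30, seq_id=f"s{i}")
            for i, v in enumerate(["HIGG", "HIGG", "HVGN"])
        ]
        census = domains.motif_census(calls, {f"s{i}": "g1" for i in range(3)})
        assert census.loc["HϕGG", "g1"] == 2
        assert census.loc["HϕGN", "g1"] == 1

    def test_found_plus_absent_equals_total(self):
        calls = [
            domains.find_high_motif(s, seq_id=f"s{i}")
            for i, s in enumerate(["A" * 10 + "HIGG" + "A" * 10, "A" * 40])
        ]
        census = domains.motif_census(calls, {"s0": "g", "s1": "g"})
        assert int(census["g"].sum()) == 2

    def test_unlabelled_id_rejected(self):
        call = domains.find_high_motif("A" * 40, seq_id="s0")
        with pytest.raises(ValueError, match="s0"):
            domains.motif_census([call], {})

    def test_empty_input(self):
        assert domains.motif_census([], {}).empty


class TestDetectYqey:
    @pytest.fixture
    def glnrs_alignment(self, rng):
        core = random_protein(673, rng)
        yqey = random_protein(143, rng)
        pad = "-" * 143
        return core, yqey, AlignedSet(
            ids=["core_ref", "yqey_ref"],
            rows=[core + pad, core + yqey],
        )

    def _with_query(self, aln, qid, row):
        return AlignedSet(ids=aln.ids + [qid], rows=aln.rows + [row])

    def test_yqey_reference_detects_itself(self, glnrs_alignment):
        core, yqey, aln = glnrs_alignment
        aln2 = self._with_query(aln, "q", core + yqey)
        call = domains.detect_yqey(
            "q", aln2, "yqey_ref", "core_ref", yqey_span=(674, 816)
        )
        assert call.present and call.identity_to_ref == pytest.approx(1.0)
        assert call.extension_length == 143

    def test_core_only_query_negative(self, glnrs_alignment):
        core, yqey, aln = glnrs_alignment
        aln2 = self._with_query(aln, "q", core + "-" * 143)
        call = domains.detect_yqey(
            "q", aln2, "yqey_ref", "core_ref", yqey_span=(674, 816)
        )
        assert not call.present and call.extension_length == 0

    def test_grafted_appendix_detected_across_replicates(self, glnrs_alignment):
        core, yqey, aln = glnrs_alignment
        t = p_distance_to_branch(0.30)  # 30% simulated divergence
        for seed in range(20):
            rep_rng = np.random.default_rng(seed)
            grafted = _mutate_str(core, 0.1, rep_rng) + _mutate_str(yqey, t, rep_rng)
            aln2 = self._with_query(aln, "q", grafted)
            call = domains.detect_yqey(
                "q", aln2, "yqey_ref", "core_ref", yqey_span=(674, 816)
            )
            assert call.present, f"graft missed at seed {seed}"
            assert call.identity_to_ref > 0.25

    def test_monotone_in_extension_length(self, glnrs_alignment, rng):
        # a detected appendix never un-detects when more of it is present
        core, yqey, aln = glnrs_alignment
        t = p_distance_to_branch(0.30)
        mutated = _mutate_str(yqey, t, rng)
        detected = []
        for keep in (80, 110, 143):
            row = core + mutated[:keep] + "-" * (143 - keep)
            aln2 = self._with_query(aln, "q", row)
            call = domains.detect_yqey(
                "q", aln2, "yqey_ref", "core_ref", yqey_span=(674, 816)
            )
            detected.append(call.present)
        assert detected == sorted(detected)  # once True, stays True

    def test_missing_reference_rejected(self, glnrs_alignment):
        core, yqey, aln = glnrs_alignment
        with pytest.raises(ValueError, match="absent"):
            domains.detect_yqey("core_ref", aln, "nope", "core_ref")


class TestAlignedSetIO:
    def test_fasta_roundtrip(self, tmp_path, rng):
        aln = AlignedSet(
            ids=["a", "b"], rows=[random_protein(30, rng), random_protein(30, rng)]
        )
        path = tmp_path / "aln.fasta"
        aln.to_fasta(path)
        back = AlignedSet.from_fasta(path)
        assert back.ids == aln.ids and back.rows == aln.rows

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            AlignedSet(ids=["a", "b"], rows=["AA", "AAA"])
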