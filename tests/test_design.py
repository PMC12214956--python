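"""Barcode design filters, orthogonality screens, library build, oligo assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyentag.design import (
    DesignParams,
    build_library,
    build_oligos,
    generate_candidates,
    generate_decoys,
    local_align_screen,
    longest_hairpin_stem,
    max_shared_substring,
    passes_composition,
    passes_structure,
    read_fasta,
    revcomp,
    write_fasta,
)

PARAMS = DesignParams()
seqs3 = st.text(alphabet="ACT", min_size=1, max_size=14)


# ---------------------------------------------------------------------------
# oracles

def _lcs_bruteforce(a: str, b: str) -> int:
    best = 0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            if a[i:j] in b:
                best = max(best, j - i)
    return best


def _sw_bruteforce(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    H = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    best = 0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            H[i][j] = max(0, diag, H[i - 1][j] + gap, H[i][j - 1] + gap)
            best = max(best, H[i][j])
    return best


# ---------------------------------------------------------------------------
# candidate generation

def test_candidates_alphabet_length_and_count():
    params = DesignParams(
        alphabet=("A", "C"), length=4, max_shared_substring=4,
        candidate_count=500, rng_seed=3,
    )
    cands = generate_candidates(params)
    assert len(cands) == 500
    assert all(len(s) == 4 and set(s) <= {"A", "C"} for s in cands)


def test_candidates_reproducible_and_empty_case():
    p = DesignParams(candidate_count=50, rng_seed=11)
    assert generate_candidates(p) == generate_candidates(p)
    assert generate_candidates(DesignParams(candidate_count=0)) == []


def test_tiny_alphabet_rejected():
    with pytest.raises(ValueError):
        DesignParams(alphabet=("A",))


# ---------------------------------------------------------------------------
# composition / structure filters

@pytest.mark.parametrize(
    "seq,ok",
    [
        ("AAAAACTCTCTCTCTCTCTC", False),  # run of 5 A's
        ("CCCCTATATATATATATATA", False),  # run of 4 C's
        ("ACCTACCTACCTACTATACC", True),  # 8 C's -> 0.40, runs within limits
        ("ATATATATATATATATATAT", False),  # no C at all: fraction 0 < 0.30
        ("TTTTTACCCACCCACCCACC", False),  # run of 5 T's
    ],
)
def test_composition_filter(seq, ok):
    assert passes_composition(seq, PARAMS) is ok


@settings(deadline=None, max_examples=60)
@given(st.text(alphabet="ACT", min_size=20, max_size=20))
def test_composition_matches_direct_recount(seq):
    import re

    runs = {c: max((len(m) for m in re.findall(f"{c}+", seq)), default=0) for c in "ATC"}
    expected = (
        0.30 <= seq.count("C") / 20 <= 0.70
        and runs["A"] <= 4 and runs["T"] <= 4 and runs["C"] <= 3
    )
    assert passes_composition(seq, PARAMS) is expected


def test_planted_stem_rejected():
    # AAAAA ... TTTTT with a long loop is a perfect 5-bp A:T stem
    seq = "AAAAA" + "CACCT" + "TTTTT" + "CCTCA"
    assert longest_hairpin_stem(seq) >= 5
    assert not passes_structure(seq, PARAMS)


def test_adjacent_complementary_halves_not_a_stem():
    # 5-bp complementary halves separated by < 3 nt do not count; only the
    # shorter loop>=3 sub-stems remain, which stay under the cutoff
    seq = "CCA" + "AAAAA" + "TTTTT" + "ACC"
    assert longest_hairpin_stem(seq, min_loop=3) < 5
    assert passes_structure(seq, PARAMS)


def test_no_g_sequences_only_pair_a_with_t():
    # no G in the alphabet means no C:G pairs: a C-rich sequence cannot stem
    assert longest_hairpin_stem("CCCACCCACCCACCCACCCA") == 0


@settings(deadline=None, max_examples=30)
@given(st.text(alphabet="ACT", min_size=8, max_size=16))
def test_stem_length_matches_bruteforce(seq):
    # brute-force: enumerate all disjoint substring pairs with loop >= 3
    n = len(seq)
    best = 0
    for L in range(1, n // 2 + 1):
        for i in range(n - L + 1):
            for j in range(i + L + 3, n - L + 1):
                if revcomp(seq[i : i + L]) == seq[j : j + L]:
                    best = max(best, L)
    assert longest_hairpin_stem(seq) == best


# ---------------------------------------------------------------------------
# pairwise screens

def test_shared_substring_identity_and_disjoint():
    assert max_shared_substring("ACTACT", "ACTACT", False) == 6
    assert max_shared_substring("ACTACT", "TTTTTT", False) == 1
    assert max_shared_substring("AAAA", "CCCC", False) == 0


def test_shared_substring_revcomp_orientation():
    a = "AAACCCTTT"
    b = revcomp(a)
    assert max_shared_substring(a, b, check_revcomp=True) == len(a)


@settings(deadline=None, max_examples=60)
@given(seqs3, seqs3)
def test_shared_substring_matches_bruteforce_and_symmetry(a, b):
    got = max_shared_substring(a, b, check_revcomp=False)
    assert got == _lcs_bruteforce(a, b)
    assert got == max_shared_substring(b, a, check_revcomp=False)
    both = max_shared_substring(a, b, check_revcomp=True)
    assert both == max(got, _lcs_bruteforce(a, revcomp(b)))


def test_local_align_perfect_and_single_substitution():
    a = "ACCTACCTACCTACTATACC"
    assert local_align_screen(a, a, PARAMS) == 20
    b = a[:10] + ("A" if a[10] != "A" else "T") + a[11:]
    assert local_align_screen(a, b, PARAMS) == 18


@settings(deadline=None, max_examples=40)
@given(seqs3, seqs3)
def test_local_align_matches_dp_oracle(a, b):
    assert local_align_screen(a, b, PARAMS) == _sw_bruteforce(a, b)


def test_local_align_at_least_shared_substring():
    a, b = "ACCTACCTAC", "TTACCTACTT"
    assert local_align_screen(a, b, PARAMS) >= max_shared_substring(a, b, False)


# ---------------------------------------------------------------------------
# library build

def test_build_library_target_reached_and_invariants(library25):
    assert len(library25) == 25 and library25.complete
    library25.validate()


def test_build_library_pairwise_orthogonality_bruteforce(library25):
    for i, a in enumerate(library25.barcodes):
        for b in library25.barcodes[i + 1 :]:
            assert _lcs_bruteforce(a, b) <= 10
            assert _lcs_bruteforce(a, revcomp(b)) <= 10


def test_build_library_deterministic(library25):
    again = build_library(DesignParams(rng_seed=0), target_size=25)
    assert again.barcodes == library25.barcodes
    assert again.shared_domains == library25.shared_domains
    assert again.to_json() == library25.to_json()


def test_build_library_single_member():
    lib = build_library(DesignParams(candidate_count=100, rng_seed=5), target_size=1)
    assert len(lib) == 1


def test_acceptance_rate_exceeds_ticket_capacity():
    # exhaustive greedy pass over the full default candidate pool: far more
    # orthogonal survivors than the 25 needed for one ticket
    lib = build_library(DesignParams(), target_size=None)
    assert len(lib) > 25


def test_library_json_roundtrip(library25):
    from hyentag.design import BarcodeLibrary

    clone = BarcodeLibrary.from_json(library25.to_json())
    assert clone.barcodes == library25.barcodes
    assert clone.params == library25.params


# ---------------------------------------------------------------------------
# oligo assembly

def test_oligo_domain_identities(library25):
    T = library25.shared_domains["T"]
    U = library25.shared_domains["U"]
    X = library25.shared_domains["X"]
    sets = [build_oligos(library25, i) for i in range(1, 6)]
    for i, o in enumerate(sets, start=1):
        si = library25.barcodes[i - 1]
        assert len(o.tag_strand) == len(T) + len(U) + len(si)
        # blocker is the revcomp of the tag strand's T*.U* prefix
        assert revcomp(o.blocker_strand) == o.tag_strand[: len(U) + len(T)]
        # probe's Si.U region revcomp-matches the anchor's U*.Si* region
        assert revcomp(si + U) == o.anchor_strand[: len(U) + len(si)]
        assert o.anchor_strand.endswith("T" * 30)
        assert o.probe_strand == X + si + U + T
        assert o.fluorophore_strand == revcomp(X)
    assert len({o.blocker_strand for o in sets}) == 1  # universal blocker


def test_anchor_polyt_orientation_configurable(library25):
    o5 = build_oligos(library25, 1, anchor_polyt_at_3prime=False)
    assert o5.anchor_strand.startswith("T" * 30)


def test_oligo_index_bounds(library25):
    with pytest.raises(IndexError):
        build_oligos(library25, 0)
    with pytest.raises(IndexError):
        build_oligos(library25, len(library25) + 1)


def test_decoys_format_and_distinctness(library25):
    assert generate_decoys(library25, 0) == []
    decoys = generate_decoys(library25, 200, rng_seed=1)
    prefix = revcomp(library25.shared_domains["T"]) + revcomp(library25.shared_domains["U"])
    assert all(d.startswith(prefix) for d in decoys)
    tails = [d[len(prefix) :] for d in decoys]
    assert all(set(t) <= set("ACGT") and len(t) == 20 for t in tails)
    assert len(set(tails)) == 200  # n << 4^20: collisions essentially impossible


def test_fasta_roundtrip(tmp_path, library25):
    sets = [build_oligos(library25, i) for i in (1, 2, 3)]
    path = tmp_path / "oligos.fasta"
    write_fasta(sets, path)
    lines = path.read_text().splitlines()
    assert sum(1 for ln in lines if ln.startswith(">")) == 15  # five strands per bit
    back = read_fasta(path)
    assert back == sets
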