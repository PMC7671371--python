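"""Digestion tests: single-enzyme splitting, modes, miscleavage, summaries."""

import random

import pytest

from pepdigest import (
    CONCURRENT,
    WATER_MASS,
    DigestJob,
    compile_enzyme,
    digest_concurrent,
    digest_one,
    digest_record,
    digest_sequential,
    load_builtin,
    peptide_mass,
    size_range_summary,
)
from pepdigest.fixtures import generate_fixtures


def seqs(peptides):
    return [p.sequence for p in peptides]


# ---------------------------------------------------------------------------
# digest_one
# ---------------------------------------------------------------------------


def test_digest_one_worked_example(staph_peptidase):
    peps = digest_one("aeert", staph_peptidase)
    assert seqs(peps) == ["ae", "ert"]
    assert [p.ordinal for p in peps] == [1, 2]
    assert [p.cleavage_position for p in peps] == [2, 0]
    assert [p.length for p in peps] == [2, 3]


def test_digest_one_full_miscleavage_returns_parent(trypsin):
    peps = digest_one("kkkkrk", trypsin, miscleavage_pct=100, rng=random.Random(0))
    assert seqs(peps) == ["kkkkrk"]
    assert peps[0].cleavage_position == 0


def test_digest_one_trypsin_wkp_motif(trypsin):
    assert seqs(digest_one("wkpakpa", trypsin)) == ["wk", "pakpa"]


def test_peptides_concatenate_to_parent(trypsin, catalog):
    for name in ("trypsin", "pepsin-ph2", "thermolysin", "tev"):
        enzyme = catalog.get(name)
        for rec in generate_fixtures(seed=5, n_records=5):
            peps = digest_one(rec.sequence, enzyme)
            assert "".join(seqs(peps)) == rec.sequence


def test_mass_conservation_under_digestion(catalog):
    for rec in generate_fixtures(seed=9, n_records=5):
        peps = digest_one(rec.sequence, catalog.get("trypsin"))
        total = sum(p.mass for p in peps)
        expected = peptide_mass(rec.sequence) + (len(peps) - 1) * WATER_MASS
        assert total == pytest.approx(expected, abs=1e-6)


# ---------------------------------------------------------------------------
# sequential mode
# ---------------------------------------------------------------------------


def test_sequential_is_concatenation_of_independent_digests(catalog):
    enzymes = [catalog.get("trypsin"), catalog.get("staphylococcal-peptidase-i")]
    record = ("r1", "wkpaeekrng")
    job = DigestJob(enzymes)
    combined = list(digest_sequential([record], job))
    separate = digest_one(record[1], enzymes[0], parent_id="r1") + digest_one(
        record[1], enzymes[1], parent_id="r1"
    )
    assert combined == separate


def test_sequential_records_are_independent(trypsin):
    job = DigestJob([trypsin])
    two = list(digest_sequential([("a", "wkpak"), ("b", "krkr")], job))
    one_a = list(digest_sequential([("a", "wkpak")], job))
    one_b = list(digest_sequential([("b", "krkr")], job))
    assert two == one_a + one_b


def test_sequential_empty_input_is_error(trypsin):
    with pytest.raises(ValueError):
        list(digest_sequential([], DigestJob([trypsin])))


# ---------------------------------------------------------------------------
# concurrent mode
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def before_p_unless_k():
    # cleaves before p (P1') unless k follows in P2'
    return compile_enzyme(
        "before-p-unless-k", [("(,p)", False), ("(,p)(k)", True)]
    )


def test_concurrent_frees_blocked_site(before_p_unless_k, catalog):
    job = DigestJob([before_p_unless_k, catalog.get("lys-n")], mode=CONCURRENT)
    peps = list(digest_concurrent([("t", "aapkaa")], job))
    assert seqs(peps) == ["aa", "p", "kaa"]
    assert [p.ordinal for p in peps] == [1, 2, 3]
    assert [p.cleavage_position for p in peps] == [2, 3, 0]


def test_concurrent_single_enzyme_equals_digest_one(trypsin):
    record = ("r", "wkpakrkkra")
    job = DigestJob([trypsin], mode=CONCURRENT)
    conc = seqs(digest_concurrent([record], job))
    assert conc == seqs(digest_one(record[1], trypsin, parent_id="r"))


def test_concurrent_is_idempotent(before_p_unless_k, catalog):
    job = DigestJob([before_p_unless_k, catalog.get("lys-n")], mode=CONCURRENT)
    first = list(digest_concurrent([("t", "aapkaapkaa")], job))
    again = list(
        digest_concurrent([(p.sequence, p.sequence) for p in first], job)
    )
    assert seqs(again) == seqs(first)


def test_concurrent_union_for_context_free_enzymes(catalog):
    # without sub-rules, concurrent sites are the union of sequential ones
    enzymes = [catalog.get("arg-c"), catalog.get("lys-n"), catalog.get("bnps-skatole")]
    seq = "arkwa" * 8
    job = DigestJob(enzymes, mode=CONCURRENT)
    conc = seqs(digest_concurrent([("r", seq)], job))
    bonds = set()
    for e in enzymes:
        from pepdigest import find_sites

        bonds.update(find_sites(seq, e))
    expected = [
        seq[a:b] for a, b in zip([0, *sorted(bonds)], [*sorted(bonds), len(seq)])
    ]
    assert conc == expected


def test_concurrent_reconstructs_parent(before_p_unless_k, catalog):
    job = DigestJob([before_p_unless_k, catalog.get("trypsin")], mode=CONCURRENT)
    for rec in generate_fixtures(seed=13, n_records=5):
        peps = list(digest_concurrent([(rec.id, rec.sequence)], job))
        assert "".join(seqs(peps)) == rec.sequence


# ---------------------------------------------------------------------------
# miscleavage
# ---------------------------------------------------------------------------


def test_miscleavage_statistics_binomial(hydroxylamine):
    # 20 planted sites, p = 25%: kept sites over 2000 trials ~ Binomial
    seq = "a" + "nga" * 20
    n_sites, pct, trials = 20, 25.0, 2000
    rng = random.Random(4242)
    kept = 0
    for _ in range(trials):
        kept += len(digest_one(seq, hydroxylamine, pct, rng)) - 1
    n = n_sites * trials
    p = 1 - pct / 100
    mean, sd = n * p, (n * p * (1 - p)) ** 0.5
    assert abs(kept - mean) < 4 * sd


def test_seed_reproducibility(trypsin):
    records = [("r", "wkpakrkkra" * 3)]
    job = lambda: DigestJob([trypsin], miscleavage={"trypsin": 50.0}, seed=77)
    first = list(digest_sequential(records, job()))
    second = list(digest_sequential(records, job()))
    assert first == second


def test_digest_record_matches_mode_dispatch(trypsin):
    rec = ("r", "wkpakr")
    assert digest_record(rec, DigestJob([trypsin])) == digest_one(
        rec[1], trypsin, parent_id="r"
    )


# ---------------------------------------------------------------------------
# size-range summary
# ---------------------------------------------------------------------------


def _pep(seq):
    return digest_one(seq, load_builtin("lys-c"))[0]


def test_size_range_boundaries_inclusive():
    peps = [_pep("g"), _pep("ggggg"), _pep("w" * 26), _pep("w" * 60)]
    masses = [p.mass for p in peps]
    lo, hi = masses[1], masses[2]
    summary = size_range_summary(peps, lo, hi)
    assert summary.count == 2  # both boundary peptides included
    assert summary.residues == peps[1].length + peps[2].length


def test_size_range_fraction_consistency(catalog):
    peps = []
    for rec in generate_fixtures(seed=3, n_records=10):
        peps.extend(digest_one(rec.sequence, catalog.get("trypsin")))
    s_in = size_range_summary(peps, 600, 5000)
    below = size_range_summary(peps, 0, 599.9999)
    above = size_range_summary(peps, 5000.0001, 10**9)
    assert s_in.count + below.count + above.count == s_in.total_peptides
    assert s_in.residues + below.residues + above.residues == s_in.total_residues
    assert s_in.fraction == pytest.approx(s_in.count / len(peps))


def test_size_range_empty_and_bad_bounds():
    s = size_range_summary([], 600, 5000)
    assert (s.count, s.fraction, s.residues, s.residue_fraction) == (0, 0, 0, 0)
    with pytest.raises(ValueError):
        size_range_summary([], 600, 500)
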