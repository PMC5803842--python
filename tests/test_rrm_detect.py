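import numpy as np
import pytest

from ptbscan.errors import FormatError, ParameterError
from ptbscan.rrm_detect import (
    RRMProfile,
    classify_ptb,
    default_profiles,
    detect_rnps,
    load_profiles,
    locate_rrms,
)
from ptbscan.seq_io import SeqRecord
from ptbscan.synthetic import gen_ptb_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


def test_packaged_profiles_structurally_valid(profiles):
    assert [p.name for p in profiles] == ["RRM1", "RRM2", "RRM3", "RRM4"]
    for p in profiles:
        assert 60 <= len(p) <= 120
        for s, e in (p.rnp1, p.rnp2):
            assert 0 <= s < e <= len(p)
            assert 6 <= e - s <= 8
        assert p.rnp2[1] <= p.rnp1[0]  # RNP2 precedes RNP1 in an RRM


def test_profile_validation_rejects_bad_spans():
    with pytest.raises(ParameterError):
        RRMProfile(name="bad", residues="A" * 90, rnp1=(85, 95), rnp2=(10, 16))
    with pytest.raises(ParameterError):
        RRMProfile(name="short", residues="A" * 40, rnp1=(20, 27), rnp2=(5, 11))


def test_load_profiles_requires_rnp_tags(tmp_path):
    p = tmp_path / "prof.fasta"
    p.write_text(">RRM1 no tags here\n" + "A" * 90 + "\n")
    with pytest.raises(FormatError):
        load_profiles(p)


def test_self_match_recovers_all_planted_rrms(profiles):
    """Concatenating the profiles with random linkers yields 4 perfect ordered hits."""
    rec, truth = gen_ptb_protein(profiles, n_rrms=4, linker_len_range=(20, 20), mutation_rate=0.0, seed=0)
    hits = locate_rrms(rec, profiles)
    assert [h.profile_name for h in hits] == ["RRM1", "RRM2", "RRM3", "RRM4"]
    assert all(h.identity_pct == 100.0 for h in hits)
    assert [list(h.query_span) for h in hits] == truth.features["rrm_spans"]
    # RNP boxes map to the profile offsets shifted by the hit start
    for h, p in zip(hits, profiles):
        assert h.rnp1_span == (h.query_span[0] + p.rnp1[0], h.query_span[0] + p.rnp1[1])
        assert h.rnp2_span == (h.query_span[0] + p.rnp2[0], h.query_span[0] + p.rnp2[1])
        assert not h.rnp1_flagged and not h.rnp2_flagged


def test_three_rrm_construct_gives_three_hits(profiles):
    rec, _ = gen_ptb_protein(profiles, n_rrms=3, mutation_rate=0.0, seed=1)
    hits = locate_rrms(rec, profiles)
    assert [h.profile_name for h in hits] == ["RRM1", "RRM2", "RRM3"]


def test_hits_never_overlap_and_are_deterministic(profiles):
    rec, _ = gen_ptb_protein(profiles, n_rrms=4, mutation_rate=0.2, seed=9)
    hits1 = locate_rrms(rec, profiles)
    hits2 = locate_rrms(rec, profiles)
    assert hits1 == hits2
    for a, b in zip(hits1, hits1[1:]):
        assert a.query_span[1] <= b.query_span[0]


def test_mutated_planted_spans_recovered(profiles):
    """At 20% substitution, recovered spans overlap planted spans by >=80% Jaccard."""
    ok = 0
    trials = 40
    for seed in range(trials):
        rec, truth = gen_ptb_protein(profiles, n_rrms=4, mutation_rate=0.2, seed=seed)
        hits = {h.profile_name: h.query_span for h in locate_rrms(rec, profiles)}
        planted = dict(zip(truth.features["profile_names"], truth.features["rrm_spans"]))
        good = True
        for name, (ps, pe) in planted.items():
            if name not in hits:
                good = False
                continue
            qs, qe = hits[name]
            inter = max(0, min(pe, qe) - max(ps, qs))
            union = max(pe, qe) - min(ps, qs)
            if inter / union < 0.8:
                good = False
        ok += good
    assert ok >= 0.9 * trials


def test_rnp_mapping_through_gapped_alignment(profiles):
    """A deletion inside RNP1 yields a shortened, flagged span; a deleted RNP2 is absent."""
    prof = profiles[0]
    rec, _ = gen_ptb_protein([prof], n_rrms=1, linker_len_range=(25, 25), mutation_rate=0.0, seed=3)
    start = 25
    # delete two residues inside RNP1
    r1s, r1e = prof.rnp1
    mutated = rec.residues[: start + r1s + 2] + rec.residues[start + r1s + 4:]
    hit = locate_rrms(SeqRecord(id="del", residues=mutated, moltype="protein"), [prof])[0]
    assert hit.rnp1_flagged
    assert hit.rnp1_span is not None
    # delete RNP2 entirely
    r2s, r2e = prof.rnp2
    mutated2 = rec.residues[: start + r2s] + rec.residues[start + r2e:]
    hit2 = locate_rrms(SeqRecord(id="del2", residues=mutated2, moltype="protein"), [prof])[0]
    assert hit2.rnp2_span is None or hit2.rnp2_flagged


def test_detect_rnps_requires_alignment(profiles):
    from ptbscan.rrm_detect import RRMHit

    with pytest.raises(ParameterError):
        detect_rnps(RRMHit("RRM1", (0, 10), 100.0, 1.0), profiles[0])


@pytest.mark.parametrize("n,call", [(4, "PTB1/6-type"), (3, "PTB7-type"), (2, "unclassified"), (0, "unclassified")])
def test_classify_ptb_rule(profiles, n, call):
    hits = []
    if n:
        rec, _ = gen_ptb_protein(profiles, n_rrms=n, mutation_rate=0.0, seed=4)
        hits = locate_rrms(rec, profiles)
        assert len(hits) == n
    else:
        rec = SeqRecord(id="none", residues="".join(np.random.default_rng(0).choice(list(AA), size=200)),
                        moltype="protein")
        hits = locate_rrms(rec, profiles)
        assert hits == []
    assert classify_ptb(rec.id, hits).call == call


def test_classify_two_hits_unclassified(profiles):
    rec, _ = gen_ptb_protein(profiles, n_rrms=2, mutation_rate=0.0, seed=5)
    hits = locate_rrms(rec, profiles)
    assert classify_ptb(rec.id, hits).call == "unclassified"


def test_rrm_count_recovery_rate_at_20pct_mutation(profiles):
    """n_rrms recovered exactly in >=95% of seeds at mutation rate 0.2."""
    trials = 60
    correct = 0
    for seed in range(trials):
        n = 4 if seed % 2 == 0 else 3
        rec, _ = gen_ptb_protein(profiles, n_rrms=n, mutation_rate=0.2, seed=seed)
        if classify_ptb(rec.id, locate_rrms(rec, profiles)).n_rrms == n:
            correct += 1
    assert correct >= 0.95 * trials
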