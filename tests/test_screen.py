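"""Forward + reciprocal screening decision logic."""

import numpy as np
import pytest

from leechmine.records import ArchetypeEntry, ProteinRecord
from leechmine.screen import (
    ScreenDecision,
    classify,
    forward_screen,
    reciprocal_screen,
    screen_proteome,
)
from leechmine.search import LocalHit, smith_waterman
from leechmine.simulate import SimConfig, evolve, plant_genome, simulate_archetype


def _hit(query="q", target="t", evalue=1e-20, bits=80.0, desc=""):
    return LocalHit(
        query_id=query, target_id=target, raw_score=100, bit_score=bits,
        evalue=evalue, query_range=(1, 50), target_range=(1, 50),
        pct_identity=80.0, pct_similarity=90.0, target_coverage=0.9,
        target_description=desc,
    )


def test_forward_screen_finds_planted_copy(scheme, small_bundle):
    fwd = forward_screen(small_bundle.proteome, small_bundle.panel, scheme)
    truth = {r.protein_id: r.family for r in small_bundle.truth}
    for fam, hits in fwd.items():
        assert hits, f"family {fam} found nothing"
        assert truth[hits[0].target_id] == fam  # a planted copy ranks first
        members = {h.target_id for h in hits}
        planted = {pid for pid, f in truth.items() if f == fam}
        assert planted <= members


def test_forward_screen_decoys_only(scheme):
    rng = np.random.default_rng(2)
    decoys = [
        ProteinRecord(id=f"d{k}", sequence="".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120)))
        for k in range(15)
    ]
    arch, _ = simulate_archetype(150, 6, rng, seq_id="arch")
    panel = [ArchetypeEntry(name="famA archetype", family="famA", accession="A1",
                            species="syn", sequence=arch.sequence)]
    fwd = forward_screen(decoys, panel, scheme)
    assert fwd == {"famA": []}


def test_shared_hit_appears_in_both_family_lists(scheme):
    """Before dedup, a protein similar to two families is listed under both."""
    rng = np.random.default_rng(3)
    arch, cys = simulate_archetype(200, 6, rng, seq_id="arch")
    cfg = SimConfig(seed=0, indel_rate=0.0)
    sibling, _ = evolve(arch, 0.15, cfg, rng, cys_positions=cys, child_id="sib")
    shared, _ = evolve(arch, 0.05, cfg, rng, cys_positions=cys, child_id="shared")
    panel = [
        ArchetypeEntry(name="famA archetype", family="famA", accession="A1",
                       species="syn", sequence=arch.sequence),
        ArchetypeEntry(name="famB archetype", family="famB", accession="B1",
                       species="syn", sequence=sibling.sequence),
    ]
    fwd = forward_screen([shared], panel, scheme)
    assert [h.target_id for h in fwd["famA"]] == ["shared"]
    assert [h.target_id for h in fwd["famB"]] == ["shared"]


def test_reciprocal_screen_self_and_none(scheme):
    rng = np.random.default_rng(4)
    arch, _ = simulate_archetype(150, 4, rng, seq_id="cand")
    sp_entry = ProteinRecord(id="sp1", sequence=arch.sequence,
                             description="famA archetype")
    unrelated = ProteinRecord(id="u1", sequence="".join(
        rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=150)), description="actin")
    res = reciprocal_screen(arch, {"swissprot": [sp_entry, unrelated]}, scheme)
    assert res["swissprot"].target_id == "sp1"
    res2 = reciprocal_screen(arch, {"nr": [unrelated]}, scheme)
    assert res2["nr"] is None
    with pytest.raises(ValueError, match="nr"):
        reciprocal_screen(arch, {"nr": []}, scheme)


def test_classify_family_consistent_reciprocal_is_candidate():
    fwd = _hit(target="cand", evalue=2e-68)
    recips = {"nr": _hit(target="nr1", evalue=1e-64, desc="Destabilase I")}
    d = classify(fwd, "destabilase", recips, {"destabilase": ["destabilase"]})
    assert d.status == "candidate"


def test_classify_far_better_unrelated_hit_rejects():
    """A reciprocal hit vastly better than the family hit flags non-orthology."""
    fwd = _hit(target="cand", evalue=3e-8)
    recips = {
        "nr": _hit(target="nr1", evalue=7e-82, bits=280.0, desc="Neurohemerythrin"),
    }
    d = classify(fwd, "lefaxin", recips, {"lefaxin": ["lefaxin"]})
    assert d.status == "rejected_unrelated"
    assert "Neurohemerythrin" in d.rejection_reason
    assert "nr" in d.rejection_reason


def test_classify_uninformative_description_cannot_reject():
    fwd = _hit(target="cand", evalue=1e-10)
    recips = {"nr": _hit(target="nr1", evalue=1e-140, desc="hypothetical protein 7")}
    d = classify(fwd, "apyrase", recips, {"apyrase": ["apyrase"]})
    assert d.status == "candidate"


def test_classify_margin_guards_close_calls():
    """An unrelated hit only slightly better than the family hit is kept."""
    fwd = _hit(target="cand", evalue=1e-20)
    recips = {
        "nr": _hit(target="a", evalue=5e-21, desc="actin"),
        "sp": _hit(target="b", evalue=1e-20, desc="guamerin"),
    }
    d = classify(fwd, "guamerin", recips, {"guamerin": ["guamerin"]})
    assert d.status == "candidate"


def test_classify_monotone_in_family_evalue():
    """Improving the family-consistent reciprocal hit never causes rejection."""
    unrelated = _hit(target="u", evalue=1e-40, desc="tubulin")
    for fam_ev in (1e-20, 1e-35, 1e-40, 1e-60):
        recips = {
            "nr": unrelated,
            "sp": _hit(target="f", evalue=fam_ev, desc="guamerin"),
        }
        d = classify(_hit(target="cand", evalue=1e-15), "guamerin", recips,
                     {"guamerin": ["guamerin"]})
        if fam_ev <= 1e-40:
            assert d.status == "candidate"
    # once rejected at a weak family hit, strengthening it can only rescue
    weak = classify(_hit(target="cand", evalue=1e-15), "guamerin",
                    {"nr": unrelated, "sp": _hit(target="f", evalue=1e-20,
                                                 desc="guamerin")},
                    {"guamerin": ["guamerin"]})
    assert weak.status == "rejected_unrelated"


def test_screen_proteome_on_bundle(scheme, small_bundle):
    fwd, decisions = screen_proteome(
        small_bundle.proteome, small_bundle.panel, small_bundle.global_dbs,
        scheme,
    )
    truth = {r.protein_id: r.family for r in small_bundle.truth}
    for fam, d in decisions.items():
        assert d.status == "candidate"
        assert truth[d.protein_id] == fam
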