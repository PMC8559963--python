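"""Domain calling, the seven-category classification and NB-ARC extraction."""

import numpy as np
import pytest

from nlrkit.classify import (
    DEFAULT_VOCABULARY as V,
    annotate_proteome,
    build_architecture,
    build_domain_calls,
    classify,
    dedupe_sequences,
    detect_nbarc,
    extract_nbarc_fasta,
    merge_category_intervals,
)
from nlrkit.model import DomainCall, MotifHit, ProteinRecord, SignatureHit


def sig(acc, start, end, db="Pfam", seq="P1"):
    return SignatureHit(seq, db, acc, start, end)


def motif(mid, start, end, score=90.0, q=1e-4, ok=True):
    return MotifHit("P1", mid, start, end, score, 1e-9, q, extraction_ok=ok)


# ----------------------------------------------------- interval merging

def test_merge_overlap_and_disjoint():
    hits = [sig("PF00560", 10, 50, "Pfam"), sig("PF00560", 40, 90)]
    calls = merge_category_intervals(hits, V, "LRR")
    assert [(c.start, c.end) for c in calls] == [(10, 90)]
    hits = [sig("PF00560", 10, 50), sig("PF00560", 200, 260)]
    assert len(merge_category_intervals(hits, V, "LRR")) == 2


def test_merge_gap_tolerance_boundary():
    # gap of exactly 20 merges; 21 does not
    calls = merge_category_intervals([sig("PF00560", 10, 50), sig("PF00560", 71, 90)],
                                     V, "LRR", gap=20)
    assert len(calls) == 1
    calls = merge_category_intervals([sig("PF00560", 10, 50), sig("PF00560", 72, 90)],
                                     V, "LRR", gap=20)
    assert len(calls) == 2


def test_merge_matches_union_find_oracle(rng):
    """Brute-force connected components on the overlap-or-gap<=G graph."""
    for trial in range(20):
        n = int(rng.integers(2, 15))
        ivs = []
        for _ in range(n):
            s = int(rng.integers(1, 400))
            ivs.append((s, s + int(rng.integers(0, 80))))
        G = 20
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                gap = max(ivs[i][0], ivs[j][0]) - min(ivs[i][1], ivs[j][1]) - 1
                if gap <= G:
                    adj[i].add(j)
                    adj[j].add(i)
        seen, comps = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k] - comp)
            seen |= comp
            comps.append(comp)
        expected = sorted((min(ivs[k][0] for k in c), max(ivs[k][1] for k in c))
                          for c in comps)
        hits = [sig("PF00560", s, e) for s, e in ivs]
        calls = merge_category_intervals(hits, V, "LRR", gap=G)
        assert [(c.start, c.end) for c in calls] == expected


# ----------------------------------------------------- NB-ARC detection

def test_pfam_nbarc_alone_is_a_region():
    assert detect_nbarc([sig("PF00931", 180, 460)], []) == [(180, 460)]


def test_ploop_plus_motif_is_a_region_extended_to_motif():
    regions = detect_nbarc([sig("SSF52540", 150, 430, "SUPERFAMILY")],
                           [motif(2, 400, 420)])
    assert regions == [(150, 430)]
    # motif hanging over the chain end extends the boundary
    regions = detect_nbarc([sig("SSF52540", 150, 410, "SUPERFAMILY")],
                           [motif(2, 400, 420)])
    assert regions == [(150, 420)]


def test_ploop_without_anchor_or_motif_is_not_a_region():
    assert detect_nbarc([sig("SSF52540", 150, 430, "SUPERFAMILY")], []) == []
    # ineligible motif (strict MHD under 85) does not rescue it
    assert detect_nbarc([sig("SSF52540", 150, 430, "SUPERFAMILY")],
                        [motif(7, 200, 214, score=70.0, ok=False)]) == []


def test_two_disjoint_nbarc_hits_numbered_in_order():
    regions = detect_nbarc([sig("PF00931", 500, 780), sig("PF00931", 100, 380)], [])
    assert regions == [(100, 380), (500, 780)]


def test_detect_nbarc_monotone_under_added_evidence(rng):
    """Adding signatures or motifs never removes a region."""
    base_sigs = [sig("SSF52540", 150, 430, "SUPERFAMILY")]
    base_motifs = [motif(2, 300, 314)]
    regions = detect_nbarc(base_sigs, base_motifs)
    more = detect_nbarc(base_sigs + [sig("PF00931", 160, 420)],
                        base_motifs + [motif(8, 350, 364)])
    for r in regions:
        assert any(m[0] <= r[0] and m[1] >= r[1] for m in more) or r in more


def test_removing_motifs_demotes_motif_supported_nlr():
    sigs = [sig("SSF52540", 150, 430, "SUPERFAMILY"), sig("PF18052", 1, 100)]
    rec = ProteinRecord("P1", "M" * 500)
    with_motif = annotate_proteome([rec], sigs, [motif(2, 300, 314)])
    without = annotate_proteome([rec], sigs, [])
    assert with_motif[0].category == "NLR"
    assert without[0].category == "NLR-degenerate"  # CC + stand-alone P-loop


# ----------------------------------------------------- classification

def run_one(sigs, motifs, length=900):
    rec = ProteinRecord("P1", "M" * length)
    return annotate_proteome([rec], sigs, motifs)[0]


def test_nbarc_presence_gives_nlr():
    res = run_one([sig("PF00931", 180, 460)], [])
    assert res.category == "NLR" and res.rule == "nbarc-signature"


def test_tir_only_is_tx():
    res = run_one([sig("PF01582", 10, 180)], [])
    assert res.category == "TX" and res.architecture.letters == "T"


def test_rpw8_with_standalone_ploop_is_degenerate():
    res = run_one([sig("PF05659", 1, 150), sig("SSF52540", 300, 500, "SUPERFAMILY")], [])
    assert res.category == "NLR-degenerate" and res.rule == "degenerate-ploop"


def test_ploop_overlapping_other_annotation_is_not_degenerate():
    """A kinase/transporter P-loop co-annotated with its own domain must
    not count: the protein falls through to its sensor-only category."""
    res = run_one([sig("PF05659", 1, 150),
                   sig("SSF52540", 300, 500, "SUPERFAMILY"),
                   sig("PF00005", 310, 490)], [])  # ABC transporter domain
    assert res.category == "RPW8"


def test_lrr_with_eligible_mhd_is_degenerate():
    res = run_one([sig("G3DSA:3.80.10.10", 100, 400, "Gene3D")],
                  [motif(7, 200, 214, score=90.0)])
    assert res.category == "NLR-degenerate" and res.rule == "degenerate-motif"


def test_lrr_with_subthreshold_mhd_is_non_nlr():
    res = run_one([sig("G3DSA:3.80.10.10", 100, 400, "Gene3D")],
                  [motif(7, 200, 214, score=70.0, ok=False)])
    assert res.category == "non-NLR"


def test_helo_domain_is_mlkl():
    res = run_one([sig("PF06760", 10, 150)], [])
    assert res.category == "MLKL"


def test_cc_only_is_ccx_and_r1_counts_as_cc_like():
    assert run_one([sig("PF18052", 1, 120)], []).category == "CCX"
    assert run_one([sig("PF12061", 1, 150)], []).category == "CCX"


def test_every_sequence_gets_exactly_one_category(rng):
    from conftest import replicate_pool
    from nlrkit.fixtures import generate_protein
    for i, spec in enumerate(replicate_pool(40)):
        rec, sigs, mots, cjid = generate_protein(spec, f"S{i}", seed=100 + i)
        res = annotate_proteome([rec], sigs, mots, cjid)
        assert len(res) == 1
        assert res[0].category in {"NLR", "NLR-degenerate", "TX", "CCX",
                                   "RPW8", "MLKL", "non-NLR"}


# ----------------------------------------------------- architecture

def arch_of(spec):
    calls = []
    for cat, s, e in spec:
        acc = {"CC": "PF18052", "NBARC": "PF00931", "LRR": "PF00560",
               "TIR": "PF01582", "OTHER": "PS50808"}[cat]
        calls.append(DomainCall("P1", cat, s, e, [sig(acc, s, e)]))
    return build_architecture(calls).letters


def test_architecture_examples():
    assert arch_of([("CC", 1, 120), ("NBARC", 150, 460), ("LRR", 500, 800)]) == "CNL"
    assert arch_of([("TIR", 1, 170), ("NBARC", 200, 500), ("LRR", 520, 600),
                    ("LRR", 640, 720), ("LRR", 760, 900)]) == "TNL"
    assert arch_of([("CC", 1, 120), ("OTHER", 130, 200), ("NBARC", 220, 520),
                    ("LRR", 560, 900)]) == "CONL"


def test_architecture_overlapping_calls_ordered_start_then_longer():
    calls = [
        DomainCall("P1", "LRR", 100, 200, [sig("PF00560", 100, 200)]),
        DomainCall("P1", "CC", 100, 400, [sig("PF18052", 100, 400)]),
    ]
    assert build_architecture(calls).letters == "CL"


# ----------------------------------------------------- extraction / dedup

def test_extract_single_region_keeps_parent_id():
    rec = ProteinRecord("P1", "M" * 900)
    (out,) = extract_nbarc_fasta(rec, [(180, 460)])
    assert out.id == "P1" and len(out) == 281


def test_extract_multiple_regions_numbered():
    rec = ProteinRecord("P1", "M" * 900)
    outs = extract_nbarc_fasta(rec, [(500, 780), (100, 380)])
    assert [o.id for o in outs] == ["P1_1", "P1_2"]
    assert outs[0].sequence == rec.sequence[99:380]


def test_extract_no_regions_and_out_of_bounds():
    rec = ProteinRecord("P1", "M" * 100)
    assert extract_nbarc_fasta(rec, []) == []
    with pytest.raises(ValueError, match="outside"):
        extract_nbarc_fasta(rec, [(50, 200)])


def test_dedupe_exact_strings():
    rs = [ProteinRecord("a", "MKV"), ProteinRecord("b", "MKV"),
          ProteinRecord("c", "MKL")]
    unique, members = dedupe_sequences(rs)
    assert [r.id for r in unique] == ["a", "c"]
    assert members == {"a": ["a", "b"], "c": ["c"]}
    unique2, members2 = dedupe_sequences(unique)
    assert [r.id for r in unique2] == ["a", "c"]
    assert all(len(v) == 1 for v in members2.values())
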