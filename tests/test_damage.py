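"""Damage generation and strand-break classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radfate as rf
from radfate.damage import (
    Chromatin,
    Complexity,
    StrandBreak,
    Strand,
    detect_and_classify,
    generate_damage,
    read_damage_tsv,
    write_damage_tsv,
)


def test_zero_dose_gives_empty_set():
    assert len(generate_damage(0.0, seed=1)) == 0


def test_degenerate_fractions_label_every_record():
    d = generate_damage(2.0, complex_fraction=1.0, hc_fraction=0.0, seed=2)
    assert len(d) > 0
    assert all(r.complexity == Complexity.COMPLEX for r in d.dsbs)
    assert all(r.chromatin == Chromatin.EC for r in d.dsbs)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"dose": -1.0},
        {"dose": 1.0, "complex_fraction": 1.5},
        {"dose": 1.0, "hc_fraction": -0.1},
        {"dose": 1.0, "dsb_yield": -5.0},
    ],
)
def test_domain_errors(kwargs):
    with pytest.raises(ValueError):
        generate_damage(**kwargs)


def test_poisson_mean_of_dsb_count():
    """Monte-Carlo mean DSB count matches the analytic Poisson mean."""
    n_rep, dose, dsb_yield = 2000, 2.0, 40.0
    counts = [len(generate_damage(dose, dsb_yield, seed=s)) for s in range(n_rep)]
    mean_expected = dose * dsb_yield
    tol = 3.0 * np.sqrt(mean_expected / n_rep)  # 3 sigma of the MC mean
    assert abs(np.mean(counts) - mean_expected) < tol


def test_label_fractions_converge():
    d = generate_damage(100.0, complex_fraction=0.3, hc_fraction=0.25, seed=3)
    n = len(d)
    for attr, enum_val, p in [
        ("complexity", Complexity.COMPLEX, 0.3),
        ("chromatin", Chromatin.HC, 0.25),
    ]:
        frac = np.mean([getattr(r, attr) == enum_val for r in d.dsbs])
        assert abs(frac - p) < 3.0 * np.sqrt(p * (1 - p) / n)


def test_coordinates_inside_nucleus():
    d = generate_damage(10.0, nucleus_radius=3000.0, seed=4)
    radii = np.linalg.norm(d.coords(), axis=1)
    assert np.all(radii <= 3000.0)


# --- classification ---------------------------------------------------------

def _sb(pos, strand, chrom=0):
    return StrandBreak(chromosome_id=chrom, position=pos, strand=strand)


def test_opposing_pair_is_simple_dsb():
    recs = detect_and_classify([_sb(100, Strand.FORWARD), _sb(105, Strand.REVERSE)])
    assert len(recs) == 1
    assert recs[0].complexity == Complexity.SIMPLE


def test_extra_nearby_break_makes_complex_dsb():
    recs = detect_and_classify(
        [_sb(100, Strand.FORWARD), _sb(105, Strand.REVERSE), _sb(108, Strand.FORWARD)]
    )
    assert len(recs) == 1
    assert recs[0].complexity == Complexity.COMPLEX


def test_far_breaks_do_not_pair():
    recs = detect_and_classify([_sb(100, Strand.FORWARD), _sb(150, Strand.REVERSE)])
    assert recs == []


def test_window_must_be_positive():
    with pytest.raises(ValueError):
        detect_and_classify([], window_bp=0)


def _oracle_pair_and_classify(breaks, window_bp=10):
    """Independent brute-force pairer applying the same greedy rule."""
    ordered = sorted(breaks, key=lambda b: (b.chromosome_id, b.position, b.strand.value))
    used = set()
    pairs = []
    for i, b in enumerate(ordered):
        if i in used:
            continue
        candidates = [
            (abs(o.position - b.position), j)
            for j, o in enumerate(ordered)
            if j != i and j not in used
            and o.chromosome_id == b.chromosome_id
            and o.strand != b.strand
            and abs(o.position - b.position) <= window_bp
        ]
        if candidates:
            _, j = min(candidates)
            used.update((i, j))
            pairs.append(tuple(sorted((i, j))))
    out = []
    for i, j in pairs:
        mid = (ordered[i].position + ordered[j].position) / 2.0
        extra = any(
            k not in (i, j)
            and ordered[k].chromosome_id == ordered[i].chromosome_id
            and abs(ordered[k].position - mid) <= window_bp
            for k in range(len(ordered))
        )
        out.append((ordered[i].position, ordered[j].position,
                    "complex" if extra else "simple"))
    return sorted(out)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 1), st.integers(0, 60), st.sampled_from(list(Strand))),
        max_size=30,
    )
)
def test_classification_matches_bruteforce_oracle(raw):
    breaks = [_sb(pos, strand, chrom) for chrom, pos, strand in raw]
    got = sorted(
        (min(b.position for b in r.breaks), max(b.position for b in r.breaks),
         r.complexity.value)
        for r in detect_and_classify(breaks)
    )
    want = sorted(
        (min(a, b), max(a, b), c) for a, b, c in _oracle_pair_and_classify(breaks)
    )
    assert got == want


def test_classification_permutation_invariant():
    rng = np.random.default_rng(5)
    breaks = [
        _sb(int(p), Strand.FORWARD if s else Strand.REVERSE)
        for p, s in zip(rng.integers(0, 100, 20), rng.integers(0, 2, 20))
    ]
    ref = [(r.complexity, tuple(b.position for b in r.breaks))
           for r in detect_and_classify(breaks)]
    for _ in range(5):
        rng.shuffle(breaks)
        got = [(r.complexity, tuple(b.position for b in r.breaks))
               for r in detect_and_classify(breaks)]
        assert got == ref


def test_damage_tsv_roundtrip(tmp_path):
    d = generate_damage(1.0, seed=6)
    d = rf.assign_pathways(d, seed=7)
    path = tmp_path / "damage.tsv"
    write_damage_tsv(d, path)
    back = read_damage_tsv(path)
    assert len(back) == len(d)
    assert back.dose == d.dose
    np.testing.assert_allclose(back.coords(), d.coords())
    assert [r.complexity for r in back.dsbs] == [r.complexity for r in d.dsbs]
    assert [r.pathway for r in back.dsbs] == [r.pathway for r in d.dsbs]
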