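"""Filtering cascade: hard filter, intersection, genic filter, adjudication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ocpmd.models import GeneModel
from ocpmd.prioritize import (
    HardFilterThresholds,
    genic_filter,
    hard_filter,
    intersect_homozygous,
    lowcov_adjudicate,
    prioritize,
)
from ocpmd.splice import ConsequenceRecord
from ocpmd.prioritize import SupportVerdict
from ocpmd.variants import Variant


def v(pos, gt=(1, 1), qd=25.0, dp=15, ref="A", alt="T", chrom="1"):
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=gt, qd=qd, dp=dp)


# ---------------------------------------------------------------------------
# hard filter


def test_hard_filter_retains_passing_hom_alt():
    passed, stats = hard_filter([v(1, qd=25, dp=15)])
    assert len(passed) == 1
    assert stats.n_passed == 1


def test_hard_filter_boundary_is_exclusive():
    passed, stats = hard_filter([v(1, qd=20.0, dp=15), v(2, qd=25.0, dp=10)])
    assert passed == []
    assert stats.n_below_threshold == 2


def test_hard_filter_hand_enumerated_ten_records():
    records = [
        v(1, qd=25, dp=15),            # pass
        v(2, qd=30, dp=11),            # pass
        v(3, qd=20, dp=15),            # QD at boundary -> drop
        v(4, qd=25, dp=10),            # DP at boundary -> drop
        v(5, qd=5, dp=50),             # low QD -> drop
        v(6, gt=(0, 1)),               # het -> drop
        v(7, gt=(0, 0)),               # hom ref -> drop
        v(8, qd=None, dp=15),          # missing QD -> tallied drop
        v(9, qd=21.0, dp=11),          # pass
        v(10, qd=100, dp=100),         # pass
    ]
    passed, stats = hard_filter(records)
    assert [x.pos for x in passed] == [1, 2, 9, 10]
    assert stats.n_missing_fields == 1
    assert stats.n_not_hom_alt == 2
    assert stats.n_below_threshold == 3
    assert stats.n_input == 10


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    qds=st.lists(st.floats(0, 60, allow_nan=False), min_size=1, max_size=30),
    bump=st.floats(0, 20, allow_nan=False),
)
def test_hard_filter_monotone_in_thresholds(qds, bump):
    variants = [v(i + 1, qd=q, dp=30) for i, q in enumerate(qds)]
    base, _ = hard_filter(variants, HardFilterThresholds(qd_min=20))
    stricter, _ = hard_filter(variants, HardFilterThresholds(qd_min=20 + bump))
    assert {x.pos for x in stricter} <= {x.pos for x in base}


# ---------------------------------------------------------------------------
# intersection


def test_intersect_idempotent_and_setlike():
    a = [v(1), v(2), v(3)]
    b = [v(2), v(3), v(4)]
    assert [x.pos for x in intersect_homozygous(a, a)] == [1, 2, 3]
    assert intersect_homozygous(a, [v(9)]) == []
    assert [x.pos for x in intersect_homozygous(a, b)] == [2, 3]


def test_intersect_requires_hom_alt_in_both():
    a = [v(1)]
    b = [v(1, gt=(0, 1))]
    assert intersect_homozygous(a, b) == []


# ---------------------------------------------------------------------------
# genic filter

GENE = GeneModel(
    gene_id="G1", chrom="1", strand="+",
    exons=((100, 200), (300, 400)), cds_start=10, cds_end=190,
)


def test_genic_filter_boundaries():
    inside_intron = v(250)  # 0-based 249, inside (200, 300)
    upstream = v(100)  # 0-based 99, one bp before gene start
    first_base = v(101)  # 0-based 100 == gene start
    kept = genic_filter([inside_intron, upstream, first_base], [GENE])
    assert [x.pos for x in kept] == [250, 101]


def test_genic_filter_matches_bruteforce_interval_checks():
    rng = np.random.default_rng(0)
    positions = rng.integers(1, 1000, size=100)
    variants = [v(int(p)) for p in positions]
    kept = genic_filter(variants, [GENE])
    expected = [x for x in variants if GENE.start <= x.pos - 1 < GENE.end]
    assert [x.pos for x in kept] == [x.pos for x in expected]
    # the gene occupies ~30% of the 1-kb contig; sanity-check the scale
    assert 10 <= len(kept) <= 50


# ---------------------------------------------------------------------------
# low-coverage adjudication


def make_pileups(ctrl_depths, aff_depths, ctrl_alt=None, aff_ref=None):
    rows = []
    for i, d in enumerate(ctrl_depths):
        alt = (ctrl_alt or {}).get(i, 0)
        rows.append((f"C{i}", "1", 500, d - alt, alt))
    for i, d in enumerate(aff_depths):
        ref = (aff_ref or {}).get(i, 0)
        rows.append((f"A{i}", "1", 500, ref, d - ref))
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref_reads", "alt_reads"])


CTRLS = [f"C{i}" for i in range(8)]
AFFS = [f"A{i}" for i in range(4)]


def test_supported_when_both_subsets_covered():
    pile = make_pileups([1, 1, 1, 1, 1, 1, 0, 0], [2, 1, 1, 0])
    verdict = lowcov_adjudicate(("1", 500), pile, CTRLS, AFFS)
    assert verdict.verdict == "supported"
    assert verdict.n_controls_covered == 6
    assert verdict.n_extra_affected_covered == 3


def test_control_alt_read_refutes():
    pile = make_pileups([3, 1, 1, 1, 1, 1, 1, 1], [2, 1, 1, 1], ctrl_alt={0: 3})
    verdict = lowcov_adjudicate(("1", 500), pile, CTRLS, AFFS)
    assert verdict.verdict == "refuted_control_alt"


def test_affected_ref_read_refutes():
    pile = make_pileups([1] * 8, [5, 1, 1, 1], aff_ref={0: 1})
    verdict = lowcov_adjudicate(("1", 500), pile, CTRLS, AFFS)
    assert verdict.verdict == "refuted_affected_ref"


def test_insufficient_coverage_below_75_percent():
    pile = make_pileups([1, 1, 1, 1, 1, 0, 0, 0], [1, 1, 1, 1])  # 5/8 < 6
    verdict = lowcov_adjudicate(("1", 500), pile, CTRLS, AFFS)
    assert verdict.verdict == "insufficient_coverage"


def test_refutation_takes_precedence_over_coverage():
    pile = make_pileups([2, 0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 0], ctrl_alt={0: 2})
    verdict = lowcov_adjudicate(("1", 500), pile, CTRLS, AFFS)
    assert verdict.verdict == "refuted_control_alt"


def test_empty_subset_raises():
    pile = make_pileups([1] * 8, [1] * 4)
    with pytest.raises(ValueError, match="non-empty"):
        lowcov_adjudicate(("1", 500), pile, [], AFFS)


# ---------------------------------------------------------------------------
# ranking


def _annot(variant, term):
    cons = ConsequenceRecord(variant=variant, term=term, gene_id="G1")
    verdict = SupportVerdict(variant.chrom, variant.pos, "supported", 8, 4)
    return (variant, cons, verdict)


def test_splice_candidate_ranks_first():
    donor = _annot(v(500, ref="AG", alt="A"), "splice_donor_variant")
    noise = [_annot(v(p), "intron_variant") for p in (100, 200, 300, 400, 600)]
    table = prioritize(noise + [donor])
    assert table.iloc[0]["pos"] == 500
    assert table.iloc[0]["rank"] == 1


def test_ties_broken_by_position():
    a = _annot(v(900), "stop_gained")
    b = _annot(v(100), "frameshift_variant")
    table = prioritize([a, b])
    assert list(table["pos"]) == [100, 900]


def test_unsupported_candidates_dropped():
    donor = _annot(v(500, ref="AG", alt="A"), "splice_donor_variant")
    refuted = (
        v(100),
        ConsequenceRecord(variant=v(100), term="stop_gained", gene_id="G1"),
        SupportVerdict("1", 100, "refuted_control_alt", 8, 4),
    )
    table = prioritize([donor, refuted])
    assert len(table) == 1
    assert table.iloc[0]["pos"] == 500
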