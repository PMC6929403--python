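"""Competition-sample counting, PMI scores and erfc significance."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cernet.candidates import CandidateNetwork
from cernet.matrix import BinaryExpressionMatrix
from cernet.scoring import (
    ScoredCrosstalk,
    SupportTable,
    compute_support_table,
    group_summaries,
    is_competition_sample,
    network_probabilities,
    pmi,
    score_network,
    select_significant,
    significance,
    support_count,
)
from _oracles import brute_score_network, brute_support, random_binary_instance


def _binary(rows):
    """rows: dict rna -> list of 0/1; samples named s0, s1, ..."""
    df = pd.DataFrame(rows).T.astype("int8")
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return BinaryExpressionMatrix(values=df)


def _net(lnc_ids, mr_ids, mirna="mir"):
    return CandidateNetwork(
        mirna=mirna, lnc_ids=tuple(lnc_ids), mr_ids=tuple(mr_ids), mode="negative"
    )


# ---------------------------------------------------------------------------
# Competition samples and supports
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pattern", list(itertools.product([0, 1], repeat=3)),
    ids=lambda p: "".join(map(str, p)),
)
def test_competition_sample_truth_table(pattern):
    I = _binary({"lnc": [pattern[0]], "mir": [pattern[1]], "mr": [pattern[2]]})
    expected = pattern in ((0, 1, 0), (1, 0, 1))
    assert is_competition_sample(I, "lnc", "mir", "mr", "s0") is expected


def test_support_upper_bound_and_constant_columns():
    I = _binary({"lnc": [0, 0, 0], "mir": [1, 1, 1], "mr": [0, 0, 0]})
    assert support_count(I, "lnc", "mir", "mr") == 3
    I2 = _binary({"lnc": [1, 1], "mir": [1, 1], "mr": [0, 1]})
    assert support_count(I2, "lnc", "mir", "mr") == 0


def test_support_conditions_mutually_exclusive(rng):
    for _ in range(50):
        lnc_ids, mirna, mr_ids, samples, rows = random_binary_instance(rng)
        I = _binary({r: [rows[r][s] for s in samples] for r in rows})
        for l in lnc_ids:
            for m in mr_ids:
                c1 = sum(
                    (rows[l][s], rows[mirna][s], rows[m][s]) == (0, 1, 0)
                    for s in samples
                )
                c2 = sum(
                    (rows[l][s], rows[mirna][s], rows[m][s]) == (1, 0, 1)
                    for s in samples
                )
                assert support_count(I, l, mirna, m, samples) == c1 + c2


def test_support_empty_sample_set_errors():
    I = _binary({"lnc": [0], "mir": [1], "mr": [0]})
    with pytest.raises(ValueError, match="empty sample set"):
        support_count(I, "lnc", "mir", "mr", [])


# ---------------------------------------------------------------------------
# Probabilities
# ---------------------------------------------------------------------------

def test_probabilities_single_pair_normalize_to_one():
    p_joint, p_lnc, p_mr = network_probabilities(np.array([[4]]))
    assert p_joint[0, 0] == p_lnc[0] == p_mr[0] == 1.0


def test_probabilities_2x2_diagonal_hand_values():
    p_joint, p_lnc, p_mr = network_probabilities(np.array([[4, 0], [0, 4]]))
    assert p_joint[0, 0] == pytest.approx(0.5)
    assert p_lnc[0] == pytest.approx(0.5)
    assert p_mr[0] == pytest.approx(0.5)


def test_probabilities_marginal_consistency(rng):
    for _ in range(30):
        supp = rng.integers(0, 9, size=(int(rng.integers(1, 4)), int(rng.integers(1, 4))))
        if supp.sum() == 0:
            continue
        p_joint, p_lnc, p_mr = network_probabilities(supp)
        assert abs(p_joint.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(p_lnc, p_joint.sum(axis=1), atol=1e-12)
        np.testing.assert_allclose(p_mr, p_joint.sum(axis=0), atol=1e-12)


def test_probabilities_zero_total_errors():
    with pytest.raises(ValueError, match="no competition samples"):
        network_probabilities(np.zeros((2, 2), dtype=int))


# ---------------------------------------------------------------------------
# PMI
# ---------------------------------------------------------------------------

def test_pmi_closed_forms():
    assert pmi(0.5, 0.5, 0.5) == pytest.approx(math.log(2.0))
    assert pmi(0.5, 0.5, 0.5, log_base="2") == pytest.approx(1.0)
    assert pmi(1.0, 1.0, 1.0) == 0.0
    assert pmi(0.25, 0.5, 0.5) == pytest.approx(0.0)  # independence
    assert math.isnan(pmi(0.0, 0.5, 0.5))  # flagged-undefined


def test_score_network_2x2_diagonal_fixture():
    I = _binary(
        {
            "lncA": [1, 1, 0, 0, 1, 1, 0, 0],
            "lncB": [0, 0, 1, 1, 0, 0, 1, 1],
            "mir": [0, 0, 0, 0, 1, 1, 1, 1],
            "mrA": [1, 1, 0, 0, 1, 1, 0, 0],
            "mrB": [0, 0, 1, 1, 0, 0, 1, 1],
        }
    )
    scored = score_network(_net(["lncA", "lncB"], ["mrA", "mrB"]), I)
    by_pair = {(s.lnc, s.mr): s for s in scored}
    assert by_pair[("lncA", "mrA")].supp == 4
    assert by_pair[("lncA", "mrA")].pmi == pytest.approx(math.log(2.0))
    assert by_pair[("lncB", "mrB")].pmi == pytest.approx(math.log(2.0))
    assert not by_pair[("lncA", "mrB")].defined
    assert not by_pair[("lncB", "mrA")].defined


def test_score_network_single_pair_pmi_zero():
    I = _binary({"lnc": [0, 1, 0], "mir": [1, 0, 1], "mr": [0, 1, 0]})
    [s] = score_network(_net(["lnc"], ["mr"]), I)
    assert s.pmi == 0.0 and s.supp == 3


def test_score_network_matches_brute_force(rng):
    for _ in range(100):
        lnc_ids, mirna, mr_ids, samples, rows = random_binary_instance(rng)
        I = _binary({r: [rows[r][s] for s in samples] for r in rows})
        try:
            expected = brute_score_network(rows, lnc_ids, mirna, mr_ids, samples)
        except ValueError:
            with pytest.raises(ValueError):
                score_network(_net(lnc_ids, mr_ids, mirna), I)
            continue
        scored = score_network(_net(lnc_ids, mr_ids, mirna), I)
        for s in scored:
            supp, p_joint, p_lnc, p_mr, score = expected[(s.lnc, s.mr)]
            assert s.supp == supp
            assert s.p_joint == pytest.approx(p_joint, abs=1e-12)
            if score is None:
                assert not s.defined
            else:
                assert s.pmi == pytest.approx(score, abs=1e-12)


def test_pmi_upper_bound_and_permutation_invariance(rng):
    for _ in range(30):
        lnc_ids, mirna, mr_ids, samples, rows = random_binary_instance(rng)
        I = _binary({r: [rows[r][s] for s in samples] for r in rows})
        try:
            scored = score_network(_net(lnc_ids, mr_ids, mirna), I)
        except ValueError:
            continue
        for s in scored:
            if s.defined:
                assert s.pmi <= min(-math.log(s.p_lnc), -math.log(s.p_mr)) + 1e-12
        perm = rng.permutation(I.values.columns.to_numpy())
        I_perm = BinaryExpressionMatrix(values=I.values[list(perm)])
        scored_perm = score_network(_net(lnc_ids, mr_ids, mirna), I_perm)
        for a, b in zip(scored, scored_perm):
            assert a.supp == b.supp
            assert (a.pmi == pytest.approx(b.pmi)) or (not a.defined and not b.defined)


# ---------------------------------------------------------------------------
# Significance and selection
# ---------------------------------------------------------------------------

def _scored(pmis, mirna="mir"):
    return [
        ScoredCrosstalk(
            lnc=f"lnc{i}", mirna=mirna, mr=f"mr{i}", supp=1,
            p_joint=0.1, p_lnc=0.3, p_mr=0.3, pmi=v,
        )
        for i, v in enumerate(pmis)
    ]


def test_erfc_identities():
    out = significance(_scored([1.0, 1.0, 2.0, 3.0]))
    # the score equal to the group mean has theta ~ 0 in a symmetric set
    scores = np.array([1.0, 1.0, 2.0, 3.0])
    sigma = scores.std()
    for s, v in zip(out, scores):
        theta = (v - scores.mean()) / sigma
        assert s.theta == pytest.approx(theta)
        assert s.p_value == pytest.approx(
            min(1.0, math.erfc(theta / math.sqrt(2.0))), abs=1e-12
        )


def test_p_at_theta_1_96_is_five_percent():
    assert math.erfc(1.96 / math.sqrt(2.0)) == pytest.approx(0.05, abs=5e-4)
    assert math.erfc(0.0) == 1.0


def test_p_ordering_reverses_pmi_ordering(rng):
    pmis = rng.gamma(2.0, 1.0, size=20) + 0.01
    out = significance(_scored(list(pmis)))
    # erfc is decreasing: sorted by descending PMI, p-values never decrease
    # (below-mean scores tie at the p = 1 clamp)
    ranked = sorted(out, key=lambda s: -s.pmi)
    for a, b in zip(ranked, ranked[1:]):
        assert a.p_value <= b.p_value + 1e-15
    above_mean = [s for s in ranked if s.theta > 0]
    ps = [s.p_value for s in above_mean]
    assert ps == sorted(ps)  # strict regime: exact reverse ordering


def test_nonpositive_and_undefined_scores_discarded():
    scored = _scored([0.5, 0.0, -0.3, float("nan"), 0.7])
    out = significance(scored)
    assert not math.isnan(out[0].p_value) and not math.isnan(out[4].p_value)
    for i in (1, 2, 3):
        assert math.isnan(out[i].p_value)


def test_zero_sigma_group_gets_p_one_with_warning():
    with pytest.warns(UserWarning, match="zero variance"):
        out = significance(_scored([0.4, 0.4, 0.4]))
    assert all(s.p_value == 1.0 for s in out)


def test_group_without_positive_scores_dropped_with_warning():
    with pytest.warns(UserWarning, match="no positive"):
        out = significance(_scored([-0.1, 0.0]))
    assert all(math.isnan(s.p_value) for s in out)


def test_per_mirna_vs_global_grouping():
    scored = _scored([0.1, 0.2, 0.3], mirna="mirA") + _scored([1.0, 2.0, 3.0], mirna="mirB")
    per = significance(scored, grouping="per_mirna")
    glob = significance(scored, grouping="global")
    # within-group standardization differs from pooled standardization
    assert per[0].theta != pytest.approx(glob[0].theta)
    summaries = {s.group: s for s in group_summaries(scored, "per_mirna")}
    assert summaries["mirA"].t == 3
    assert summaries["mirA"].mean_pmi == pytest.approx(0.2)


def test_selection_strict_boundary():
    scored = _scored([1.0, 2.0])
    scored[0].p_value, scored[1].p_value = 0.05, 0.049
    assert [s.p_value for s in select_significant(scored)] == [0.049]
    assert select_significant(scored, alpha=0.0) == []


def test_selection_monotone_in_alpha(rng):
    for _ in range(20):
        out = significance(_scored(list(rng.gamma(1.0, 1.0, size=15) + 0.01)))
        n_prev = None
        for alpha in (0.2, 0.1, 0.05, 0.01):
            n = len(select_significant(out, alpha=alpha))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


def test_selection_sorted_by_descending_pmi(rng):
    out = significance(_scored(list(rng.gamma(2.0, 1.0, size=30) + 0.01)))
    sel = select_significant(out, alpha=0.5)
    pmis = [s.pmi for s in sel]
    assert pmis == sorted(pmis, reverse=True)
    assert all(s.selected for s in sel)
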