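"""QC cascade: per-stage contracts and truth-conditional behaviour."""

import numpy as np
import pandas as pd
import pytest

from mthet import qc
from mthet.reference import HomopolymerMask
from tests.conftest import toy_calls, toy_samples


def test_sample_coverage_strict_boundary():
    s = toy_samples(["a", "b", "c"])
    s["covered_fraction"] = [0.96, 0.95, 0.80]
    kept = qc.filter_samples(s)
    assert list(kept["sample_id"]) == ["a"]
    empty = qc.filter_samples(s.iloc[0:0])
    assert empty.empty


@pytest.mark.parametrize("depth,fwd,rev,hf,kept", [
    (1000, 15, 15, 0.20, True),
    (1000, 30, 0, 0.20, False),   # all alt reads on one strand
    (1000, 0, 30, 0.20, False),
    (499, 15, 15, 0.20, False),   # depth boundary
    (500, 15, 15, 0.20, True),
    (1000, 12, 12, 0.20, False),  # < 25 alt reads
    (1000, 13, 12, 0.20, True),
    (1000, 15, 15, 0.049, False),
    (1000, 25, 25, 0.05, True),
])
def test_basic_call_filter(depth, fwd, rev, hf, kept):
    calls = pd.DataFrame([{"sample_id": "s", "pos": 100, "ref": "A", "alt": "G",
                           "hf": hf, "depth": depth, "alt_fwd": fwd,
                           "alt_rev": rev}])
    out = qc.basic_call_filter(calls)
    assert (len(out) == 1) is kept


def test_homopolymer_filter():
    mask = HomopolymerMask(frozenset({303, 304, 305}), 5)
    calls = toy_calls([("s", 303, "C", "T", 0.2), ("s", 306, "C", "T", 0.2)])
    out = qc.homopolymer_site_filter(calls, mask)
    assert list(out["pos"]) == [306]
    empty_mask = HomopolymerMask(frozenset(), 5)
    pd.testing.assert_frame_equal(qc.homopolymer_site_filter(calls, empty_mask),
                                  calls)


def _prevalence_fixture():
    rows = []
    for i in range(100):  # group A: 3 heteroplasmic carriers at pos 500 (3%)
        rows.append((f"A{i}", 1000 + i, "A", "G", 0.99))
    for i in range(3):
        rows.append((f"A{i}", 500, "C", "T", 0.30))
    for i in range(100):  # group B: 2 carriers at pos 500 (2%)
        rows.append((f"B{i}", 2000 + i, "A", "G", 0.99))
    for i in range(2):
        rows.append((f"B{i}", 500, "C", "T", 0.30))
    rows.append(("A5", 500, "C", "T", 0.99))  # homoplasmic at the same site
    calls = toy_calls(rows)
    samples = pd.concat([
        toy_samples([f"A{i}" for i in range(100)], group="HTN"),
        toy_samples([f"B{i}" for i in range(100)], group="control"),
    ], ignore_index=True)
    return calls, samples


def test_prevalence_filter_group_local():
    calls, samples = _prevalence_fixture()
    out = qc.cohort_prevalence_filter(calls, samples, 0.02, scope="group")
    at_site = out[out["pos"] == 500]
    # removed only the heteroplasmic calls of the offending group (A, 3%)
    assert set(at_site["sample_id"]) == {"B0", "B1", "A5"}
    assert (at_site.loc[at_site["sample_id"] == "A5", "hf"] > 0.95).all()


def test_prevalence_filter_cohort_scope():
    calls, samples = _prevalence_fixture()
    out = qc.cohort_prevalence_filter(calls, samples, 0.02, scope="cohort")
    at_site = out[out["pos"] == 500]
    # 5/200 = 2.5% pooled: heteroplasmic calls removed everywhere
    assert set(at_site["sample_id"]) == {"A5"}
    with pytest.raises(ValueError):
        qc.cohort_prevalence_filter(calls, samples, 0.02, scope="banana")


def test_panel_concordance_examples():
    samples = toy_samples([f"s{i}" for i in range(100)])
    rows = [(f"s{i}", 100, "A", "G", 0.99) for i in range(95)]   # cohort AF .95
    rows += [(f"s{i}", 200, "C", "T", 0.99) for i in range(50)]  # cohort AF .50
    calls = toy_calls(rows)
    panel = pd.DataFrame({"pos": [100, 200], "ref": ["A", "C"],
                          "alt": ["G", "T"], "af": [0.01, 0.40]})
    out = qc.panel_concordance_filter(calls, samples, [panel])
    assert 100 not in set(out["pos"])     # diff 0.94 > 0.9
    assert (out["pos"] == 200).sum() == 50
    # allele absent from the panel counts as AF 0
    out2 = qc.panel_concordance_filter(calls, samples,
                                       [panel[panel["pos"] == 200]])
    assert 100 not in set(out2["pos"])


def test_cv_filter_exact_quartile():
    rows = []
    for j in range(100):  # 100 sites, 4 carriers each, distinct CVs
        spread = 0.001 + 0.0015 * j
        for k in range(4):
            rows.append((f"s{k}", 1000 + j, "A", "G", 0.4 + spread * (k - 1.5)))
    calls = toy_calls(rows)
    out, stats = qc.cv_site_filter(calls, percentile=25, min_carriers=3)
    assert stats["cv"].notna().sum() == 100
    removed = 100 - out["pos"].nunique()
    assert removed == 25
    # the removed quartile is the lowest-CV (most NUMT-like) one
    kept_cv = stats[stats["pos"].isin(out["pos"])]["cv"]
    gone_cv = stats[~stats["pos"].isin(out["pos"])]["cv"]
    assert gone_cv.max() <= kept_cv.min()


def test_cv_filter_constant_hf_site_removed():
    rows = [(f"s{k}", 500, "C", "T", 0.30) for k in range(10)]
    rows += [(f"s{k}", 1000 + j, "A", "G", 0.3 + 0.02 * j * (-1) ** k)
             for j in range(6) for k in range(4)]
    out, stats = qc.cv_site_filter(toy_calls(rows), percentile=25)
    assert 500 not in set(out["pos"])
    assert stats.loc[stats["pos"] == 500, "cv"].iloc[0] == 0.0


def test_cv_filter_single_carrier_sites_protected():
    rows = [(f"s{k}", 100 + k, "A", "G", 0.2) for k in range(10)]  # singletons
    with pytest.warns(UserWarning):
        out, stats = qc.cv_site_filter(toy_calls(rows))
    pd.testing.assert_frame_equal(out, toy_calls(rows))
    assert stats["cv"].isna().all()


def test_cascade_all_pass_fixture(ann):
    # a homoplasmy outside the mask: passes every stage (panel stage absent)
    pos = next(p for p in range(4000, 5000) if p not in ann.mask.positions)
    ref = ann.genome.base(pos)
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
    calls = toy_calls([("s1", pos, ref, alt, 0.99)])
    samples = toy_samples(["s1", "s2"])
    report = qc.apply_qc_cascade(calls, samples, ann.mask)
    assert all(s.n_removed == 0 for s in report.stages)
    assert len(report.calls) == 1


def test_cascade_is_idempotent(default_cohort, default_qc, ann):
    second = qc.apply_qc_cascade(default_qc.calls, default_qc.samples, ann.mask,
                                 [default_cohort.panel_genbank,
                                  default_cohort.panel_kg])
    assert all(s.n_removed == 0 for s in second.stages)
    pd.testing.assert_frame_equal(
        second.calls.reset_index(drop=True),
        default_qc.calls.reset_index(drop=True))


def test_filters_never_add_calls(default_cohort, ann):
    c = default_cohort.calls
    s = default_cohort.samples
    stages = [
        qc.basic_call_filter(c),
        qc.homopolymer_site_filter(c, ann.mask),
        qc.cohort_prevalence_filter(c, s),
        qc.panel_concordance_filter(c, s, [default_cohort.panel_genbank]),
    ]
    for out in stages:
        assert len(out) <= len(c)
        assert out.index.isin(c.index).all()


def test_basic_and_homopolymer_filters_commute(default_cohort, ann):
    c = default_cohort.calls
    ab = qc.homopolymer_site_filter(qc.basic_call_filter(c), ann.mask)
    ba = qc.basic_call_filter(qc.homopolymer_site_filter(c, ann.mask))
    pd.testing.assert_frame_equal(ab, ba)


def test_cascade_removes_artifacts(default_cohort, default_qc):
    truth = default_cohort.truth
    surviving = default_qc.calls.merge(truth, on=["sample_id", "pos", "ref", "alt"])
    n_art = (truth["label"] == "artifact").sum()
    n_left = (surviving["label"] == "artifact").sum()
    assert n_art > 0
    assert n_left / n_art <= 0.05


def test_cv_filter_targets_numt_sites(default_cohort, ann):
    cfg = qc.QCConfig(enable_cv_filter=True)
    report = qc.apply_qc_cascade(default_cohort.calls, default_cohort.samples,
                                 ann.mask,
                                 [default_cohort.panel_genbank,
                                  default_cohort.panel_kg], cfg)
    stats = report.site_stats
    numt_sites = set(zip(default_cohort.numt_site_table["pos"],
                         default_cohort.numt_site_table["alt"]))
    elig = stats[stats["cv"].notna()]
    cut = np.percentile(elig["cv"], cfg.cv_percentile)
    removed = set(zip(elig.loc[elig["cv"] <= cut, "pos"],
                      elig.loc[elig["cv"] <= cut, "alt"]))
    present = set(zip(elig["pos"], elig["alt"])) & numt_sites
    assert present, "NUMT sites should reach the CV stage"
    frac = np.mean([s in removed for s in present])
    assert frac >= 0.8
    # removal set enriched for NUMT sites (odds ratio > 1)
    kept = set(zip(elig["pos"], elig["alt"])) - removed
    a = len(removed & numt_sites)
    b = len(removed) - a
    c_ = len(kept & numt_sites)
    d = len(kept) - c_
    odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c_ + 0.5))
    assert odds > 1
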