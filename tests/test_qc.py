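"""Tests for the staged filtering cascade."""

import numpy as np
import pandas as pd
import pytest

from panelpipe import stats as ms
from panelpipe.dataset import FormatError
from panelpipe.qc import (
    BasicMarkerFilter,
    ExactDuplicateFilter,
    HWEPopulationFilter,
    LowDepthCallSilencer,
    MendelianCallSilencer,
    MendelianErrorFilter,
    QCConfig,
    QCPipeline,
    TagRedundancyClusterer,
    run_qc,
    sequence_identity,
)
from panelpipe.simulate import SimConfig, simulate_dataset


# -------------------------------------------------------- low-depth silencing ----
def test_silence_low_depth_boundary(make_dataset):
    # counts (2,2) sum 4 < 5 -> silenced; (3,2) sum 5 -> retained
    calls = np.array([[1, 1, 0]])
    ref = np.array([[2, 3, 10]])
    alt = np.array([[2, 2, 0]])
    ds = make_dataset(calls, ref_counts=ref, alt_counts=alt)
    stage = LowDepthCallSilencer(min_call_depth=5).fit(ds)
    out = stage.transform(ds)
    assert stage.n_silenced_ == 1
    assert out.calls.tolist() == [[-1, 1, 0]]
    assert out.silenced["reason"].tolist() == ["low_depth"]
    # counts are retained after silencing
    assert out.ref_counts.tolist() == ref.tolist()


def test_silence_low_depth_noop_when_all_deep(make_dataset):
    ds = make_dataset(
        np.array([[0, 1]]), ref_counts=np.array([[9, 5]]), alt_counts=np.array([[0, 5]])
    )
    out, n = __import__("panelpipe.qc", fromlist=["silence_low_depth"]).silence_low_depth(ds)
    assert n == 0
    np.testing.assert_array_equal(out.calls, ds.calls)


def test_silence_requires_counts(make_dataset):
    ds = make_dataset(np.array([[0, 1]]))
    with pytest.raises(FormatError):
        LowDepthCallSilencer().fit(ds)


# ----------------------------------------------------------------- basic filter ----
def test_basic_filter_thresholds(make_dataset):
    n = 50
    rng = np.random.default_rng(0)
    low_maf = np.zeros(n, dtype=np.int8)
    low_maf[0] = 1  # MAF 0.01 < 0.02 -> removed
    half_cr = np.where(np.arange(n) < 25, rng.choice([0, 1, 2], size=n), -1)  # CR == 0.5
    good = rng.choice([0, 1], size=n, p=[0.6, 0.4])  # common marker, full CR
    ds = make_dataset(np.vstack([low_maf, half_cr, good]).astype(np.int8))
    stage = BasicMarkerFilter().fit(ds)
    assert stage.removal_reason_[0] == "maf"
    assert stage.removal_reason_[1] == "call_rate"  # CR exactly 0.5 is removed
    assert stage.keep_mask_[2]
    assert stage.removed_by_["maf"] == 1 and stage.removed_by_["call_rate"] == 1


def test_basic_filter_repeatability_and_all_missing(make_dataset):
    calls = np.array([[1, 0, 1, 0], [-1, -1, -1, -1]], dtype=np.int8)
    reps = {"S1": "g", "S2": "g", "S3": "h", "S4": "h"}
    # marker 0: both pairs discordant -> repeatability 0 < 0.9
    ds = make_dataset(calls, replicate_groups=reps)
    stage = BasicMarkerFilter().fit(ds)
    assert stage.removal_reason_[0] == "repeatability"
    assert stage.removal_reason_[1] == "maf"  # all-missing fails the MAF criterion


# ----------------------------------------------------------------- exact dedup ----
def test_dedup_keeps_highest_maf_per_clone(make_dataset):
    tag = "A" * 30
    calls = np.array(
        [
            [0, 1, 1, 2],  # MAF 0.5 -> winner
            [0, 0, 0, 1],  # same clone, MAF 0.125
            [0, 1, 0, 0],  # unique clone
        ],
        dtype=np.int8,
    )
    ds = make_dataset(
        calls, tags=[tag, tag, "C" * 30], clone_ids=["T1", "T1", "T2"], snp_positions=[3, 7, 0]
    )
    stage = ExactDuplicateFilter().fit(ds)
    assert stage.keep_mask_.tolist() == [True, False, True]


def test_dedup_unique_tags_remove_nothing(make_dataset):
    ds = make_dataset(np.zeros((4, 3), dtype=np.int8))
    stage = ExactDuplicateFilter().fit(ds)
    assert stage.n_removed_ == 0


def test_dedup_maf_tie_broken_by_call_rate(make_dataset):
    tag = "G" * 30
    calls = np.array([[0, 1, 1, 0], [0, 1, -1, -1]], dtype=np.int8)  # same MAF 0.25
    ds = make_dataset(calls, tags=[tag, tag], clone_ids=["T", "T"], snp_positions=[1, 2])
    stage = ExactDuplicateFilter().fit(ds)
    assert stage.keep_mask_.tolist() == [True, False]  # CR 0.75 beats 0.5


# ------------------------------------------------------------------- clustering ----
def _mutate(seq, k):
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(seq)
    for i in range(k):
        out[i * 7] = swap[out[i * 7]]
    return "".join(out)


def test_sequence_identity_thresholds():
    base = ("ACGT" * 18)[:69]
    assert sequence_identity(base, _mutate(base, 3)) == pytest.approx(66 / 69)
    assert sequence_identity(base, _mutate(base, 4)) == pytest.approx(65 / 69)
    assert 66 / 69 >= 0.95 > 65 / 69


def test_cluster_tags_95_identity(make_dataset):
    base = ("ACGT" * 18)[:69]
    near = _mutate(base, 3)  # 3 mismatches -> within 95 %
    far = _mutate(base, 4)  # 4 mismatches -> outside
    calls = np.array([[1, 1, 0, 0], [0, 1, 0, 0], [0, 1, 1, 0]], dtype=np.int8)
    ds = make_dataset(calls, tags=[base, near, far], clone_ids=["A", "B", "C"])
    stage = TagRedundancyClusterer(0.95).fit(ds)
    assert stage.n_clusters_ == 2
    assert stage.keep_mask_.tolist() == [True, False, True]


def test_cluster_all_identical_leaves_one(make_dataset):
    tag = ("ACGT" * 18)[:69]
    ds = make_dataset(
        np.zeros((5, 3), dtype=np.int8), tags=[tag] * 5, clone_ids=[f"T{i}" for i in range(5)]
    )
    stage = TagRedundancyClusterer().fit(ds)
    assert stage.keep_mask_.sum() == 1


# ------------------------------------------------------------------ HWE filter ----
def _two_pop_dataset(make_dataset, marker_rows, n_per_pop=40):
    samples = [f"A{i}" for i in range(n_per_pop)] + [f"B{i}" for i in range(n_per_pop)]
    pops = {s: ("EC" if s.startswith("A") else "NT") for s in samples}
    return make_dataset(np.array(marker_rows, dtype=np.int8), samples=samples, populations=pops)


def test_hwe_filter_requires_deviation_in_all_populations(make_dataset):
    n = 40
    all_het = [1] * n  # grossly out of HWE (p tiny)
    hwe_ok = ([0] * 10 + [1] * 20 + [2] * 10)  # exact HWE at p = 0.5
    ds = _two_pop_dataset(
        make_dataset,
        [all_het + all_het, all_het + hwe_ok, hwe_ok + hwe_ok],
        n_per_pop=n,
    )
    stage = HWEPopulationFilter(hwe_alpha=1e-4).fit(ds)
    assert stage.keep_mask_.tolist() == [False, True, True]
    any_pop = HWEPopulationFilter(hwe_alpha=1e-4, require_all_pops=False).fit(ds)
    assert any_pop.keep_mask_.tolist() == [False, False, True]


def test_hwe_filter_without_populations_raises(make_dataset):
    ds = make_dataset(np.array([[0, 1]]))
    with pytest.raises(FormatError):
        HWEPopulationFilter().fit(ds)


# ------------------------------------------------------------------- MI filter ----
def _trio_dataset(make_dataset, n_trios, n_errors, marker_extra=()):
    """One marker with exactly n_errors erroneous trios out of n_trios."""
    samples, trios, calls = [], [], []
    row = []
    for t in range(n_trios):
        s, d, p = f"s{t}", f"d{t}", f"p{t}"
        samples += [s, d, p]
        trios.append((p, s, d))
        if t < n_errors:
            row += [0, 0, 1]  # impossible
        else:
            row += [0, 0, 0]
    calls.append(row)
    for extra in marker_extra:
        calls.append(list(extra))
    return make_dataset(np.array(calls, dtype=np.int8), samples=samples, trios=trios)


def test_mi_filter_boundary_is_strict(make_dataset):
    removed = MendelianErrorFilter(0.09).fit(_trio_dataset(make_dataset, 100, 10))
    assert removed.keep_mask_.tolist() == [False]  # 10 % > 9 %
    kept = MendelianErrorFilter(0.09).fit(_trio_dataset(make_dataset, 100, 9))
    assert kept.keep_mask_.tolist() == [True]  # exactly 9 % retained


def test_mi_filter_uninformative_marker_retained(make_dataset):
    ds = make_dataset(
        np.array([[-1, 0, 0]]), samples=["s", "d", "p"], trios=[("p", "s", "d")]
    )
    stage = MendelianErrorFilter().fit(ds)
    assert stage.keep_mask_.tolist() == [True]


# ---------------------------------------------------------------- MI silencing ----
def test_silence_mi_calls_targets_progeny_only(make_dataset):
    ds = _trio_dataset(make_dataset, 20, 1)
    stage = MendelianCallSilencer().fit(ds)
    out = stage.transform(ds)
    assert stage.n_silenced_ == 1
    assert out.calls[0, 2] == -1  # the progeny call
    assert out.calls[0, 0] == 0 and out.calls[0, 1] == 0  # parents untouched
    rate, _ = ms.mi_scan(out)
    assert rate[0] == 0.0  # fixed point: rescanning finds nothing


def test_silence_mi_calls_without_trios(make_dataset):
    ds = make_dataset(np.array([[0, 1]]))
    stage = MendelianCallSilencer().fit(ds)
    assert stage.n_silenced_ == 0


# -------------------------------------------------------------------- pipeline ----
def test_run_qc_empty_dataset(make_dataset):
    ds = make_dataset(np.zeros((0, 3), dtype=np.int8))
    filtered, report = run_qc(ds)
    assert filtered.n_markers == 0
    assert (report["snps_removed"] == 0).all()
    assert (report["calls_silenced"] == 0).all()


def test_run_qc_conservation_and_determinism():
    cfg = SimConfig(
        n_markers=600,
        n_pop_A=30,
        n_pop_B=30,
        families=[("S1", "D1", 8), ("S2", "D2", 8)],
        n_trio_records=12,
        seed=9,
    )
    ds, _ = simulate_dataset(cfg)
    pipe = QCPipeline()
    filtered = pipe.fit_transform(ds)
    report = pipe.report_
    # conservation at every stage
    assert (report["snps_in"] - report["snps_removed"] == report["snps_out"]).all()
    for prev, nxt in zip(report.index[:-1], report.index[1:]):
        assert report.loc[prev, "snps_out"] == report.loc[nxt, "snps_in"]
    assert report["snps_out"].iloc[-1] == filtered.n_markers
    # determinism: same config, same counts
    ds2, _ = simulate_dataset(cfg)
    pipe2 = QCPipeline()
    pipe2.fit_transform(ds2)
    pd.testing.assert_frame_equal(report, pipe2.report_)


def test_run_qc_monotone_silencing():
    cfg = SimConfig(n_markers=300, n_pop_A=25, n_pop_B=25, families=[("S1", "D1", 10)],
                    n_trio_records=10, seed=4)
    ds, _ = simulate_dataset(cfg)
    pipe = QCPipeline()
    filtered = pipe.fit_transform(ds)
    # the set of missing calls only grows: every surviving marker/sample call
    # that was missing in the input is still missing in the output
    idx = [i for i, m in enumerate(ds.marker_ids) if m in set(filtered.marker_ids)]
    before = ds.calls[idx]
    assert ((before == -1) <= (filtered.calls == -1)).all()


def test_run_qc_idempotent_without_mi_errors():
    # with no read errors there are no MI errors (so the final silencing
    # stage is inert) and with no technical replicates the replicate
    # collapsing cannot re-pick representatives, so the cascade is a
    # strict fixed point
    cfg = SimConfig(
        n_markers=500,
        n_pop_A=40,
        n_pop_B=40,
        families=[("S1", "D1", 10), ("S2", "D2", 10)],
        n_trio_records=20,
        allele_error_rate=0.0,
        replicate_fraction=0.0,
        seed=2,
    )
    ds, _ = simulate_dataset(cfg)
    first = QCPipeline()
    filtered = first.fit_transform(ds)
    assert first.report_["snps_removed"].sum() > 0  # the run did real work
    second = QCPipeline()
    second.fit_transform(filtered)
    assert second.report_["snps_removed"].sum() == 0
    assert second.report_["calls_silenced"].sum() == 0


def test_threshold_monotonicity():
    cfg = SimConfig(n_markers=400, n_pop_A=30, n_pop_B=30, families=[],
                    n_trio_records=0, seed=6)
    ds, _ = simulate_dataset(cfg)
    retained = []
    for min_maf in (0.02, 0.05, 0.10):
        filtered, _ = run_qc(ds, QCConfig(min_maf=min_maf))
        retained.append(filtered.n_markers)
    assert retained[0] >= retained[1] >= retained[2]


def test_qc_config_validation():
    with pytest.raises(ValueError):
        QCConfig(min_maf=1.5)
    with pytest.raises(ValueError):
        QCConfig(hwe_alpha=0.0)
    with pytest.raises(ValueError):
        QCConfig(max_avg_depth=-5)
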