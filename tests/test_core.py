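"""Call-table I/O, QC boundaries, haplotype collapsing, duplicate-run
resolution, arm exclusions, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cstelo import core
from cstelo.arms import ANALYSIS_ARMS


# ---- I/O -------------------------------------------------------------------

def test_roundtrip_identity(toy_calls, tmp_path):
    p = tmp_path / "calls.tsv"
    core.save_calls(toy_calls, p)
    back = core.load_calls(p)
    pd.testing.assert_frame_equal(
        back[list(core.CALL_COLUMNS)], toy_calls[list(core.CALL_COLUMNS)]
    )


def test_empty_file_with_header(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("\t".join(core.CALL_COLUMNS) + "\n")
    assert core.load_calls(p).empty


def test_missing_column_named(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("sample_id\tarm\ttl_p75\n" "s1\t7q\t4000\n")
    with pytest.raises(core.CallFormatError, match="tvr_len"):
        core.load_calls(p)


def test_negative_read_count_rejected_with_line_number(toy_calls, tmp_path):
    bad = toy_calls.copy()
    bad.loc[2, "n_supporting_reads"] = -1
    p = tmp_path / "neg.tsv"
    core.save_calls(bad, p)
    with pytest.raises(core.CallFormatError, match="line.*4"):
        core.load_calls(p)
    with pytest.warns(UserWarning, match="line"):
        loose = core.load_calls(p, strict=False)
    assert len(loose) == len(bad) - 1


# ---- QC --------------------------------------------------------------------

def test_qc_boundaries(toy_calls):
    out = core.qc_filter(toy_calls)
    # tl 99 dropped, 100 kept ("shorter than 100 bp"); tvr -1 dropped;
    # ambiguous dropped
    assert 99.0 not in out["tl_p75"].values
    assert 100.0 in out["tl_p75"].values
    assert (out["tvr_len"] >= 0).all()
    assert not out["mapping_ambiguous"].any()
    assert len(out) == 5


def test_qc_idempotent(toy_calls):
    once = core.qc_filter(toy_calls)
    twice = core.qc_filter(once)
    pd.testing.assert_frame_equal(once, twice)


# ---- collapsing ------------------------------------------------------------

def test_two_alleles_averaged_single_kept(toy_calls):
    tab = core.collapse_to_arm(core.qc_filter(toy_calls))
    s1 = tab[tab.sample_id == "s1"].set_index("arm")["cstl_bp"]
    assert s1["7q"] == pytest.approx(5000.0)       # mean of 4000, 6000
    s2 = tab[tab.sample_id == "s2"].set_index("arm")["cstl_bp"]
    assert s2["7q"] == pytest.approx(3200.0)       # single estimate used as-is


def test_p75_linear_interpolation_oracle():
    reads = pd.DataFrame({
        "sample_id": ["s"] * 4, "arm": ["7q"] * 4, "allele": [0] * 4,
        "read_tl_bp": [1000.0, 2000.0, 3000.0, 4000.0],
    })
    tab = core.collapse_to_arm(reads, min_reads=4)
    # type-7: 75th pct of {1,2,3,4} kb = 3.25 kb
    assert tab["cstl_bp"].iloc[0] == pytest.approx(3250.0)
    assert tab["cstl_bp"].iloc[0] == pytest.approx(
        float(np.percentile(reads.read_tl_bp, 75)))


@given(st.lists(st.floats(100, 20000), min_size=1, max_size=12),
       st.integers(0, 2**31 - 1))
def test_p75_matches_numpy_oracle(values, seed):
    reads = pd.DataFrame({
        "sample_id": "s", "arm": "1p", "allele": 0,
        "read_tl_bp": np.asarray(values, dtype=float),
    })
    out = core.group_p75(reads)
    assert out["tl_p75"].iloc[0] == pytest.approx(
        float(np.percentile(values, 75)), rel=1e-12)


def test_min_reads_threshold_drops_cluster():
    reads = pd.DataFrame({
        "sample_id": ["s"] * 5, "arm": ["7q"] * 3 + ["3p"] * 2,
        "allele": [0] * 3 + [0] * 2,
        "read_tl_bp": [3000.0] * 5,
    })
    tab = core.collapse_to_arm(reads, min_reads=3)
    assert set(tab["arm"]) == {"7q"}   # 3p cluster has only 2 reads


def test_filter_then_collapse_commutes(toy_calls):
    a = core.collapse_to_arm(core.qc_filter(toy_calls))
    b = core.collapse_to_arm(core.qc_filter(core.qc_filter(toy_calls)))
    pd.testing.assert_frame_equal(a, b)


# ---- duplicates ------------------------------------------------------------

def _dup_meta(platforms, n_arms):
    calls = pd.concat([
        pd.DataFrame({
            "sample_id": sid, "arm": ANALYSIS_ARMS[:k], "allele_index": 0,
            "tl_p75": 4000.0, "tvr_len": 100.0, "n_supporting_reads": 4,
            "mapping_ambiguous": False,
        })
        for sid, k in n_arms.items()
    ])
    meta = pd.DataFrame({
        "sample_id": list(platforms), "individual_id": "P1",
        "platform": list(platforms.values()),
    })
    return calls, meta


def test_pacbio_preferred_over_ont():
    calls, meta = _dup_meta({"a": "Sequel IIe", "b": "ONT"},
                            {"a": 10, "b": 20})
    out = core.resolve_duplicate_samples(calls, meta)
    assert set(out["sample_id"]) == {"a"}


def test_more_arms_wins_within_pacbio():
    calls, meta = _dup_meta({"a": "Revio", "b": "Sequel IIe"},
                            {"a": 30, "b": 35})
    out = core.resolve_duplicate_samples(calls, meta)
    assert set(out["sample_id"]) == {"b"}


def test_no_duplicates_identity(toy_calls):
    meta = pd.DataFrame({"sample_id": ["s1", "s2"],
                         "individual_id": ["P1", "P2"],
                         "platform": ["Revio", "ONT"]})
    out = core.resolve_duplicate_samples(toy_calls, meta)
    pd.testing.assert_frame_equal(out, toy_calls)


def test_three_runs_is_error(toy_calls):
    meta = pd.DataFrame({"sample_id": ["s1", "s2", "s3"],
                         "individual_id": "P1",
                         "platform": ["Revio", "ONT", "Sequel IIe"]})
    with pytest.raises(ValueError, match="P1"):
        core.resolve_duplicate_samples(toy_calls, meta)


# ---- exclusions and summaries ---------------------------------------------

@pytest.fixture()
def full_arm_sample():
    from cstelo.arms import ARM_LABELS
    return pd.DataFrame({"sample_id": "s1", "arm": list(ARM_LABELS),
                         "cstl_bp": 4000.0})


def test_exclusion_modes(full_arm_sample):
    assert len(core.exclude_arms(full_arm_sample, "acrocentric_p")) == 43
    analysis = core.exclude_arms(full_arm_sample, "analysis")
    assert len(analysis) == 39
    assert set(analysis["arm"]) == set(ANALYSIS_ARMS)
    with pytest.raises(ValueError, match="mode"):
        core.exclude_arms(full_arm_sample, "everything")


def test_sample_losing_all_arms_reported():
    tab = pd.DataFrame({"sample_id": ["s1", "s2"], "arm": ["14p", "7q"],
                        "cstl_bp": [4000.0, 5000.0]})
    with pytest.warns(UserWarning, match="1 sample"):
        out = core.exclude_arms(tab, "analysis")
    assert out.attrs["dropped_samples"] == ["s1"]
    assert set(out["sample_id"]) == {"s2"}


def test_sample_summaries_mean_and_min():
    tab = pd.DataFrame({"sample_id": "s1", "arm": ["1p", "2p", "3p"],
                        "cstl_bp": [2000.0, 4000.0, 6000.0],
                        "n_supporting_reads": [3, 4, 5]})
    s = core.sample_summaries(tab).iloc[0]
    assert s["mean_tl"] == pytest.approx(4000.0)
    assert s["shortest_tl"] == pytest.approx(2000.0)
    assert s["n_arms_with_estimate"] == 3
    assert s["telomeric_coverage"] == 12


def test_coverage_correlates_with_arm_count(small_cohort, small_reads):
    tab = core.collapse_to_arm(
        small_reads, metadata=small_cohort.individuals,
        min_reads=small_cohort.config.min_reads_per_cluster)
    summ = core.sample_summaries(tab, reads=small_reads)
    from scipy.stats import spearmanr
    rho, _ = spearmanr(summ["telomeric_coverage"], summ["n_arms_with_estimate"])
    assert rho > 0


def test_arm_call_rate_bounds_and_order_invariance(full_arm_sample):
    other = pd.DataFrame({"sample_id": "s2", "arm": ["17q"], "cstl_bp": 1.0})
    tab = pd.concat([full_arm_sample, other])
    rates = core.arm_call_rate(tab)
    assert rates.loc["17q", "all"] == 1.0
    assert rates.loc["Yp", "all"] == 0.5
    shuffled = core.arm_call_rate(tab.sample(frac=1, random_state=0))
    pd.testing.assert_frame_equal(rates, shuffled)
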