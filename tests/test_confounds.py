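"""Confound parsing, expansion arithmetic, sample masks and the registry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fcbench
from fcbench import confounds as capi
from fcbench.errors import (
    FilePairingError,
    InputError,
    MissingConfoundError,
    RegistryError,
    StrategyMismatchError,
)

from conftest import complete_confounds_frame, write_confounds_fixture


# ---------------------------------------------------------------------------
# parsing and pairing
# ---------------------------------------------------------------------------


def test_read_pair_row_count(complete_table_path):
    table, sidecar = capi.read_confounds_pair(complete_table_path)
    assert table.n_volumes == 20
    assert len(sidecar.compcor_components) == 8


def test_missing_sibling_names_expected_path(tmp_path):
    img = tmp_path / "sub-02_task-rest_desc-preproc_bold.nii.gz"
    with pytest.raises(FilePairingError, match="desc-confounds_timeseries"):
        capi.read_confounds_pair(img)


def test_unaccepted_suffix_rejected(tmp_path):
    with pytest.raises(InputError, match="suffix"):
        capi.read_confounds_pair(tmp_path / "sub-01_bold.nii.gz")


def test_na_token_parsed_at_volume_zero_only(tmp_path):
    frame = pd.DataFrame(
        {
            **{c: [0.0, 1.0, 3.0] for c in capi.MOTION_BASE},
            "trans_x_derivative1": [np.nan, 1.0, 2.0],
        }
    )
    img = write_confounds_fixture(tmp_path, frame)
    table, _ = capi.read_confounds_pair(img)
    col = table.frame["trans_x_derivative1"]
    assert np.isnan(col.iloc[0]) and np.isfinite(col.iloc[1:]).all()


def test_derivative_nan_beyond_volume_zero_rejected(tmp_path):
    frame = pd.DataFrame(
        {
            **{c: [0.0, 1.0, 3.0] for c in capi.MOTION_BASE},
            "trans_x_derivative1": [np.nan, np.nan, 2.0],
        }
    )
    img = write_confounds_fixture(tmp_path, frame)
    with pytest.raises(InputError, match="volume 0"):
        capi.read_confounds_pair(img)


def test_round_trip_preserves_values_and_missing(tmp_path,
                                                 complete_table_path):
    table, _ = capi.read_confounds_pair(complete_table_path)
    out = tmp_path / "copy" / "sub-01" / "func"
    out.mkdir(parents=True)
    tsv = out / "sub-01_task-rest_desc-confounds_timeseries.tsv"
    capi.write_confounds_table(table, tsv)
    again, _ = capi.read_confounds_pair(
        out / "sub-01_task-rest_desc-preproc_bold.nii.gz"
    )
    pd.testing.assert_frame_equal(table.frame, again.frame)


# ---------------------------------------------------------------------------
# expansion arithmetic: (k, 2k, 2k, 4k) columns for k base columns
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "option,expected", [("basic", 6), ("derivatives", 12), ("power2", 12),
                        ("full", 24)]
)
def test_motion_expansion_counts(complete_table_path, option, expected):
    table, _ = capi.read_confounds_pair(complete_table_path)
    sel = capi.expand_motion(table, option)
    assert sel.n_regressors == expected == sel.counts["motion"]


@pytest.mark.parametrize(
    "category,option,expected",
    [
        ("wm_csf", "basic", 2),
        ("wm_csf", "full", 8),
        ("wm_csf", "derivatives", 4),
        ("global_signal", "basic", 1),
        ("global_signal", "full", 4),
    ],
)
def test_tissue_expansion_counts(complete_table_path, category, option,
                                 expected):
    table, _ = capi.read_confounds_pair(complete_table_path)
    sel = capi.select_tissue(table, category, option)
    assert sel.n_regressors == expected


def test_basic_motion_is_identity_selection(complete_table_path):
    table, _ = capi.read_confounds_pair(complete_table_path)
    sel = capi.expand_motion(table, "basic")
    assert sel.names == list(capi.MOTION_BASE)
    np.testing.assert_array_equal(
        sel.matrix, table.frame[list(capi.MOTION_BASE)].to_numpy()
    )


def test_derivative_finite_difference_oracle(tmp_path):
    frame = pd.DataFrame(
        {
            "trans_x": [0.0, 1.0, 3.0], "trans_y": [0.0] * 3,
            "trans_z": [0.0] * 3, "rot_x": [0.0] * 3, "rot_y": [0.0] * 3,
            "rot_z": [0.0] * 3,
        }
    )
    for c in list(frame.columns):
        frame[f"{c}_derivative1"] = np.concatenate(
            [[np.nan], np.diff(frame[c])])
    img = write_confounds_fixture(tmp_path, frame)
    table, _ = capi.read_confounds_pair(img)
    sel = capi.expand_motion(table, "derivatives")
    got = sel.matrix[:, sel.names.index("trans_x_derivative1")]
    np.testing.assert_allclose(got, [0.0, 1.0, 2.0])  # imputed at volume 0


def test_missing_expansion_columns_listed(tmp_path):
    frame = pd.DataFrame({c: np.zeros(3) for c in capi.MOTION_BASE})
    img = write_confounds_fixture(tmp_path, frame)
    table, _ = capi.read_confounds_pair(img)
    with pytest.raises(MissingConfoundError, match="trans_x_derivative1"):
        capi.expand_motion(table, "full")


# ---------------------------------------------------------------------------
# CompCor / AROMA / cosine / non-steady-state
# ---------------------------------------------------------------------------


def test_compcor_fifty_percent_prefix(complete_table_path):
    # ladder (0.20, 0.35, 0.48, 0.51, ...) crosses 0.50 at the 4th entry
    table, sidecar = capi.read_confounds_pair(complete_table_path)
    sel = capi.select_compcor(table, sidecar, n="all")
    assert sel.n_regressors == 4
    assert sel.names == [f"a_comp_cor_{k:02d}" for k in range(4)]


def test_compcor_fixed_count(complete_table_path):
    table, sidecar = capi.read_confounds_pair(complete_table_path)
    assert capi.select_compcor(table, sidecar, n=6).n_regressors == 6


def test_compcor_too_few_components(tmp_path):
    frame, sidecar = complete_confounds_frame(n_compcor=4)
    img = write_confounds_fixture(tmp_path, frame, sidecar)
    table, meta = capi.read_confounds_pair(img)
    with pytest.raises(MissingConfoundError, match="4"):
        capi.select_compcor(table, meta, n=6)


def test_compcor_requires_combined_mask(tmp_path):
    frame, _ = complete_confounds_frame()
    sidecar = {"a_comp_cor_00": {"Mask": "CSF",
                                 "CumulativeVarianceExplained": 0.6}}
    img = write_confounds_fixture(tmp_path, frame, sidecar)
    table, meta = capi.read_confounds_pair(img)
    with pytest.raises(MissingConfoundError, match="combined"):
        capi.select_compcor(table, meta)


def test_aroma_nonaggressive_zero_columns(complete_table_path):
    table, _ = capi.read_confounds_pair(complete_table_path)
    sel = capi.select_aroma(table, image_variant="smoothAROMAnonaggr")
    assert sel.n_regressors == 0 and sel.requires_aroma_image


def test_aroma_on_preproc_image_mismatch(complete_table_path):
    table, _ = capi.read_confounds_pair(complete_table_path)
    with pytest.raises(StrategyMismatchError):
        capi.select_aroma(table, image_variant="preproc")


def test_aroma_aggressive_needs_columns(tmp_path):
    frame = pd.DataFrame({c: np.zeros(3) for c in capi.MOTION_BASE})
    img = write_confounds_fixture(tmp_path, frame)
    table, _ = capi.read_confounds_pair(img)
    with pytest.raises(MissingConfoundError, match="aroma_motion"):
        capi.select_aroma(table, "smoothAROMAnonaggr", mode="aggressive")


def test_cosine_selection_count(complete_table_path):
    table, _ = capi.read_confounds_pair(complete_table_path)
    sel = capi.select_high_pass(table)
    assert sel.names == [f"cosine{k:02d}" for k in range(4)]


def test_high_pass_demanded_but_absent(tmp_path):
    frame = pd.DataFrame({c: np.zeros(3) for c in capi.MOTION_BASE})
    img = write_confounds_fixture(tmp_path, frame)
    table, _ = capi.read_confounds_pair(img)
    with pytest.raises(MissingConfoundError, match="cosine"):
        capi.select_high_pass(table)


def test_non_steady_state_selection(tmp_path):
    frame, sidecar = complete_confounds_frame(n_nonsteady=2)
    img = write_confounds_fixture(tmp_path, frame, sidecar)
    table, _ = capi.read_confounds_pair(img)
    sel = capi.select_non_steady_state(table)
    assert sel.n_regressors == 2
    flagged = [np.flatnonzero(sel.matrix[:, k]) for k in range(2)]
    assert all(f.size == 1 for f in flagged)
    assert flagged[0][0] != flagged[1][0]  # one-hot rows mutually distinct


def test_non_steady_state_absent_gives_empty(complete_table_path):
    table, _ = capi.read_confounds_pair(complete_table_path)
    assert capi.select_non_steady_state(table).n_regressors == 0


# ---------------------------------------------------------------------------
# sample mask
# ---------------------------------------------------------------------------


def _table_with_fd(fd, dvars=None, n_nonsteady=0):
    n = len(fd)
    cols = {
        "framewise_displacement": np.asarray(fd, dtype=float),
        "std_dvars": np.ones(n) if dvars is None else np.asarray(dvars),
    }
    for k in range(n_nonsteady):
        onehot = np.zeros(n)
        onehot[k] = 1
        cols[f"non_steady_state_outlier{k:02d}"] = onehot
    return capi.ConfoundTable(pd.DataFrame(cols))


def brute_force_mask(fd, dvars, fd_thr, dvars_thr, min_segment):
    """Independent oracle: threshold pass then run-length filter."""
    n = len(fd)
    keep = []
    for t in range(n):
        bad = (np.isfinite(fd[t]) and fd[t] > fd_thr) or (
            np.isfinite(dvars[t]) and dvars[t] > dvars_thr)
        keep.append(not bad)
    kept = []
    t = 0
    while t < n:
        if not keep[t]:
            t += 1
            continue
        run = [t]
        while t + 1 < n and keep[t + 1]:
            t += 1
            run.append(t)
        if len(run) >= min_segment:
            kept.extend(run)
        t += 1
    return np.array(kept, dtype=int)


def test_mask_keeps_all_below_threshold():
    table = _table_with_fd([0.1] * 20)
    mask = capi.build_sample_mask(table, 0.5, 3.0, 5)
    np.testing.assert_array_equal(mask.kept, np.arange(20))
    assert mask.censored_count == 0


def test_mask_short_leading_run_censored():
    fd = [0.1, 0.6, 0.1, 0.1, 0.1, 0.1, 0.1]
    mask = capi.build_sample_mask(_table_with_fd(fd), 0.5, 3.0, 5)
    np.testing.assert_array_equal(mask.kept, [2, 3, 4, 5, 6])


def test_mask_matches_brute_force_on_random_traces():
    rng = np.random.default_rng(42)
    for _ in range(20):
        fd = rng.uniform(0, 0.5, 100)
        fd[0] = np.nan
        dvars = rng.uniform(0.5, 4.0, 100)
        table = _table_with_fd(fd, dvars)
        mask = capi.build_sample_mask(table, 0.2, 3.0, 5)
        oracle = brute_force_mask(fd, dvars, 0.2, 3.0, 5)
        np.testing.assert_array_equal(mask.kept, oracle)


def test_mask_exhaustive_over_short_binary_traces():
    # every below/above pattern up to length 12 agrees with the oracle
    for n in range(1, 13):
        for bits in range(2 ** n):
            fd = np.array(
                [0.5 if (bits >> t) & 1 else 0.1 for t in range(n)]
            )
            table = _table_with_fd(fd)
            mask = capi.build_sample_mask(table, 0.2, 3.0, 3)
            oracle = brute_force_mask(fd, np.ones(n), 0.2, 3.0, 3)
            np.testing.assert_array_equal(mask.kept, oracle)


def test_mask_censors_non_steady_state_volumes():
    table = _table_with_fd([0.1] * 20, n_nonsteady=2)
    mask = capi.build_sample_mask(table, 0.5, 3.0, 5)
    assert 0 not in mask.kept and 1 not in mask.kept


def test_missing_fd_column_raises():
    table = capi.ConfoundTable(pd.DataFrame({"std_dvars": np.ones(5)}))
    with pytest.raises(MissingConfoundError):
        capi.build_sample_mask(table, 0.5, 3.0, 5)


@settings(max_examples=50, derandomize=True)
@given(
    fd=st.lists(st.floats(0.0, 1.0), min_size=5, max_size=40),
    thr=st.floats(0.05, 0.9),
    delta=st.floats(0.01, 0.5),
)
def test_lowering_threshold_never_enlarges_kept_set(fd, thr, delta):
    fd = np.asarray(fd)
    strict = capi.build_sample_mask(_table_with_fd(fd), thr, 3.0, 3)
    liberal = capi.build_sample_mask(_table_with_fd(fd), thr + delta, 3.0, 3)
    assert set(strict.kept) <= set(liberal.kept)


# ---------------------------------------------------------------------------
# assembled loaders
# ---------------------------------------------------------------------------


def test_load_confounds_category_composition(complete_table_path):
    sel, mask = capi.load_confounds(
        complete_table_path, ["high_pass", "motion", "wm_csf"],
        motion="basic", wm_csf="basic",
    )
    assert sel.n_regressors == 6 + 2 + 4
    assert mask.censored_count == 0


def test_load_confounds_empty_strategy(complete_table_path):
    sel, mask = capi.load_confounds(complete_table_path, [])
    assert sel.n_regressors == 0
    np.testing.assert_array_equal(mask.kept, np.arange(20))


def test_load_confounds_unknown_category(complete_table_path):
    with pytest.raises(InputError, match="unknown"):
        capi.load_confounds(complete_table_path, ["wavelet"])


def test_load_confounds_error_names_category(tmp_path):
    frame = pd.DataFrame({c: np.zeros(6) for c in capi.MOTION_BASE})
    img = write_confounds_fixture(tmp_path, frame)
    with pytest.raises(MissingConfoundError, match=r"\[wm_csf\]"):
        capi.load_confounds(img, ["motion", "wm_csf"], motion="basic")


def test_load_confounds_scrub_composition(tmp_path):
    fd = np.array([0.1, 0.6, 0.1, 0.1, 0.1, 0.1, 0.1])
    frame = pd.DataFrame(
        {
            **{c: np.arange(7, dtype=float) for c in capi.MOTION_BASE},
            "framewise_displacement": fd,
            "std_dvars": np.ones(7),
        }
    )
    img = write_confounds_fixture(tmp_path, frame)
    sel, mask = capi.load_confounds(
        img, ["motion", "scrub"], motion="basic",
        scrub=5, fd_threshold=0.5, std_dvars_threshold=3.0, demean=False,
    )
    np.testing.assert_array_equal(mask.kept, [2, 3, 4, 5, 6])
    # the selection still spans all volumes; downstream cleaning subsets it
    assert sel.matrix.shape == (7, 6)


def test_demean_over_retained_volumes_only(tmp_path):
    fd = np.array([0.1, 0.6, 0.1, 0.1, 0.1, 0.1, 0.1])
    frame = pd.DataFrame(
        {
            **{c: np.arange(7, dtype=float) for c in capi.MOTION_BASE},
            "framewise_displacement": fd,
            "std_dvars": np.ones(7),
        }
    )
    img = write_confounds_fixture(tmp_path, frame)
    sel, mask = capi.load_confounds(
        img, ["motion", "scrub"], motion="basic",
        scrub=5, fd_threshold=0.5, std_dvars_threshold=3.0, demean=True,
    )
    np.testing.assert_allclose(sel.matrix[mask.kept].mean(axis=0), 0,
                               atol=1e-12)


def test_list_input_returns_per_path_results(complete_table_path):
    results = capi.load_confounds(
        [complete_table_path, complete_table_path], ["motion"],
        motion="basic",
    )
    assert len(results) == 2
    np.testing.assert_array_equal(results[0][0].matrix,
                                  results[1][0].matrix)


# ---------------------------------------------------------------------------
# registry and strategy bundles
# ---------------------------------------------------------------------------


def test_registry_has_ten_benchmark_strategies():
    assert set(capi.BENCHMARK_STRATEGIES) == {
        "baseline", "simple", "simple+gsr", "scrubbing.5",
        "scrubbing.5+gsr", "scrubbing.2", "scrubbing.2+gsr", "compcor",
        "compcor6", "aroma",
    }


def test_registry_parameters_cell_for_cell():
    reg = capi.BENCHMARK_STRATEGIES
    assert reg["baseline"].motion is None and reg["baseline"].high_pass
    assert reg["simple"].motion == "full" and reg["simple"].wm_csf == "basic"
    assert reg["simple+gsr"].global_signal == "basic"
    for name, thr in [("scrubbing.5", 0.5), ("scrubbing.2", 0.2)]:
        assert reg[name].scrub == 5 and reg[name].fd_threshold == thr
        assert reg[name].wm_csf == "full"
        assert reg[name].std_dvars_threshold == 3.0
    assert reg["compcor"].n_compcor == "all"
    assert reg["compcor6"].n_compcor == 6
    assert reg["aroma"].image_variant == "smoothAROMAnonaggr"
    assert reg["aroma"].motion is None and reg["aroma"].wm_csf == "basic"
    assert all(s.demean and s.high_pass for s in reg.values())


def test_unknown_strategy_lists_valid_names():
    with pytest.raises(RegistryError, match="scrubbing.2"):
        capi.get_strategy("nonsense")


def test_strategy_equivalent_to_explicit_bundle(complete_table_path):
    sel_a, mask_a = capi.load_confounds_strategy(complete_table_path,
                                                 "simple")
    sel_b, mask_b = capi.load_confounds(
        complete_table_path, ["high_pass", "motion", "wm_csf"],
        motion="full", wm_csf="basic",
    )
    assert sel_a.names == sel_b.names
    np.testing.assert_array_equal(sel_a.matrix, sel_b.matrix)
    np.testing.assert_array_equal(mask_a.kept, mask_b.kept)


def test_baseline_selects_cosines_only(complete_table_path):
    sel, _ = capi.load_confounds_strategy(complete_table_path, "baseline")
    assert sel.names == [f"cosine{k:02d}" for k in range(4)]


def test_simple_counts_match_expected(complete_table_path):
    sel, _ = capi.load_confounds_strategy(complete_table_path, "simple")
    assert sel.counts["motion"] + sel.counts["tissue"] == 26
    sel2, _ = capi.load_confounds_strategy(complete_table_path,
                                           "simple+gsr")
    assert (sel2.counts["motion"] + sel2.counts["tissue"]
            + sel2.counts["global"]) == 27


def test_aggressive_scrub_mask_nested_in_liberal(small_tree):
    root, config, _ = small_tree
    img = root / "sub-01" / "func" / \
        "sub-01_task-rest_desc-preproc_bold.nii.gz"
    _, mask2 = capi.load_confounds_strategy(img, "scrubbing.2")
    _, mask5 = capi.load_confounds_strategy(img, "scrubbing.5")
    assert set(mask2.kept) <= set(mask5.kept)


def test_aroma_strategy_requires_matching_image(small_tree):
    root, _, _ = small_tree
    func = root / "sub-01" / "func"
    with pytest.raises(StrategyMismatchError):
        capi.load_confounds_strategy(
            func / "sub-01_task-rest_desc-preproc_bold.nii.gz", "aroma")
    with pytest.raises(StrategyMismatchError):
        capi.load_confounds_strategy(
            func / "sub-01_task-rest_desc-smoothAROMAnonaggr_bold.nii.gz",
            "simple")


# ---------------------------------------------------------------------------
# independent cross-check against the established implementation
# ---------------------------------------------------------------------------


def test_selection_matches_nilearn(small_tree):
    nilearn = pytest.importorskip("nilearn")
    from nilearn.interfaces.fmriprep import load_confounds as nl_load

    root, _, _ = small_tree
    img = str(root / "sub-01" / "func" /
              "sub-01_task-rest_desc-preproc_bold.nii.gz")
    ours, mask = capi.load_confounds(
        img, ["high_pass", "motion", "wm_csf"], motion="full",
        wm_csf="basic", demean=False,
    )
    theirs, _ = nl_load(
        img, strategy=["high_pass", "motion", "wm_csf"], motion="full",
        wm_csf="basic", demean=False,
    )
    assert sorted(ours.names) == sorted(theirs.columns)
    a = theirs[ours.names].to_numpy()
    # volume-0 derivative imputation differs by design; compare from row 1
    np.testing.assert_allclose(a[1:], ours.matrix[1:], atol=1e-8)


def test_scrub_mask_matches_nilearn(small_tree):
    nilearn = pytest.importorskip("nilearn")
    from nilearn.interfaces.fmriprep import load_confounds as nl_load

    root, config, _ = small_tree
    for i in (1, 2, 3):
        img = str(root / f"sub-0{i}" / "func" /
                  f"sub-0{i}_task-rest_desc-preproc_bold.nii.gz")
        _, ours = capi.load_confounds(
            img, ["motion", "scrub"], motion="basic", scrub=5,
            fd_threshold=0.2, std_dvars_threshold=3.0,
        )
        _, theirs = nl_load(
            img, strategy=["motion", "scrub"], motion="basic", scrub=5,
            fd_threshold=0.2, std_dvars_threshold=3.0,
        )
        expect = np.arange(config.n_volumes) if theirs is None else theirs
        np.testing.assert_array_equal(ours.kept, expect)
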