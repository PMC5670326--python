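"""MSAP loading, locus classification, state calling and Shannon diversity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiterroir import msap
from epiterroir.msap import (
    FULL_OR_MUTATION, HEMIMETHYLATED, INTERNAL_CG, MSL, NML, STATE_TABLE,
    UNINFORMATIVE, UNMETHYLATED, AlignmentError, EpilocusDataset,
)


def _write_dataset(tmp_path, hpa, msp, meta=None):
    samples = list(hpa.index)
    if meta is None:
        meta = pd.DataFrame(
            {
                "vineyard": ["V1"] * len(samples),
                "subregion": ["R1"] * len(samples),
                "clone": ["c"] * len(samples),
                "pruning": ["spur"] * len(samples),
                "lat": [-34.5] * len(samples),
                "lon": [139.0] * len(samples),
                "alt_m": [250.0] * len(samples),
            },
            index=pd.Index(samples, name="sample"),
        )
    paths = tmp_path / "hpa.csv", tmp_path / "msp.csv", tmp_path / "samples.tsv"
    hpa.to_csv(paths[0])
    msp.to_csv(paths[1])
    meta.to_csv(paths[2], sep="\t")
    return paths


class TestLoading:
    def test_size_filter_keeps_inclusive_bounds(self, tmp_path):
        loci = ["a_80", "b_95", "c_500", "d_510"]
        m = pd.DataFrame(np.ones((3, 4)), index=["s1", "s2", "s3"], columns=loci)
        p = _write_dataset(tmp_path, m, m)
        ds = msap.load_epilocus_dataset(*p)
        assert ds.loci == ["b_95", "c_500"]

    def test_identical_matrices_yield_zero_msl(self, tmp_path):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 2, (6, 10)).astype(float),
                         index=[f"s{i}" for i in range(6)],
                         columns=[f"L{j}_200" for j in range(10)])
        p = _write_dataset(tmp_path, m, m)
        ds = msap.load_epilocus_dataset(*p)
        classes = [c.klass for c in msap.classify_loci(ds)]
        assert MSL not in classes

    def test_sample_only_in_one_file_is_named(self, tmp_path):
        m = pd.DataFrame(np.ones((3, 2)), index=["s1", "s2", "s3"],
                         columns=["L0_200", "L1_200"])
        p = _write_dataset(tmp_path, m, m.drop(index="s3"))
        with pytest.raises(AlignmentError, match="s3"):
            msap.load_epilocus_dataset(*p)

    def test_non_binary_cell_reports_coordinates(self, tmp_path):
        m = pd.DataFrame(np.ones((2, 2)), index=["s1", "s2"],
                         columns=["L0_200", "L1_200"])
        bad = m.copy()
        bad.loc["s2", "L1_200"] = 2.0
        p = _write_dataset(tmp_path, m, bad)
        with pytest.raises(ValueError, match="s2.*L1_200"):
            msap.load_epilocus_dataset(*p)

    def test_unparseable_fragment_size_is_an_error(self):
        with pytest.raises(ValueError, match="fragment size"):
            msap.parse_fragment_sizes(["locus_without_number_"])

    def test_size_row_in_matrix_takes_precedence(self, tmp_path):
        m = pd.DataFrame(np.ones((2, 2)), index=["s1", "s2"], columns=["x", "y"])
        withsize = pd.concat(
            [m, pd.DataFrame([[90, 200]], index=["size"], columns=m.columns)]
        )
        p = _write_dataset(tmp_path, withsize, withsize)
        ds = msap.load_epilocus_dataset(*p)
        assert ds.loci == ["y"]


class TestClassification:
    def _ds(self, hpa_rows, msp_rows):
        samples = [f"s{i}" for i in range(len(hpa_rows))]
        meta = pd.DataFrame(
            {"vineyard": "V1", "subregion": "R1", "clone": "c", "pruning": "spur",
             "lat": -34.5, "lon": 139.0, "alt_m": 250.0},
            index=pd.Index(samples, name="sample"),
        )
        mk = lambda rows: pd.DataFrame(np.array(rows, dtype=float)[:, None],
                                       index=samples, columns=["L_200"])
        return EpilocusDataset(mk(hpa_rows), mk(msp_rows),
                               pd.Series({"L_200": 200}), meta)

    def test_fully_concordant_bands_are_nml(self):
        ds = self._ds([1, 1, 1, 1], [1, 1, 1, 1])
        (c,) = msap.classify_loci(ds)
        assert c.klass == NML and c.discordance_fraction == 0

    def test_quarter_discordance_beats_default_threshold(self):
        ds = self._ds([1, 1, 1, 1], [0, 1, 1, 1])
        (c,) = msap.classify_loci(ds)
        assert c.klass == MSL and c.discordance_fraction == pytest.approx(0.25)

    def test_bandless_locus_is_uninformative(self):
        ds = self._ds([0, 0, 0, 0], [0, 0, 0, 0])
        (c,) = msap.classify_loci(ds)
        assert c.klass == UNINFORMATIVE

    def test_raising_threshold_never_adds_msl(self, msap_small):
        ds, _ = msap_small
        counts = []
        for thr in (0.0, 0.05, 0.1, 0.25, 0.5, 0.9):
            counts.append(sum(c.klass == MSL for c in msap.classify_loci(ds, thr)))
        assert counts == sorted(counts, reverse=True)


class TestStateCalling:
    @pytest.mark.parametrize(
        "pair,state",
        [((1, 1), UNMETHYLATED), ((1, 0), HEMIMETHYLATED),
         ((0, 1), INTERNAL_CG), ((0, 0), FULL_OR_MUTATION)],
    )
    def test_truth_table(self, pair, state):
        assert STATE_TABLE[pair] == state

    def test_table_is_exhaustive_and_exclusive(self):
        assert sorted(STATE_TABLE) == [(0, 0), (0, 1), (1, 0), (1, 1)]
        assert len(set(STATE_TABLE.values())) == 4

    def test_missing_call_gives_missing_state(self, msap_small):
        ds, _ = msap_small
        hpa = ds.hpa.copy()
        hpa.iloc[0, 0] = np.nan
        ds2 = EpilocusDataset(hpa, ds.msp.copy(), ds.sizes, ds.metadata.copy())
        cl = msap.classify_loci(ds2)
        states = msap.call_methylation_states(ds2, cl)
        first_locus = ds.loci[0]
        if first_locus in states.states.columns:
            assert pd.isna(states.states.iloc[0][first_locus])

    def test_frequencies_sum_to_100(self, msap_small):
        ds, _ = msap_small
        states = msap.call_methylation_states(ds, msap.classify_loci(ds))
        assert states.frequencies().sum() == pytest.approx(100.0, abs=0.1)

    def test_full_policy_changes_binary_view(self, msap_small):
        ds, _ = msap_small
        states = msap.call_methylation_states(ds, msap.classify_loci(ds))
        meth = states.binary("methylated")
        miss = states.binary("missing")
        full_mask = states.states == FULL_OR_MUTATION
        assert (meth.values[full_mask.values] == 1).all()
        assert np.isnan(miss.values[full_mask.values]).all()


class TestShannon:
    def test_maximum_entropy_at_half(self):
        view = pd.DataFrame({"L": [0.0, 1.0, 0.0, 1.0]})
        assert msap.per_locus_shannon(view)["L"] == pytest.approx(np.log(2))

    def test_monomorphic_locus_is_zero(self):
        view = pd.DataFrame({"L": [1.0, 1.0, 1.0]})
        assert msap.per_locus_shannon(view)["L"] == 0

    def test_quarter_frequency_closed_form(self):
        view = pd.DataFrame({"L": [1.0, 0.0, 0.0, 0.0]})
        expected = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        assert msap.per_locus_shannon(view)["L"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5623, abs=5e-5)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=4, max_size=20))
    def test_relabel_invariance(self, calls):
        view = pd.DataFrame({"L": np.array(calls, dtype=float)})
        flipped = 1.0 - view
        a = msap.per_locus_shannon(view)["L"]
        b = msap.per_locus_shannon(flipped)["L"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_small_group_excluded(self, msap_small):
        ds, _ = msap_small
        states = msap.call_methylation_states(ds, msap.classify_loci(ds))
        groups = ds.groups("subregion").copy()
        groups.iloc[0] = "singleton"
        res = msap.shannon_diversity(states.binary(), groups)
        assert "singleton" not in {r.group for r in res}

    def test_percent_polymorphic_bounds(self, msap_small):
        ds, _ = msap_small
        states = msap.call_methylation_states(ds, msap.classify_loci(ds))
        for r in msap.shannon_diversity(states.binary(), ds.groups("subregion")):
            assert 0 <= r.percent_polymorphic <= 100
            assert 0 <= r.shannon_mean <= np.log(2)


def test_nml_view_is_band_presence_with_either_enzyme(msap_small):
    ds, _ = msap_small
    cl = msap.classify_loci(ds)
    view = msap.nml_binary_view(ds, cl)
    nml = [c.locus for c in cl if c.klass == NML]
    assert list(view.columns) == nml
    expected = np.fmax(ds.hpa[nml].values, ds.msp[nml].values)
    assert np.array_equal(view.values, expected, equal_nan=True)
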