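import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcanomaly.anomaly import (
    count_by_network,
    fit_normative,
    flag_anomalies,
    flag_edges,
    network_counts_table,
    summarize_groups,
)
from fcanomaly.atlas import build_edge_index, synthetic_parcellation
from fcanomaly.simulate import SimulationConfig, simulate_cohort

from conftest import symmetric_matrix


def matrices_with_edge_values(values_per_control, n_regions):
    """Build control matrices whose edge (0, 1) takes the given values and
    all other edges are 0."""
    out = []
    for v in values_per_control:
        m = np.eye(n_regions)
        m[0, 1] = m[1, 0] = v
        out.append(m)
    return out


class TestFitNormative:
    def test_hand_computed_median_and_mad(self, toy_edge_index):
        mats = matrices_with_edge_values([0.1, 0.2, 0.3, 0.4, 0.5], 4)
        model = fit_normative(mats, toy_edge_index)
        e = toy_edge_index.index_of(0, 1)
        assert model.median[e] == pytest.approx(0.3)
        assert model.mad[e] == pytest.approx(0.1)

    def test_even_count_interpolates(self, toy_edge_index):
        mats = matrices_with_edge_values([1, 2, 3, 4], 4)
        # stretch the correlation range: use raw values on a virtual scale
        model = fit_normative(mats, toy_edge_index)
        e = toy_edge_index.index_of(0, 1)
        assert model.median[e] == pytest.approx(2.5)
        assert model.mad[e] == pytest.approx(1.0)

    def test_identical_controls_give_zero_mad(self, toy_edge_index):
        model = fit_normative(matrices_with_edge_values([0.4] * 5, 4), toy_edge_index)
        assert model.mad[toy_edge_index.index_of(0, 1)] == 0.0

    def test_too_few_controls_rejected(self, toy_edge_index):
        with pytest.raises(ValueError, match=">= 3"):
            fit_normative(matrices_with_edge_values([0.1, 0.2], 4), toy_edge_index)

    def test_mismatched_dimension_rejected(self, toy_edge_index):
        with pytest.raises(ValueError):
            fit_normative([np.eye(4), np.eye(4), np.eye(5)], toy_edge_index)


class TestFlagging:
    @staticmethod
    def model_with(median, mad, edge_index):
        from fcanomaly.anomaly import NormativeModel

        e = edge_index.n_edges
        return NormativeModel(
            median=np.full(e, median), mad=np.full(e, mad),
            n_controls=5, edge_index=edge_index,
        )

    def test_three_mad_boundary(self, toy_edge_index):
        model = self.model_with(0.3, 0.1, toy_edge_index)
        flags = flag_edges(np.array([0.65, 0.55, 0.3, 0.3, -0.05, 0.3]), model)
        assert flags[0]  # |0.35| >= 0.3: "3 or more MAD" is inclusive
        assert not flags[1]  # 2.5 MAD
        assert flags[4]  # 3.5 MAD below

    def test_exactly_three_mad_is_flagged(self, toy_edge_index):
        # binary-exact values so the inclusive boundary is hit precisely
        model = self.model_with(0.0, 0.125, toy_edge_index)
        flags = flag_edges(np.array([0.375, -0.375, 0.374, 0.0, 0.0, 0.0]), model)
        assert flags[0] and flags[1]
        assert not flags[2]

    def test_zero_mad_convention(self, toy_edge_index):
        model = self.model_with(0.3, 0.0, toy_edge_index)
        flags = flag_edges(np.array([0.3, 0.31, 0.3, 0.3, 0.3, 0.3]), model)
        assert not flags[0]  # exact tie with a degenerate band
        assert flags[1]  # deviation above the zero-MAD tolerance

    def test_threshold_must_be_positive(self, toy_edge_index):
        model = self.model_with(0.3, 0.1, toy_edge_index)
        with pytest.raises(ValueError):
            flag_edges(np.zeros(6), model, threshold=0.0)

    @settings(max_examples=200, deadline=None)
    @given(
        n_regions=st.integers(3, 10),
        n_controls=st.integers(3, 8),
        seed=st.integers(0, 10_000),
    )
    def test_matches_brute_force_oracle(self, n_regions, n_controls, seed):
        """Flags agree with an independent reimplementation that recomputes
        medians and MADs by explicit sorting, edge by edge."""
        rng = np.random.default_rng(seed)
        ei = build_edge_index(n_regions)
        controls = [symmetric_matrix(rng, n_regions) for _ in range(n_controls)]
        subject = symmetric_matrix(rng, n_regions)
        model = fit_normative(controls, ei)
        got = flag_edges(ei.edge_values(subject), model)

        def median_by_sorting(vals):
            s = sorted(vals)
            n = len(s)
            return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2

        for e, (i, j) in enumerate(ei.pairs()):
            vals = [c[i, j] for c in controls]
            med = median_by_sorting(vals)
            mad = median_by_sorting([abs(v - med) for v in vals])
            v = subject[i, j]
            if mad <= 1e-6:
                expect = abs(v - med) > 1e-6
            else:
                expect = abs(v - med) >= 3 * mad
            assert got[e] == expect, (i, j)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 1000), t1=st.floats(0.5, 3.0), dt=st.floats(0.0, 3.0))
    def test_raising_threshold_never_adds_flags(self, seed, t1, dt):
        rng = np.random.default_rng(seed)
        ei = build_edge_index(8)
        controls = [symmetric_matrix(rng, 8) for _ in range(6)]
        model = fit_normative(controls, ei)
        v = ei.edge_values(symmetric_matrix(rng, 8))
        low = flag_edges(v, model, threshold=t1)
        high = flag_edges(v, model, threshold=t1 + dt)
        assert not np.any(high & ~low)

    def test_deterministic(self, default_cohort):
        c = default_cohort
        model = fit_normative([c.baseline[s] for s in c.control_ids], c.edge_index)
        sid = c.patient_ids[0]
        p1 = flag_anomalies(c.baseline[sid], model, c.parcellation, subject_id=sid)
        p2 = flag_anomalies(c.baseline[sid], model, c.parcellation, subject_id=sid)
        assert np.array_equal(p1.flags, p2.flags)
        assert p1.network_counts == p2.network_counts


class TestNetworkCounts:
    def test_cross_network_edge_counts_for_both(self, toy_parcellation, toy_edge_index):
        flags = np.zeros(6, dtype=bool)
        flags[toy_edge_index.index_of(0, 1)] = True  # within-DMN
        counts = count_by_network(flags, toy_edge_index, toy_parcellation)
        assert counts == {"DMN": 1, "SMN": 0, "OTHER": 0}

        flags = np.zeros(6, dtype=bool)
        flags[toy_edge_index.index_of(0, 2)] = True  # DMN-SMN
        counts = count_by_network(flags, toy_edge_index, toy_parcellation)
        assert counts == {"DMN": 1, "SMN": 1, "OTHER": 0}

    def test_within_only_mode(self, toy_parcellation, toy_edge_index):
        flags = np.ones(6, dtype=bool)
        counts = count_by_network(
            flags, toy_edge_index, toy_parcellation, mode="within_only"
        )
        assert counts == {"DMN": 1, "SMN": 0, "OTHER": 0}

    def test_no_flags_gives_zeros(self, toy_parcellation, toy_edge_index):
        counts = count_by_network(
            np.zeros(6, dtype=bool), toy_edge_index, toy_parcellation
        )
        assert set(counts.values()) == {0}

    def test_counts_determined_by_flags(self, default_cohort):
        """Profile network counts are exactly reproducible from the flags."""
        c = default_cohort
        model = fit_normative([c.baseline[s] for s in c.control_ids], c.edge_index)
        sid = c.patient_ids[3]
        prof = flag_anomalies(c.baseline[sid], model, c.parcellation, subject_id=sid)
        assert prof.network_counts == count_by_network(
            prof.flags, c.edge_index, c.parcellation
        )


class TestSummaries:
    @staticmethod
    def profile(sid, tp, counts):
        from fcanomaly.anomaly import AnomalyProfile

        return AnomalyProfile(
            subject_id=sid, timepoint=tp,
            flags=np.zeros(1, dtype=bool), network_counts=counts,
        )

    def test_hand_computed_group_means(self):
        base = {
            "a": self.profile("a", "baseline", {"DMN": 10}),
            "b": self.profile("b", "baseline", {"DMN": 6}),
        }
        fu = {
            "a": self.profile("a", "follow_up", {"DMN": 2}),
            "b": self.profile("b", "follow_up", {"DMN": 4}),
        }
        s = summarize_groups(
            base, fu, responder={"a": True, "b": True},
            arms={"a": "drug", "b": "drug"},
        )
        mc = s.mean_counts.set_index(["group", "timepoint"])["mean_count"]
        assert mc[("responder", "baseline")] == pytest.approx(8.0)
        assert mc[("responder", "follow_up")] == pytest.approx(3.0)
        assert s.mean_abs_change["mean_abs_change"].iloc[0] == pytest.approx(5.0)
        assert s.mean_signed_change_by_arm["mean_signed_change"].iloc[
            0
        ] == pytest.approx(-5.0)

    def test_no_change_gives_zero_abs_change(self):
        base = {"a": self.profile("a", "baseline", {"DMN": 4})}
        fu = {"a": self.profile("a", "follow_up", {"DMN": 4})}
        s = summarize_groups(base, fu, {"a": False}, {"a": "drug"})
        assert s.mean_abs_change["mean_abs_change"].iloc[0] == 0.0

    def test_missing_timepoint_names_subject(self):
        base = {"a": self.profile("a", "baseline", {"DMN": 4})}
        with pytest.raises(ValueError, match="'a'"):
            summarize_groups(base, {}, {"a": True}, {"a": "drug"})


class TestControlCalibration:
    def test_holdout_control_flag_rate_matches_gaussian_tail(self, default_cohort):
        """A held-out control scored against the remaining controls is
        flagged at the rate implied by a 3-raw-MAD band on Gaussian noise
        (population tail 4.3%, inflated by finite-sample MAD noise) — a
        deliberately raw band, several times wider than a 3-sigma rule."""
        c = default_cohort
        rates = []
        for held in c.control_ids[:8]:
            rest = [c.baseline[s] for s in c.control_ids if s != held]
            model = fit_normative(rest, c.edge_index)
            flags = flag_edges(c.edge_index.edge_values(c.baseline[held]), model)
            rates.append(flags.mean())
        assert 0.02 <= np.mean(rates) <= 0.10
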