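"""Pairing construction and in/out-group synchrony averaging."""

import numpy as np
import pytest

from cardiosync.crqa import CRQAMetrics
from cardiosync.groups import (
    build_pairings,
    group_contrast,
    participant_synchrony,
    synchrony_table,
)
from cardiosync.manifest import SessionManifest
from cardiosync.preprocess import extract_segments
from cardiosync.simulate import SimulationConfig, simulate_session


def _manifest(n_quartets):
    manifest, _, _ = simulate_session(
        SimulationConfig(n_quartets=n_quartets, fixed_performance_s=240.0,
                         seed=1)
    )
    return manifest


class TestBuildPairings:
    def test_two_quartets_partition(self):
        manifest = _manifest(2)
        pairings = build_pairings(manifest, seed=0)
        for pid, pairing in pairings.items():
            q = manifest.quartet_of[pid]
            assert len(pairing.in_partners) == 3
            assert all(manifest.quartet_of[p] == q
                       for p in pairing.in_partners)
            assert len(set(pairing.out_partners)) == 3
            assert all(manifest.quartet_of[p] != q
                       for p in pairing.out_partners)

    def test_deterministic_for_seed(self):
        manifest = _manifest(3)
        assert build_pairings(manifest, seed=5) == \
            build_pairings(manifest, seed=5)
        assert build_pairings(manifest, seed=5) != \
            build_pairings(manifest, seed=6)

    def test_out_partners_never_in_own_quartet_many_seeds(self):
        manifest = _manifest(3)
        for seed in range(1000):
            pairings = build_pairings(manifest, seed=seed)
            for pid, pairing in pairings.items():
                q = manifest.quartet_of[pid]
                assert all(manifest.quartet_of[p] != q
                           for p in pairing.out_partners)

    def test_single_quartet_rejected(self):
        manifest = _manifest(1)
        with pytest.raises(ValueError, match="2 quartets"):
            build_pairings(manifest, seed=0)


@pytest.fixture(scope="module")
def session_synchrony(small_session_module):
    manifest, tachograms, _ = small_session_module
    series = extract_segments(manifest, tachograms, segments=("m1_T1",))
    pairings = build_pairings(manifest, seed=3)
    synchrony = participant_synchrony(pairings, series, epsilon=0.2, m=11,
                                      segments=("m1_T1",))
    return manifest, series, pairings, synchrony


@pytest.fixture(scope="module")
def small_session_module():
    from cardiosync.simulate import simulate_fixture_small
    return simulate_fixture_small(seed=7)


class TestParticipantSynchrony:
    def test_two_rows_per_participant_segment(self, session_synchrony):
        manifest, _, _, synchrony = session_synchrony
        assert len(synchrony) == len(manifest.participants) * 2

    def test_mean_is_arithmetic_over_pairs(self, session_synchrony):
        # averaging 3 pair metrics equals the row value
        manifest, series, pairings, synchrony = session_synchrony
        from cardiosync.groups import _PairMetricsCache
        cache = _PairMetricsCache(series, 0.2, 11, 1, "rms", 2, 2, False,
                                  epsilon_mode="absolute")
        row = synchrony[0]
        per_pair = [cache.metrics(row.participant, p, "m1_T1")
                    for p in row.pairing_ids]
        assert row.metrics.rec == pytest.approx(
            np.mean([p.rec for p in per_pair]), abs=1e-12
        )

    def test_partner_order_invariance(self, session_synchrony):
        manifest, series, pairings, _ = session_synchrony
        reversed_pairings = {
            pid: type(p)(in_partners=p.in_partners[::-1],
                         out_partners=p.out_partners[::-1])
            for pid, p in pairings.items()
        }
        a = participant_synchrony(pairings, series, epsilon=0.2, m=11,
                                  segments=("m1_T1",))
        b = participant_synchrony(reversed_pairings, series, epsilon=0.2,
                                  m=11, segments=("m1_T1",))
        for ra, rb in zip(a, b):
            assert ra.metrics.rec == pytest.approx(rb.metrics.rec, abs=1e-15)
            assert ra.metrics.lam == pytest.approx(rb.metrics.lam, abs=1e-15)

    def test_missing_partner_series_dropped_with_warning(
            self, session_synchrony, caplog):
        manifest, series, pairings, _ = session_synchrony
        victim = manifest.participants[-1]
        reduced = {k: v for k, v in series.items() if k[0] != victim}
        with caplog.at_level("WARNING"):
            synchrony = participant_synchrony(
                pairings, reduced, epsilon=0.2, m=11, segments=("m1_T1",)
            )
        assert any("pairing dropped" in r.message for r in caplog.records)
        # remaining averages built from 2 pairs still reported
        assert all(len(s.pairing_ids) >= 2 for s in synchrony)

    def test_self_pairing_reproduces_self_crp(self, session_synchrony):
        manifest, series, pairings, _ = session_synchrony
        pid = manifest.participants[0]
        degenerate = {pid: type(pairings[pid])(
            in_partners=(pid, pid, pid), out_partners=(pid, pid, pid)
        )}
        sync = participant_synchrony(degenerate, series, epsilon=0.2, m=11,
                                     segments=("m1_T1",))
        from cardiosync.groups import _PairMetricsCache
        cache = _PairMetricsCache(series, 0.2, 11, 1, "rms", 2, 2, False,
                                  epsilon_mode="absolute")
        self_metrics = cache.metrics(pid, pid, "m1_T1")
        assert sync[0].metrics.rec == pytest.approx(self_metrics.rec)


class TestGroupContrast:
    def test_summary_shape_and_direction(self, session_synchrony):
        _, _, _, synchrony = session_synchrony
        table = group_contrast(synchrony)
        assert set(table["metric"]) == {"rec", "ent", "lam", "lmax"}
        assert set(table["group_type"]) == {"in", "out"}
        assert {"mean", "se", "n"} <= set(table.columns)

    def test_identical_groups_equal_means(self, session_synchrony):
        manifest, _, _, synchrony = session_synchrony
        mirrored = []
        for s in synchrony:
            if s.group_type == "in":
                mirrored.append(s)
                mirrored.append(type(s)(
                    participant=s.participant, segment=s.segment,
                    group_type="out", metrics=s.metrics,
                    pairing_ids=s.pairing_ids,
                ))
        table = group_contrast(mirrored)
        wide = table.pivot(index="metric", columns="group_type",
                           values="mean")
        np.testing.assert_allclose(wide["in"], wide["out"], rtol=1e-12)

    def test_single_participant_se_missing(self, session_synchrony):
        _, _, _, synchrony = session_synchrony
        pid = synchrony[0].participant
        sub = [s for s in synchrony if s.participant == pid]
        table = group_contrast(sub)
        assert table["se"].isna().all()

    def test_empty_filter_rejected(self, session_synchrony):
        _, _, _, synchrony = session_synchrony
        with pytest.raises(ValueError):
            group_contrast(synchrony, segments=("nonexistent",))


def test_synchrony_table_tidy_columns(session_synchrony):
    _, _, _, synchrony = session_synchrony
    table = synchrony_table(synchrony)
    assert list(table.columns) == ["participant_id", "segment", "group_type",
                                   "metric", "value"]
    assert len(table) == len(synchrony) * 4
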