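"""Contact detection, Annexin-V validity/localization and summaries."""

import numpy as np
import pytest

from apobd import (
    ApoptosisEvent,
    CellRecord,
    annexin_validity,
    classify_localization,
    delineate_synapse,
    detect_contacts,
    iou,
    localization_pcc,
    segment_cells_standin,
    summarize_events,
)
from apobd.interaction import AnnexinAssessment, track_cells_standin


def _pair_with_overlap(frames_overlapping, n_frames=10):
    """Effector/target records overlapping in the given frames."""
    eff = CellRecord(cell_id=1, cell_type="effector")
    tgt = CellRecord(cell_id=2, cell_type="target")
    for t in range(n_frames):
        e = np.zeros((20, 20), bool)
        g = np.zeros((20, 20), bool)
        e[5:10, 5:10] = True
        if t in frames_overlapping:
            g[8:13, 8:13] = True  # overlaps e
        else:
            g[14:19, 14:19] = True
        eff.masks[t], eff.centroids[t] = e, (7.0, 7.0)
        tgt.masks[t] = g
        tgt.centroids[t] = (10.0, 10.0) if t in frames_overlapping else (16.0, 16.0)
    return eff, tgt


class TestContacts:
    def test_five_frame_overlap_qualifies(self):
        eff, tgt = _pair_with_overlap({2, 3, 4, 5, 6})
        out = detect_contacts([eff], [tgt], 10)
        assert len(out) == 1
        assert (out[0].start_frame, out[0].end_frame) == (2, 6)

    def test_three_frame_overlap_does_not_qualify(self):
        eff, tgt = _pair_with_overlap({2, 3, 4})
        assert detect_contacts([eff], [tgt], 10) == []

    def test_no_overlap_gives_empty_list(self):
        eff, tgt = _pair_with_overlap(set())
        assert detect_contacts([eff], [tgt], 10) == []

    def test_intervals_maximal_and_disjoint(self):
        eff, tgt = _pair_with_overlap({0, 1, 2, 3, 6, 7, 8, 9})
        out = detect_contacts([eff], [tgt], 10)
        spans = [(iv.start_frame, iv.end_frame) for iv in out]
        assert spans == [(0, 3), (6, 9)]


def _masks_with_iou(n_overlap, n_a_only, n_c_only, shape=(30, 60)):
    """An 'annexin region' and cell mask with an exact pixel overlap."""
    ann_region = np.zeros(shape, bool)
    cell = np.zeros(shape, bool)
    ann_region[0, :n_overlap] = cell[0, :n_overlap] = True
    ann_region[1, :n_a_only] = True
    cell[2, :n_c_only] = True
    return ann_region, cell


class TestAnnexinValidity:
    def test_iou_quarter_is_valid(self):
        region, cell = _masks_with_iou(4, 6, 6)  # 4 / 16 = 0.25
        chan = np.where(region, 2000.0, 0.0)
        a = annexin_validity(chan, cell)
        assert a.iou_vs_cell == pytest.approx(0.25)
        assert a.valid

    def test_iou_twentieth_is_invalid(self):
        region, cell = _masks_with_iou(2, 19, 19)  # 2 / 40 = 0.05
        a = annexin_validity(np.where(region, 2000.0, 0.0), cell)
        assert a.iou_vs_cell == pytest.approx(0.05)
        assert not a.valid

    def test_boundary_iou_exactly_point_one_is_invalid(self):
        region, cell = _masks_with_iou(2, 9, 9)  # 2 / 20 = 0.10
        a = annexin_validity(np.where(region, 2000.0, 0.0), cell)
        assert a.iou_vs_cell == pytest.approx(0.10)
        assert not a.valid  # strictly "above 0.1"

    def test_dark_channel_is_invalid(self):
        cell = np.zeros((10, 10), bool)
        cell[2:5, 2:5] = True
        a = annexin_validity(np.zeros((10, 10)), cell)
        assert a.iou_vs_cell == 0.0 and not a.valid

    def test_monotone_in_signal_extent(self):
        """Growing the annexin region inside the cell never invalidates."""
        cell = np.zeros((20, 20), bool)
        cell[5:15, 5:15] = True
        prev_iou = -1.0
        for width in range(1, 11):
            region = np.zeros((20, 20), bool)
            region[5:15, 5:5 + width] = True
            a = annexin_validity(np.where(region, 1000.0, 0.0), cell)
            assert a.iou_vs_cell >= prev_iou
            prev_iou = a.iou_vs_cell


class TestLocalization:
    @pytest.mark.parametrize("value,expected", [
        (0.7, "even"), (0.2, "localized"), (0.5, "localized")])
    def test_even_threshold(self, value, expected):
        a = AnnexinAssessment(iou_vs_cell=value, valid=True)
        assert classify_localization(a) == expected
        assert a.distribution == expected


class TestSynapse:
    def _disks(self, gap):
        rr, cc = np.mgrid[:60, :80]
        e = (rr - 30) ** 2 + (cc - 20) ** 2 <= 8**2
        t = (rr - 30) ** 2 + (cc - (20 + 16 + gap)) ** 2 <= 8**2
        return e, t

    def test_abutting_disks_share_a_band(self):
        e, t = self._disks(gap=1)
        syn = delineate_synapse(e, t, dilation_radius=3)
        assert syn.any()
        rows, cols = np.nonzero(syn)
        assert 24 <= cols.mean() <= 33  # band near the shared boundary

    def test_distant_disks_give_empty_mask(self):
        e, t = self._disks(gap=20)
        assert not delineate_synapse(e, t, dilation_radius=3).any()

    def test_synapse_within_each_dilation(self):
        from scipy.ndimage import binary_dilation
        from skimage.morphology import disk as disk_se
        e, t = self._disks(gap=2)
        syn = delineate_synapse(e, t, dilation_radius=3)
        assert not np.any(syn & ~binary_dilation(e, structure=disk_se(3)))
        assert not np.any(syn & ~binary_dilation(t, structure=disk_se(3)))


class TestLocalizationPCC:
    def _scene(self):
        rr, cc = np.mgrid[:60, :80]
        cell = (rr - 30) ** 2 + (cc - 30) ** 2 <= 10**2
        eff = (rr - 30) ** 2 + (cc - 51) ** 2 <= 10**2
        syn = delineate_synapse(eff, cell, dilation_radius=3)
        return cell, syn

    def test_even_signal_correlates_with_cell(self):
        cell, syn = self._scene()
        ann = np.where(cell, 2000.0, 0.0)
        p_cell, p_syn = localization_pcc(ann, cell, syn)
        assert p_cell > p_syn

    def test_synapse_signal_correlates_with_synapse(self):
        cell, syn = self._scene()
        ann = np.where(syn, 2000.0, 0.0)
        p_cell, p_syn = localization_pcc(ann, cell, syn)
        assert p_syn > p_cell

    def test_dark_channel_errors(self):
        cell, syn = self._scene()
        with pytest.raises(ValueError):
            localization_pcc(np.zeros((60, 80)), cell, syn)


class TestCellSegmentation:
    def test_truth_cells_recovered(self, event_sim):
        frame = event_sim.video.frames[0]
        seg = segment_cells_standin(frame)
        truth = event_sim.truth.cells
        for ctype in ("effector", "target"):
            truth_cells = [c for c in truth if c.cell_type == ctype]
            _, inst = seg[ctype]
            for c in truth_cells:
                best = max(
                    (iou(c.masks[0], inst.instance(i))
                     for i in range(1, inst.n_instances + 1)),
                    default=0.0)
                assert best >= 0.6

    def test_instance_count_bounded_by_components(self, quiet_sim):
        frame = quiet_sim.video.frames[0]
        seg = segment_cells_standin(frame)
        from scipy.ndimage import label as cc_label
        for name, (mask, inst) in seg.items():
            _, n_cc = cc_label(mask)
            assert inst.n_instances <= n_cc

    def test_constant_channel_errors(self):
        from apobd import MultiChannelFrame
        frame = MultiChannelFrame(
            phase=np.zeros((32, 32)),
            channels={"effector": np.full((32, 32), 5.0)})
        with pytest.raises(ValueError):
            segment_cells_standin(frame)

    def test_tracks_follow_truth_cells(self, event_sim):
        tracks = track_cells_standin(event_sim.video)
        truth = event_sim.truth.cells
        assert len(tracks) == len(truth)
        n_frames = len(event_sim.video)
        for tc in truth:
            # some tracked cell matches this truth cell in every frame
            match = None
            for tr in tracks:
                if tr.cell_type != tc.cell_type:
                    continue
                if all(tr.present(t) and iou(tr.masks[t], tc.masks[t]) >= 0.6
                       for t in range(n_frames)):
                    match = tr
                    break
            assert match is not None


class TestSummaries:
    def _events(self, n_valid, n_invalid, killing=False):
        out = []
        for i in range(n_valid + n_invalid):
            out.append(ApoptosisEvent(
                nanowell_id=f"w{i}", onset_frame=3,
                apoptotic_cell_id=1, killing=killing,
                annexin_valid=i < n_valid))
        return out

    def test_fraction_three_in_ten(self):
        table = summarize_events(self._events(3, 7))
        row = table[table.category == "all"].iloc[0]
        assert row.n_events == 10
        assert row.frac_annexin_valid == pytest.approx(0.30)

    def test_all_killing_leaves_nonkilling_empty(self):
        table = summarize_events(self._events(2, 2, killing=True))
        row = table[table.category == "non_killing"].iloc[0]
        assert row.n_events == 0

    def test_empty_input_gives_zero_counts(self):
        table = summarize_events([])
        assert (table.n_events == 0).all()

    def test_recovers_simulated_annexin_rate(self):
        """End-to-end parameter recovery of the 30% Annexin-valid rate."""
        from apobd import SimConfig, simulate_video
        events = []
        n = 60
        for seed in range(n):
            cfg = SimConfig(image_size=(64, 64), n_effectors=0, n_targets=1,
                            apobd_count_at_burst=(1, 2), onset_frame=0,
                            n_frames=2, seed=2000 + seed)
            sim = simulate_video(cfg)
            dying = next(c for c in sim.truth.cells
                         if c.cell_id == sim.truth.apoptotic_cell_id)
            a = annexin_validity(
                sim.video.frames[0].channels["annexin"], dying.masks[0])
            events.append(ApoptosisEvent(
                nanowell_id=sim.video.nanowell_id, onset_frame=0,
                apoptotic_cell_id=dying.cell_id, annexin_valid=a.valid))
        frac = summarize_events(events).set_index("category").loc[
            "all", "frac_annexin_valid"]
        p = 0.3
        se = (p * (1 - p) / n) ** 0.5
        assert abs(frac - p) <= 3 * se + 1 / n
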