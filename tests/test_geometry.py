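import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from glottalgap import (
    GLOTTIS,
    LEFT_FOLD,
    RIGHT_FOLD,
    GeometryError,
    LabeledFrame,
    MaskSequence,
    PhonationParams,
    compute_anchor_ratio,
    compute_areas,
    extract_contact_points,
    find_collision_points,
    fit_midline,
    generate_sequence,
    locate_anchor_point,
    measure_sequence,
    perpendicular_gap_distance,
    relative_glottal_area,
    select_reference_frame,
)
from glottalgap.geometry import AreaRecord, CollisionSet, _oriented_direction

from conftest import make_frame, paint_rect, vertical_larynx_frame

label_grids = hnp.arrays(
    dtype=np.uint8,
    shape=st.tuples(st.integers(8, 32), st.integers(8, 32)),
    elements=st.integers(0, 3),
)


# ---------------------------------------------------------------------------
# areas


class TestAreas:
    def test_all_background(self):
        a = compute_areas(make_frame(16, 16))
        assert (a.left_px, a.right_px, a.glottis_px) == (0, 0, 0)

    def test_glottis_block(self):
        fr = paint_rect(make_frame(32, 32), GLOTTIS, 5, 15, 5, 15)
        assert compute_areas(fr).glottis_px == 100

    @given(grid=label_grids)
    @settings(max_examples=30, deadline=None)
    def test_counts_match_per_cell_tally(self, grid):
        a = compute_areas(LabeledFrame(grid))
        tally = {c: 0 for c in range(4)}
        for row in grid:
            for cell in row:
                tally[int(cell)] += 1
        assert (a.left_px, a.right_px, a.glottis_px) == (tally[1], tally[2], tally[3])

    def test_relative_area_closed_glottis(self):
        assert relative_glottal_area(AreaRecord(30, 40, 0)) == 0.0

    def test_relative_area_half(self):
        assert relative_glottal_area(AreaRecord(25, 25, 50)) == 0.5

    def test_relative_area_empty_frame_errors(self):
        with pytest.raises(GeometryError, match="no larynx"):
            relative_glottal_area(AreaRecord(0, 0, 0))

    @given(
        left=st.integers(0, 1000), right=st.integers(0, 1000), gl=st.integers(0, 1000)
    )
    @settings(max_examples=50, deadline=None)
    def test_relative_area_matches_direct_arithmetic(self, left, right, gl):
        total = left + right + gl
        if total == 0:
            return
        assert relative_glottal_area(AreaRecord(left, right, gl)) == pytest.approx(
            gl / total
        )


class TestReferenceFrame:
    def _seq(self, glottis_sizes):
        frames = []
        for k, g in enumerate(glottis_sizes):
            fr = make_frame(32, 32, frame_index=k)
            paint_rect(fr, LEFT_FOLD, 0, 4, 0, 32)
            if g:
                paint_rect(fr, GLOTTIS, 10, 10 + g, 10, 11)
            frames.append(fr)
        return MaskSequence(frames)

    def test_argmax_area(self):
        assert select_reference_frame(self._seq([1, 5, 3])) == 1

    def test_tie_breaks_to_lowest_index(self):
        assert select_reference_frame(self._seq([4, 4])) == 0

    def test_never_open_errors(self):
        with pytest.raises(GeometryError, match="never opens"):
            select_reference_frame(self._seq([0, 0]))

    def test_simulator_argmax_matches_analytic_peak(self):
        # f0=200 at 4000 fps peaks at frame 5 within the first cycle
        params = PhonationParams(n_frames=20, f0=200.0, fps=4000.0)
        seq = generate_sequence(params)
        assert abs(select_reference_frame(seq) - 5) <= 1


# ---------------------------------------------------------------------------
# contact points


def brute_force_contact_points(frame):
    """Exhaustive scan over all 8-adjacent (left, right) cell pairs."""
    lab = frame.labels
    pts = set()
    h, w = lab.shape
    for j in range(h):
        for i in range(w):
            if lab[j, i] != LEFT_FOLD:
                continue
            for dj in (-1, 0, 1):
                for di in (-1, 0, 1):
                    if dj == di == 0:
                        continue
                    jj, ii = j + dj, i + di
                    if 0 <= jj < h and 0 <= ii < w and lab[jj, ii] == RIGHT_FOLD:
                        pts.add((i + 0.5 + di / 2.0, j + 0.5 + dj / 2.0))
    return pts


class TestContactPoints:
    def test_abutting_rectangles_give_shared_edge(self):
        fr = make_frame()
        paint_rect(fr, LEFT_FOLD, 100, 128, 20, 200)
        paint_rect(fr, RIGHT_FOLD, 128, 156, 20, 200)
        pts, source = extract_contact_points(fr)
        assert source == "contact"
        assert np.allclose(pts[:, 0], 128.0)

    def test_separated_folds_fall_back_to_glottis_midpoints(self):
        fr = vertical_larynx_frame(glottis_y=(20, 200), fold_y=(20, 200),
                                   glottis_halfwidth=2)
        pts, source = extract_contact_points(fr)
        assert source == "glottis_midpoints"
        assert np.allclose(pts[:, 0], 128.0)

    def test_no_evidence_errors(self):
        fr = paint_rect(make_frame(16, 16), LEFT_FOLD, 0, 8, 0, 16)
        with pytest.raises(GeometryError, match="no midline evidence"):
            extract_contact_points(fr)

    @given(grid=label_grids, data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_exhaustive_pair_scan(self, grid, data):
        fr = LabeledFrame(grid)
        expected = brute_force_contact_points(fr)
        if len(expected) >= 3:
            pts, source = extract_contact_points(fr)
            assert source == "contact"
            assert set(map(tuple, pts)) == expected


# ---------------------------------------------------------------------------
# midline regression


def normal_equation_x_on_y(points):
    """Independent least-squares oracle minimizing horizontal residuals."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([np.ones_like(y), y])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    return coef  # x = coef[0] + coef[1] * y


class TestFitMidline:
    def test_vertical_points_give_exactly_vertical_line(self):
        pts = np.array([[5.0, 0.0], [5.0, 1.0], [5.0, 2.0]])
        m = fit_midline(pts)
        assert m.fit_mode == "x_over_y"
        assert m.direction[0] == 0.0
        assert abs(m.direction[1]) == 1.0
        assert m.anchor_point[0] == 5.0

    def test_collinear_points_recovered_exactly(self):
        y = np.array([0.0, 1.0, 2.0, 5.0])
        pts = np.column_stack([y / 2.0, y])  # the line y = 2x
        m = fit_midline(pts)
        dy_dx = m.direction[1] / m.direction[0]
        assert dy_dx == pytest.approx(2.0)

    def test_horizontal_points_fall_back(self):
        pts = np.array([[0.0, 3.0], [1.0, 3.0], [4.0, 3.0]])
        m = fit_midline(pts)
        assert m.fit_mode == "fallback_horizontal"
        np.testing.assert_allclose(m.direction, [1.0, 0.0])

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            fit_midline(np.array([[1.0, 1.0]]))
        with pytest.raises(GeometryError):
            fit_midline(np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_matches_normal_equation_oracle_on_random_point_sets(self, rng):
        for _ in range(200):
            n = rng.integers(3, 30)
            pts = rng.uniform(0, 256, size=(n, 2))
            m = fit_midline(pts)
            intercept, slope = normal_equation_x_on_y(pts)
            b = m.direction[0] / m.direction[1]
            assert b == pytest.approx(slope, rel=1e-9, abs=1e-12)
            x_at_ybar = m.anchor_point[0]
            assert x_at_ybar == pytest.approx(
                intercept + slope * m.anchor_point[1], rel=1e-9
            )


# ---------------------------------------------------------------------------
# collision points


def fine_march_collisions(frame, line, rear="top", step=0.01):
    """0.01-px marching oracle for region entry/exit along the midline."""
    d = _oriented_direction(line.direction, rear)
    p0 = line.anchor_point
    span = frame.width + frame.height
    ts = np.arange(-span, span, step)
    pts = p0[None, :] + ts[:, None] * d[None, :]
    labels = np.array([frame.label_at(x, y) for x, y in pts])
    inside = np.isin(labels, (LEFT_FOLD, RIGHT_FOLD, GLOTTIS))
    if not inside.any():
        return None
    idx = np.nonzero(inside)[0]
    gidx = np.nonzero(labels == GLOTTIS)[0]
    out = {"fold_upper": pts[idx[0]], "fold_lower": pts[idx[-1]]}
    if gidx.size:
        out["glottis_upper"] = pts[gidx[0]]
        out["glottis_lower"] = pts[gidx[-1]]
    return out


class TestCollisionPoints:
    def test_axis_aligned_rectangles(self):
        fr = vertical_larynx_frame(fold_y=(20, 200), glottis_y=(50, 150))
        line = fit_midline(np.array([[128.0, 0.0], [128.0, 1.0], [128.0, 2.0]]))
        cs = find_collision_points(line, fr)
        assert cs.fold_upper[1] == pytest.approx(200.0, abs=0.25)
        assert cs.fold_lower[1] == pytest.approx(20.0, abs=0.25)
        assert cs.glottis_upper[1] == pytest.approx(150.0, abs=0.25)
        assert cs.glottis_lower[1] == pytest.approx(50.0, abs=0.25)

    def test_closed_glottis_has_no_glottis_collisions(self):
        fr = vertical_larynx_frame(glottis_halfwidth=0)
        line = fit_midline(np.array([[128.0, 0.0], [128.0, 2.0]]))
        cs = find_collision_points(line, fr)
        assert cs.glottis_upper is None and cs.glottis_lower is None
        assert cs.fold_upper is not None

    def test_line_missing_larynx_errors(self):
        fr = vertical_larynx_frame()
        line = fit_midline(np.array([[5.0, 0.0], [5.0, 2.0]]))
        with pytest.raises(GeometryError, match="misses larynx"):
            find_collision_points(line, fr)

    def test_random_blobs_match_fine_marching_oracle(self, rng):
        for trial in range(25):
            params = PhonationParams(
                width=96,
                height=96,
                n_frames=1,
                glottis_half_length=20.0,
                max_opening_halfwidth=6.0,
                fold_width=12.0,
                fold_axis_margin=6.0,
                rotation_deg=rng.uniform(-25, 25),
                translation=(rng.uniform(-6, 6), rng.uniform(-6, 6)),
                boundary_jitter_px=0.6,
                phase=rng.uniform(0.2, np.pi - 0.2),
                rear_gap_halfwidth=rng.uniform(0, 3),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            fr = generate_sequence(params).frames[0]
            pts, src = extract_contact_points(fr)
            line = fit_midline(pts, source=src)
            cs = find_collision_points(line, fr)
            oracle = fine_march_collisions(fr, line)
            assert oracle is not None
            for key in ("fold_upper", "fold_lower", "glottis_upper", "glottis_lower"):
                got = getattr(cs, key)
                want = oracle.get(key)
                if want is None:
                    assert got is None
                    continue
                assert np.linalg.norm(got - want) <= 0.25, (trial, key)


# ---------------------------------------------------------------------------
# anchors


def _vertical_collision_set(x=128.0, fold=(20.0, 200.0), glottis=(50.0, 150.0)):
    return CollisionSet(
        fold_upper=np.array([x, fold[1]]),
        fold_lower=np.array([x, fold[0]]),
        glottis_upper=np.array([x, glottis[1]]) if glottis else None,
        glottis_lower=np.array([x, glottis[0]]) if glottis else None,
    )


class TestAnchors:
    def test_coincident_segments_fraction_10(self):
        cs = _vertical_collision_set(fold=(20.0, 200.0), glottis=(20.0, 200.0))
        assert compute_anchor_ratio(cs, 0.10).stored_ratio == pytest.approx(0.90)

    def test_coincident_segments_fraction_50(self):
        cs = _vertical_collision_set(fold=(20.0, 200.0), glottis=(20.0, 200.0))
        assert compute_anchor_ratio(cs, 0.50).stored_ratio == pytest.approx(0.50)

    def test_hand_arithmetic_example(self):
        # fold y in [20, 200], glottis y in [50, 150], rear at the top:
        # the 10% point sits at y = 140, i.e. ratio (140-20)/180 = 2/3
        cs = _vertical_collision_set()
        spec = compute_anchor_ratio(cs, 0.10)
        assert spec.stored_ratio == pytest.approx(2.0 / 3.0)
        anchor = locate_anchor_point(cs, spec)
        np.testing.assert_allclose(anchor, [128.0, 140.0])

    def test_ratio_boundaries_map_to_fold_collisions(self):
        from glottalgap import AnchorSpec

        cs = _vertical_collision_set()
        np.testing.assert_allclose(
            locate_anchor_point(cs, AnchorSpec(0.0, 0.0)), cs.fold_lower
        )
        np.testing.assert_allclose(
            locate_anchor_point(cs, AnchorSpec(0.0, 1.0)), cs.fold_upper
        )

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            compute_anchor_ratio(_vertical_collision_set(), 1.5)

    def test_missing_glottis_collisions(self):
        cs = _vertical_collision_set(glottis=None)
        with pytest.raises(GeometryError):
            compute_anchor_ratio(cs, 0.1)


# ---------------------------------------------------------------------------
# perpendicular distances


def elliptical_glottis_frame(a=40.0, b=10.0, cx=128.0, cy=128.0):
    fr = make_frame()
    ys, xs = np.mgrid[0:256, 0:256]
    X, Y = xs + 0.5, ys + 0.5
    inside = ((X - cx) / b) ** 2 + ((Y - cy) / a) ** 2 < 1.0
    left = (X < cx) & ~inside & (np.abs(X - cx) < 50) & (np.abs(Y - cy) < 60)
    right = (X >= cx) & ~inside & (np.abs(X - cx) < 50) & (np.abs(Y - cy) < 60)
    fr.labels[inside] = GLOTTIS
    fr.labels[left] = LEFT_FOLD
    fr.labels[right] = RIGHT_FOLD
    return fr


class TestPerpendicularDistance:
    def test_closed_glottis_gives_zero(self):
        fr = vertical_larynx_frame(glottis_halfwidth=0)
        line = fit_midline(np.array([[128.0, 0.0], [128.0, 2.0]]))
        assert perpendicular_gap_distance(fr, line, np.array([128.0, 100.0])) == 0.0

    def test_ellipse_center_chord(self):
        fr = elliptical_glottis_frame(a=40.0, b=10.0)
        line = fit_midline(np.array([[128.0, 0.0], [128.0, 2.0]]))
        d = perpendicular_gap_distance(fr, line, np.array([128.0, 128.0]))
        assert d == pytest.approx(20.0, abs=1.0)

    def test_ellipse_off_center_chord(self):
        # anchor at 10% from the rear of the glottis segment = 0.8a above
        # center; the analytic chord is 2 b sqrt(1 - 0.8^2) = 12
        fr = elliptical_glottis_frame(a=40.0, b=10.0)
        line = fit_midline(np.array([[128.0, 0.0], [128.0, 2.0]]))
        d = perpendicular_gap_distance(fr, line, np.array([128.0, 128.0 + 0.8 * 40]))
        assert d == pytest.approx(12.0, abs=1.0)

    def test_monotone_under_glottis_enlargement(self, rng):
        line = fit_midline(np.array([[128.0, 0.0], [128.0, 2.0]]))
        anchor = np.array([128.0, 100.0])
        for _ in range(10):
            gh = rng.integers(1, 6)
            fr = vertical_larynx_frame(glottis_halfwidth=int(gh))
            d1 = perpendicular_gap_distance(fr, line, anchor)
            big = vertical_larynx_frame(glottis_halfwidth=int(gh) + rng.integers(1, 5))
            d2 = perpendicular_gap_distance(big, line, anchor)
            assert d2 >= d1


# ---------------------------------------------------------------------------
# whole-sequence measurement


class TestMeasureSequence:
    def test_static_closed_sequence_all_zero(self):
        fr = [
            vertical_larynx_frame(glottis_halfwidth=0)
            for _ in range(3)
        ]
        # one barely-open frame so a reference exists
        open_fr = vertical_larynx_frame(glottis_halfwidth=2, glottis_y=(50, 150))
        frames = fr[:2] + [open_fr] + fr[2:]
        for k, f in enumerate(frames):
            f.frame_index = k
        seq = MaskSequence(frames)
        table = measure_sequence(seq, [0.5])
        closed = table[table.frame_index != 2]
        assert (closed.distance_px == 0).all()
        assert (closed.relative_glottal_area == 0).all()
        assert not table.flagged.any()

    def test_constant_rear_gap_recovered_every_frame(self):
        params = PhonationParams(rear_gap_halfwidth=2.0)
        seq = generate_sequence(params)
        table = measure_sequence(seq, [0.10])
        assert np.allclose(table.distance_px, 4.0, atol=1.5)

    def test_rotation_changes_distances_by_at_most_pixelation(self):
        base = PhonationParams(rear_gap_halfwidth=2.0, seed=7)
        rot = PhonationParams(rear_gap_halfwidth=2.0, rotation_deg=25.0, seed=7)
        t0 = measure_sequence(generate_sequence(base), [0.10, 0.50])
        t1 = measure_sequence(generate_sequence(rot), [0.10, 0.50])
        diff = np.abs(t0.distance_px.to_numpy() - t1.distance_px.to_numpy())
        assert np.nanmax(diff) <= 1.5

    def test_row_count_and_flagging_contract(self):
        params = PhonationParams(n_frames=10)
        seq = generate_sequence(params)
        table = measure_sequence(seq, [0.1, 0.5])
        assert len(table) == 10 * 2
        assert set(table.fraction.unique()) == {0.1, 0.5}
        assert (table.groupby("fraction").frame_index.count() == 10).all()

    def test_empty_fractions_rejected(self):
        seq = generate_sequence(PhonationParams(n_frames=2))
        with pytest.raises(ValueError):
            measure_sequence(seq, [])


# ---------------------------------------------------------------------------
# invariance properties


class TestInvariances:
    @staticmethod
    def _shift_sequence(seq, dx, dy):
        shifted = []
        for fr in seq.frames:
            lab = np.roll(np.roll(fr.labels, dy, axis=0), dx, axis=1)
            shifted.append(LabeledFrame(lab, frame_index=fr.frame_index))
        return MaskSequence(shifted, fps=seq.fps)

    def test_translation_invariance(self):
        params = PhonationParams(
            rear_gap_halfwidth=2.0, boundary_jitter_px=0.4, n_frames=20, seed=11
        )
        seq = generate_sequence(params)
        t0 = measure_sequence(seq, [0.1, 0.5])
        t1 = measure_sequence(self._shift_sequence(seq, 17, -23), [0.1, 0.5])
        diff = np.abs(t0.distance_px.to_numpy() - t1.distance_px.to_numpy())
        assert np.nanmax(diff) <= 0.25

    def test_zoom_scales_distances_and_preserves_ratio(self):
        from glottalgap.geometry import (
            compute_anchor_ratio,
            extract_contact_points,
            find_collision_points,
            fit_midline,
        )

        s = 1.5
        base = PhonationParams(rear_gap_halfwidth=2.0, n_frames=20, seed=3)
        zoom = PhonationParams(
            rear_gap_halfwidth=2.0 * s,
            glottis_half_length=60.0 * s,
            max_opening_halfwidth=12.0 * s,
            fold_width=40.0 * s,
            fold_axis_margin=10.0 * s,
            n_frames=20,
            seed=3,
        )
        seq0, seq1 = generate_sequence(base), generate_sequence(zoom)
        t0 = measure_sequence(seq0, [0.1])
        t1 = measure_sequence(seq1, [0.1])
        d0 = t0.distance_px.to_numpy()
        d1 = t1.distance_px.to_numpy()
        assert np.nanmax(np.abs(d1 - s * d0)) <= 1.5

        def stored_ratio(seq):
            ref = seq.frames[0]
            idx = max(
                range(len(seq.frames)),
                key=lambda k: compute_areas(seq.frames[k]).glottis_px,
            )
            ref = seq.frames[idx]
            pts, src = extract_contact_points(ref)
            line = fit_midline(pts, source=src)
            cs = find_collision_points(line, ref)
            return compute_anchor_ratio(cs, 0.1).stored_ratio

        assert abs(stored_ratio(seq0) - stored_ratio(seq1)) <= 0.02
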