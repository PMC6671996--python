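"""Subspace sampling, surface-area estimation and condition comparison."""

import numpy as np
import pytest

import hpacirc as h
from hpacirc.errors import DegenerateGeometry, EmptySubspaceWarning
from hpacirc.subspace import SamplingBox, surface_area


class TestSamplingBox:
    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            SamplingBox(K_p1=(0.5, 0.1))
        with pytest.raises(ValueError):
            SamplingBox(k_p3=(-1.0, 1.0))

    def test_contains(self):
        box = SamplingBox()
        assert box.contains([0.5, 1.0, 0.8])
        assert not box.contains([5.0, 1.0, 0.8])


class TestSampleSubspace:
    def test_identical_seed_is_bit_identical(self, params, schedule, target, conditions):
        kw = dict(n_samples=128, seed=42, schedule=schedule)
        a = h.sample_subspace(conditions[0], target, params, **kw)
        b = h.sample_subspace(conditions[0], target, params, **kw)
        assert np.array_equal(a.triples, b.triples)
        assert a.table.equals(b.table)

    def test_empty_draw_warns(self, params, schedule, target, conditions):
        box = SamplingBox(K_p1=(3.0, 4.0), K_p2=(0.01, 0.02), k_p3=(8.0, 9.0))
        with pytest.warns(EmptySubspaceWarning):
            sub = h.sample_subspace(
                conditions[0], target, params, schedule=schedule,
                box=box, n_samples=8, seed=0,
            )
        assert len(sub) == 0
        assert len(sub.table) == 8

    def test_tight_box_around_generator_is_accepted(
        self, params, schedule, target, conditions
    ):
        """Self-consistency: sampling a tight box around the generating
        triple against its own zero-noise target accepts nearly everything."""
        g = np.array([params.K_p1, params.K_p2, params.k_p3])
        box = SamplingBox(
            K_p1=(g[0] * 0.99, g[0] * 1.01),
            K_p2=(g[1] * 0.99, g[1] * 1.01),
            k_p3=(g[2] * 0.99, g[2] * 1.01),
        )
        sub = h.sample_subspace(
            conditions[0], target, params, schedule=schedule,
            box=box, n_samples=16, seed=1,
        )
        assert len(sub) >= 15  # acceptance fraction -> 1 as the box shrinks

    def test_shrinking_sd_nests_the_accepted_set(
        self, params, schedule, conditions, target
    ):
        """Halving the acceptance SDs can only remove accepted triples
        (monotone nesting), and the set diameter cannot grow."""
        t = target
        tighter = h.CalibrationTarget(
            target=t.target,
            sd_mesor=t.sd_mesor / 2,
            sd_amplitude=t.sd_amplitude / 2,
            sd_acrophase=t.sd_acrophase / 2,
        )
        kw = dict(n_samples=512, seed=3, schedule=schedule)
        wide = h.sample_subspace(conditions[0], t, params, **kw)
        narrow = h.sample_subspace(conditions[0], tighter, params, **kw)
        wide_set = {tuple(x) for x in wide.triples}
        narrow_set = {tuple(x) for x in narrow.triples}
        assert narrow_set <= wide_set

        def diameter(s):
            if len(s) < 2:
                return 0.0
            pts = np.log(np.array(sorted(s)))
            return max(
                np.linalg.norm(a - b) for a in pts for b in pts
            )

        assert diameter(narrow_set) <= diameter(wide_set) + 1e-12


class TestSurfaceArea:
    def test_planar_unit_right_triangle(self):
        pts = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        assert surface_area(pts, alpha=10.0) == pytest.approx(0.5)

    def test_tilted_plane_triangle(self):
        """k_p3 plane tilted 45 degrees along K_p1 scales the area by sqrt(2)."""
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        assert surface_area(pts, alpha=10.0) == pytest.approx(0.5 * np.sqrt(2.0))

    def test_analytic_patch_matches_quadrature(self):
        """Dense samples of z = f(x, y) converge to the surface integral
        of sqrt(1 + fx^2 + fy^2) computed by high-resolution quadrature."""
        f = lambda x, y: 0.3 * np.sin(2 * x) + 0.2 * y**2

        # quadrature reference on [0,1]^2
        gx, gy = np.meshgrid(*(np.linspace(0, 1, 801),) * 2, indexing="ij")
        fx = 0.6 * np.cos(2 * gx)
        fy = 0.4 * gy
        integrand = np.sqrt(1 + fx**2 + fy**2)
        ref = np.trapezoid(
            np.trapezoid(integrand, gx[:, 0], axis=0), gy[0], axis=0
        )

        m = 40
        xs, ys = np.meshgrid(*(np.linspace(0, 1, m),) * 2, indexing="ij")
        pts = np.column_stack([xs.ravel(), ys.ravel(), f(xs, ys).ravel()])
        est = surface_area(pts, alpha=10.0)
        assert est == pytest.approx(ref, rel=0.02)

    def test_density_doubling_changes_area_less_than_two_percent(self):
        f = lambda x, y: 0.3 * np.sin(2 * x) + 0.2 * y**2
        vals = {}
        for m in (30, 60):
            xs, ys = np.meshgrid(*(np.linspace(0, 1, m),) * 2, indexing="ij")
            pts = np.column_stack([xs.ravel(), ys.ravel(), f(xs, ys).ravel()])
            vals[m] = surface_area(pts, alpha=10.0)
        assert abs(vals[60] - vals[30]) / vals[30] < 0.02

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateGeometry):
            surface_area(np.array([[0.0, 0.0, 1.0], [1.0, 1.0, 1.0]]))
        collinear = np.array([[0.0, 0.0, 1.0], [1.0, 1.0, 2.0], [2.0, 2.0, 3.0]])
        with pytest.raises(DegenerateGeometry):
            surface_area(collinear)

    def test_alpha_shape_excludes_far_apart_components(self):
        """Two clusters far apart must not be bridged by hull triangles
        when the alpha radius is set from nearest-neighbor spacing."""
        a = np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [0.1, 0.1]])
        b = a + np.array([10.0, 0.0])
        pts2 = np.vstack([a, b])
        pts = np.column_stack([pts2, np.zeros(len(pts2))])
        area = surface_area(pts)  # automatic alpha
        assert area == pytest.approx(2 * 0.01, rel=1e-6)


class TestCompareConditions:
    def _fake_sub(self, label, triples, conditions, target):
        cond = {c.label: c for c in conditions}[label]
        return h.AcceptedSubspace(
            condition=cond,
            triples=np.asarray(triples, dtype=float),
            fits=[],
            seed=0,
            box=SamplingBox(),
            target=target,
        )

    def test_identical_subspaces_have_zero_deltas(self, conditions, target):
        tri = np.array(
            [[0.5, 1.0, 0.7], [0.6, 1.1, 0.8], [0.55, 0.9, 0.75], [0.7, 1.3, 0.72]]
        )
        subs = [
            self._fake_sub(lab, tri, conditions, target)
            for lab in ("nominal", "intermediate", "high")
        ]
        out = h.compare_conditions(*subs)
        a = out["areas"]
        assert a["nominal"] == pytest.approx(a["high"])
        assert not out["trends"]["mean_K_p1_decreases"]
        assert not out["trends"]["area_decreases"]

    def test_constructed_means_are_reported_exactly(self, conditions, target):
        tri_nom = np.array([[0.8, 1.0, 0.6], [0.9, 1.2, 0.7], [1.0, 0.8, 0.8]])
        tri_int = tri_nom * np.array([0.5, 1.1, 1.2])
        tri_high = tri_nom * np.array([0.25, 1.2, 1.5])
        out = h.compare_conditions(
            self._fake_sub("nominal", tri_nom, conditions, target),
            self._fake_sub("intermediate", tri_int, conditions, target),
            self._fake_sub("high", tri_high, conditions, target),
        )
        assert out["conditions"]["nominal"]["means"]["K_p1"] == pytest.approx(0.9)
        assert out["conditions"]["high"]["means"]["k_p3"] == pytest.approx(
            tri_high[:, 2].mean()
        )
        assert out["trends"]["mean_K_p1_decreases"]
        assert out["trends"]["mean_k_p3_increases"]

    def test_empty_condition_propagates(self, conditions, target):
        empty = self._fake_sub("nominal", np.empty((0, 3)), conditions, target)
        full = self._fake_sub(
            "intermediate", [[0.5, 1, 0.7], [0.6, 1, 0.8], [0.7, 1, 0.9]], conditions, target
        )
        full_h = self._fake_sub(
            "high", [[0.5, 1, 0.7], [0.6, 1, 0.8], [0.7, 1, 0.9]], conditions, target
        )
        with pytest.raises(ValueError):
            h.compare_conditions(empty, full, full_h)
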