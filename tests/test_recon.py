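import numpy as np
import pytest

from ossimetry import forward_model as fm
from ossimetry import phantom as ph
from ossimetry import recon as rc
from ossimetry.errors import FlatFieldError, GeometryError, StitchError
from .conftest import sphere_mask


def make_ps(proj, angular_range=360, flats=None, darks=None, **meta):
    n, rows, cols = proj.shape
    g = fm.Geometry(n_projections=n, angular_range_deg=angular_range)
    return fm.ProjectionSet(
        projections=proj, angles_deg=g.angles_deg(),
        flats=np.ones((1, rows, cols)) if flats is None else flats,
        darks=np.zeros((1, rows, cols)) if darks is None else darks,
        geometry=g, meta=meta,
    )


def disk_sinogram(ncols, nang, mu, r, angular_range=360, pixel_um=2.0):
    c = (ncols - 1) / 2.0
    s = np.arange(ncols) - c
    row = np.where(np.abs(s) < r,
                   2 * mu * np.sqrt(np.clip(r * r - s * s, 0, None)), 0.0)
    row = row * pixel_um * 1e-3  # optical depth at this sampling
    proj = np.tile(row, (nang, 1))[:, None, :]
    ps = make_ps(proj, angular_range)
    ps.is_log = True
    return ps


def partial_volume_disk(ncols, r, ss=8):
    c = (ncols - 1) / 2.0
    yy, xx = np.mgrid[: ncols * ss, : ncols * ss]
    big = ((yy + 0.5) / ss - 0.5 - c) ** 2 + ((xx + 0.5) / ss - 0.5 - c) ** 2 < r**2
    return big.reshape(ncols, ss, ncols, ss).mean(axis=(1, 3))


class TestFlatCorrect:
    def test_flat_input_gives_ones(self):
        proj = np.full((3, 4, 5), 7.0)
        ps = make_ps(proj, flats=np.full((2, 4, 5), 7.0),
                     darks=np.zeros((2, 4, 5)))
        out = rc.flat_correct(ps)
        assert np.allclose(out.projections, 1.0)

    def test_dark_input_clips_at_epsilon(self):
        proj = np.full((2, 4, 4), 3.0)
        ps = make_ps(proj, flats=np.full((1, 4, 4), 10.0),
                     darks=np.full((1, 4, 4), 3.0))
        out = rc.flat_correct(ps, epsilon=1e-6)
        assert np.allclose(out.projections, 1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        proj = rng.uniform(1, 2, (2, 6, 6))
        flats = rng.uniform(2, 3, (1, 6, 6))
        a = rc.flat_correct(make_ps(proj, flats=flats.copy(),
                                    darks=np.zeros((1, 6, 6))))
        b = rc.flat_correct(make_ps(5 * proj, flats=5 * flats,
                                    darks=np.zeros((1, 6, 6))))
        assert np.allclose(a.projections, b.projections)

    def test_flat_below_dark_raises(self):
        proj = np.ones((1, 4, 4))
        flats = np.ones((1, 4, 4))
        darks = np.ones((1, 4, 4)) * 2
        with pytest.raises(FlatFieldError, match="16 pixel"):
            rc.flat_correct(make_ps(proj, flats=flats, darks=darks))


@pytest.fixture(scope="module")
def two_sphere_full():
    # asymmetric object: two spheres off the rotation axis
    z, y, x = np.ogrid[:48, :64, :64]
    m1 = (z - 24) ** 2 + (y - 28) ** 2 + (x - 37) ** 2 <= 10.0**2
    m2 = (z - 20) ** 2 + (y - 41) ** 2 + (x - 24) ** 2 <= 6.0**2
    mask = m1 | m2
    p = ph.Phantom(volume=mask, voxel_size_um=2.0,
                   labels=mask.astype(np.uint8), truth={}, seed=0)
    g = fm.Geometry(n_projections=40, angular_range_deg=360)
    return rc.flat_correct(fm.project(p, 0.2, 0.0, g))


class TestStitch360:
    @pytest.mark.parametrize("offset", [4, 10])
    def test_round_trip_matches_direct(self, two_sphere_full, offset):
        split = fm.split_extended_fov(two_sphere_full, offset)
        stitched = rc.stitch_360(split)
        direct = two_sphere_full.projections[:20]
        rmse = np.sqrt(np.mean((stitched.projections - direct) ** 2))
        scale = np.sqrt(np.mean(direct**2))
        assert rmse / scale < 0.01

    def test_shape_contract(self, two_sphere_full):
        split = fm.split_extended_fov(two_sphere_full, 6)
        stitched = rc.stitch_360(split)
        w_in = split.projections.shape[2]
        overlap = 12
        assert stitched.projections.shape[2] == 2 * (w_in - overlap) + overlap
        assert stitched.n_angles == split.n_angles // 2
        assert stitched.geometry.angular_range_deg == 180

    def test_overlap_blend_convexity(self):
        # rows differ in the overlap: blend must lie between contributions
        n, rows, cols = 2, 1, 8
        proj = np.zeros((n, rows, cols))
        proj[0] = 1.0
        proj[1] = 3.0
        g = fm.Geometry(n_projections=2, angular_range_deg=360, fov_offset_px=2)
        ps = fm.ProjectionSet(projections=proj, angles_deg=[0.0, 180.0],
                              flats=np.ones((1, rows, cols)),
                              darks=np.zeros((1, rows, cols)), geometry=g)
        out = rc.stitch_360(ps)
        band = out.projections[0, 0, 4:8]  # the 4 blended columns
        assert np.all(band > 1.0) and np.all(band < 3.0)
        assert np.all(np.diff(band) < 0)  # ramp from mirrored 3.0 to 1.0

    def test_errors(self, two_sphere_full):
        with pytest.raises(StitchError, match="360"):
            rc.stitch_360(make_ps(np.ones((4, 2, 8)), angular_range=180))
        bad = two_sphere_full.replace(
            angles_deg=two_sphere_full.angles_deg * 1.01)
        with pytest.raises(StitchError, match="partner"):
            rc.stitch_360(bad)


class TestPhaseRetrieve:
    def test_zero_delta_beta_is_neg_log(self):
        rng = np.random.default_rng(1)
        proj = rng.uniform(0.5, 1.5, (3, 8, 8))
        out = rc.phase_retrieve(make_ps(proj), 0.0)
        assert np.array_equal(out.projections, -np.log(proj))
        assert out.is_log

    def test_inverse_pair_with_propagation(self, sphere50):
        g = fm.Geometry(n_projections=10, angular_range_deg=360)
        ps = rc.flat_correct(fm.project(sphere50, 0.05, 0.0, g))
        prop = fm.propagate(ps, 300.0)
        ret = rc.phase_retrieve(prop, 300.0)
        expected = -np.log(ps.projections)
        err = np.abs(ret.projections - expected).max()
        assert err / np.abs(expected).max() < 1e-8

    def test_low_pass_on_white_noise(self):
        rng = np.random.default_rng(5)
        proj = rng.uniform(0.8, 1.2, (2, 64, 64))
        ps = make_ps(proj)
        out = rc.phase_retrieve(ps, 300.0)
        assert out.projections.var() < (-np.log(proj)).var()

    def test_nonpositive_input_raises(self):
        proj = np.ones((1, 4, 4))
        proj[0, 0, 0] = 0.0
        ps = make_ps(proj)
        with pytest.raises(FlatFieldError, match="flat_correct"):
            rc.phase_retrieve(ps, 300.0)


class TestFBP:
    def test_zero_sinogram(self):
        ps = make_ps(np.zeros((8, 2, 16)))
        ps.is_log = True
        vol = rc.fbp_reconstruct(ps)
        assert np.allclose(vol.volume, 0.0)
        assert vol.voxel_size_um == ps.geometry.pixel_size_um

    def test_disk_oracle(self):
        mu, r, ncols = 0.5, 40.0, 128
        ps = disk_sinogram(ncols, 360, mu, r)
        sl = rc.fbp_reconstruct(ps).volume[0]
        c = (ncols - 1) / 2.0
        yy, xx = np.mgrid[:ncols, :ncols]
        interior = (yy - c) ** 2 + (xx - c) ** 2 < (0.8 * r) ** 2
        assert sl[interior].mean() == pytest.approx(mu, rel=0.02)
        ref = mu * partial_volume_disk(ncols, r)
        assert np.sqrt(np.mean((sl - ref) ** 2)) < 0.05 * mu

    def test_angle_convergence_monotone(self):
        mu, r, ncols = 0.5, 40.0, 128
        ref = mu * partial_volume_disk(ncols, r)
        errs = []
        for nang in (45, 90, 180, 360):
            ps = disk_sinogram(ncols, nang, mu, r, angular_range=180)
            sl = rc.fbp_reconstruct(ps).volume[0]
            errs.append(np.sqrt(np.mean((sl - ref) ** 2)))
        assert errs[0] > errs[1] > errs[2] > errs[3]

    def test_linearity(self):
        ps = disk_sinogram(64, 30, 0.3, 20.0)
        v1 = rc.fbp_reconstruct(ps).volume
        ps3 = ps.replace(projections=3 * ps.projections)
        v3 = rc.fbp_reconstruct(ps3).volume
        assert np.allclose(v3, 3 * v1, rtol=1e-10, atol=1e-12)

    def test_too_few_angles(self):
        g = fm.Geometry(n_projections=1, angular_range_deg=180)
        ps = fm.ProjectionSet(projections=np.zeros((1, 2, 8)),
                              angles_deg=[0.0], flats=np.ones((1, 2, 8)),
                              darks=np.zeros((1, 2, 8)), geometry=g,
                              is_log=True)
        with pytest.raises(GeometryError, match="2 angles"):
            rc.fbp_reconstruct(ps)

    def test_requires_log_data(self):
        ps = make_ps(np.ones((4, 2, 8)))
        with pytest.raises(GeometryError, match="line integrals"):
            rc.fbp_reconstruct(ps)


@pytest.mark.slow
class TestFullChain:
    def test_chain_fidelity_128(self):
        p = ph.make_ossicle("sphere", {"radius_um": 70.0}, 2.0,
                            cavity_fraction=0.2, grid_shape=(128, 128, 128))
        g = fm.Geometry(n_projections=160, angular_range_deg=360)
        ps = fm.project(p, 0.15, 0.01, g)
        ps = fm.propagate(ps, 60.0)
        ps = fm.add_noise(ps, 1e5, seed=2)
        ps = rc.flat_correct(ps)
        ps = rc.phase_retrieve(ps, 60.0)
        vol = rc.fbp_reconstruct(ps)
        truth = np.where(p.volume, 0.15, 0.01)
        corr = np.corrcoef(vol.volume.ravel(), truth.ravel())[0, 1]
        assert corr > 0.95
        assert np.isfinite(vol.volume).all()
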