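"""Analytic fixture suite: fast closed-form checks of the whole stack.

Each fixture compares a computed quantity with a closed form (cylinder
areas, Poiseuille/Couette stresses, Willmore energy, finite-difference force
oracles, hand quadratures) and reports a machine-readable pass/fail record.
"""

from __future__ import annotations

import numpy as np


def _record(name: str, value: float, expected: float, tol: float,
            relative: bool = True) -> dict:
    err = abs(value - expected) / (abs(expected) if relative and expected
                                   else 1.0)
    return {"name": name, "value": float(value), "expected": float(expected),
            "tolerance": tol, "error": float(err), "passed": bool(err <= tol)}


def fixture_suite(viscosity: float = 0.001, seed: int = 0) -> list[dict]:
    """Run every analytic fixture; failures are report entries, not errors.

    ``viscosity`` (Pa s) feeds the Poiseuille/Couette WSS fixtures — the
    fault-injection hook: a perturbed value fails those fixtures by the
    matching factor.
    """
    from .geometry import make_tube
    from .membrane import (bending_energy, bending_forces, make_biconcave,
                           skalak_energy, skalak_forces)
    from .wss import (CallableSampler, local_frames, roi_average, vessel_std,
                      wall_shear_stress, wssg)
    from .wss.fields import WSSField

    rep: list[dict] = []
    rng = np.random.default_rng(seed)

    # --- membrane geometry -------------------------------------------------
    cell = make_biconcave(7.8, 4)
    rep.append(_record("biconcave_area_um2", cell.reference_area, 134.1, 0.01))
    rep.append(_record("biconcave_volume_um3", cell.reference_volume, 94.1, 0.01))
    sph = make_biconcave(7.8, 4, sphere_path=True)
    rep.append(_record("sphere_area", sph.reference_area, 4 * np.pi, 0.005))
    rep.append(_record("sphere_volume", sph.reference_volume, 4 * np.pi / 3, 0.005))
    rep.append(_record("willmore_energy_8pikb",
                       bending_energy(sph, sph.vertices) / sph.k_b,
                       8 * np.pi, 0.05))

    # --- force = -grad(energy) oracles ------------------------------------
    cell3 = make_biconcave(7.8, 3)
    x = cell3.vertices * 1.03 + 0.02 * rng.normal(size=cell3.vertices.shape)
    eps = 1e-7
    for label, force_fn, energy_fn in (
            ("skalak", lambda: skalak_forces(cell3, x).elastic, skalak_energy),
            ("bending", lambda: bending_forces(cell3, x).bending, bending_energy)):
        f = force_fn()
        worst = 0.0
        for v, ax in ((0, 0), (50, 1), (200, 2)):
            xp = x.copy(); xp[v, ax] += eps
            xm = x.copy(); xm[v, ax] -= eps
            num = -(energy_fn(cell3, xp) - energy_fn(cell3, xm)) / (2 * eps * 1e-6)
            worst = max(worst, abs(num - f[v, ax]) / (abs(f[v, ax]) + 1e-30))
        rep.append(_record(f"{label}_force_fd_relerr", worst, 0.0, 1e-5,
                           relative=False))

    # --- wall stress fixtures ---------------------------------------------
    mesh, _ = make_tube(10.0, 24.0, None, 0.5)
    lat = mesh.roi_labels != "cap"

    G, R, mu_true = 0.1e6, 5e-6, 0.001  # Pa/m, m, Pa s

    def pois(pts):
        pts = np.atleast_2d(pts)
        r2 = (pts[:, 1] ** 2 + pts[:, 2] ** 2) * 1e-12
        u = np.zeros((len(pts), 3))
        u[:, 0] = G * np.maximum(R**2 - r2, 0.0) / (4 * mu_true)
        return u

    s = CallableSampler(pois)
    fr = local_frames(mesh, s)
    w = wall_shear_stress(s, mesh, fr, 0.3, viscosity)
    rep.append(_record("poiseuille_wss_dyncm2", w.t_s[lat].mean(),
                       G * R / 2 * 10.0, 0.05))

    shear = 100.0  # 1/s planar Couette

    def couette(pts):
        pts = np.atleast_2d(pts)
        u = np.zeros((len(pts), 3))
        u[:, 0] = shear * (pts[:, 1] + 5.0) * 1e-6
        return u

    sc = CallableSampler(couette)
    # flat plate at y = -5, fluid above: exact plasma WSS for the linear
    # profile is mu_pl * 100/s = 0.1 Pa = 1 dyne/cm² at every vertex
    plate = _plate_mesh(y0=-5.0)
    frc = local_frames(plate, sc)
    wc = wall_shear_stress(sc, plate, frc, 0.3, viscosity)
    rep.append(_record("couette_wss_dyncm2", wc.t_s.mean(), 1.0, 1e-10))
    rep.append(_record("couette_wss_spread", np.abs(wc.t_s - wc.t_s.mean()).max(),
                       0.0, 1e-10, relative=False))

    uni = CallableSampler(lambda p: np.tile([1e-3, 0, 0], (len(np.atleast_2d(p)), 1)))
    wu = wall_shear_stress(uni, mesh, local_frames(mesh, uni), 0.3, viscosity)
    rep.append(_record("uniform_field_wss", np.abs(wu.t_s[lat]).max(), 0.0,
                       1e-12, relative=False))

    # --- WSSG closed forms -------------------------------------------------
    k_lin = 3.0
    tau_lin = WSSField(t_s=k_lin * mesh.vertices[:, 0],
                       t_theta=np.zeros(mesh.n_vertices),
                       t_r_visc=np.zeros(mesh.n_vertices))
    g = wssg(tau_lin, mesh, fr, 0.3)
    ok = lat & g.valid
    rep.append(_record("wssg_linear_grad_s", np.abs(g.grad_s[ok] - k_lin).max(),
                       0.0, 1e-6, relative=False))
    th = np.arctan2(mesh.vertices[:, 2], mesh.vertices[:, 1])
    tau_sin = WSSField(t_s=np.sin(th), t_theta=np.zeros(mesh.n_vertices),
                       t_r_visc=np.zeros(mesh.n_vertices))
    g2 = wssg(tau_sin, mesh, fr, 0.3)
    ok2 = lat & g2.valid
    rep.append(_record("wssg_sin_theta_maxerr",
                       np.abs(g2.grad_theta[ok2] - np.cos(th[ok2]) / 5.0).max(),
                       0.0, (0.3 / 5.0) ** 2 + 1e-6, relative=False))

    # --- statistics closed forms (hand-quadrature oracles) -----------------
    from .geometry.wallmesh import WallMesh
    from .wss import temporal_rms

    toy = _two_patch_mesh()
    tau_patch = np.array([2.0, 2.0, 2.0, 6.0, 6.0, 6.0])
    rep.append(_record("roi_average_two_patch",
                       roi_average(tau_patch, toy, toy.roi_labels == "vessel:0"),
                       5.0, 1e-12))
    mask2 = np.array([True, True, False, False, False, False])
    rep.append(_record("vessel_std_pair",
                       vessel_std(np.array([1.0, 3.0, 0, 0, 0, 0]), toy, mask2),
                       np.sqrt(2) / 2, 1e-12))
    t = np.arange(1024) / 1024.0
    series = [np.full(6, 2.0 + 0.5 * np.sin(2 * np.pi * 4 * tk)) for tk in t]
    rms = temporal_rms(series, toy, toy.roi_labels == "vessel:0")
    rep.append(_record("sinusoid_abs_rms", rms.absolute, 0.5 / np.sqrt(2), 1e-5))
    rep.append(_record("sinusoid_rel_rms", rms.relative,
                       0.5 / (np.sqrt(2) * 2.0), 1e-5))
    from .netstats import phase_separation_points

    fit = phase_separation_points([-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0])
    rep.append(_record("ols_slope_exact_line", fit.slope, 2.0, 1e-12))
    return rep


def _plate_mesh(y0: float = -5.0, n: int = 8):
    """Flat wall plate at y = y0 with fluid above (outward normal -y)."""
    from .geometry.wallmesh import WallMesh

    xs, zs = np.meshgrid(np.arange(n, dtype=float),
                         np.arange(n, dtype=float), indexing="ij")
    verts = np.column_stack([xs.ravel(), np.full(n * n, y0), zs.ravel()])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            tris += [[a, a + n, a + 1], [a + 1, a + n, a + n + 1]]
    normals = np.tile([0.0, -1.0, 0.0], (n * n, 1))
    labels = np.array(["vessel:0"] * (n * n), dtype=object)
    return WallMesh(verts, np.asarray(tris), normals, labels)


def _two_patch_mesh():
    """Two disjoint right triangles of areas 1 and 3 µm² (one ROI)."""
    from .geometry.wallmesh import WallMesh

    verts = np.array([
        [0, 0, 0], [2, 0, 0], [0, 1, 0],          # area 1
        [10, 0, 0], [12, 0, 0], [10, 3, 0],        # area 3
    ], dtype=float)
    tris = np.array([[0, 1, 2], [3, 4, 5]])
    normals = np.tile([0.0, 0.0, 1.0], (6, 1))
    labels = np.array(["vessel:0"] * 6, dtype=object)
    return WallMesh(verts, tris, normals, labels)


def report_passed(report: list[dict]) -> bool:
    return all(r["passed"] for r in report)
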