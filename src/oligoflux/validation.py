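"""Round-trip validation protocols for the whole pipeline.

Each function simulates inputs at the study's documented conditions with the
synthetic generators, runs the corresponding analysis stage, and measures its
accuracy against an independent numerical oracle (finite differences,
quadrature, grid search, planted ground truth) or against the generating
truth. The returned dictionaries carry plain floats so results can be
serialized directly. All randomness derives from the single ``seed``
argument.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import binding as bnd
from . import flux as flx
from . import imaging as img
from . import kinetics as kin
from . import reporting as rep
from . import synthetic as syn

__all__ = [
    "flux_closed_form_agreement",
    "amplification_fd_agreement",
    "logistic_recovery",
    "elongation_recovery",
    "inhibitor_ordering",
    "control_normalization_identity",
    "binding_recovery",
    "spot_detection_fidelity",
    "morphometrics_fidelity",
    "statistical_calibration",
]

R_PLUS = 0.002  # effective elongation rate used throughout (per minute)


def _make_fit(a: float, kappa: float, c: float = 0.3) -> kin.LogisticFit:
    return kin.LogisticFit(
        a=a,
        kappa=kappa,
        c=c,
        lambda_=kin.primary_nucleation_combination(a, kappa),
        rss=0.0,
        r_squared=1.0,
        t_half=kin._half_time_root(a, kappa, c),
        converged=True,
    )


def _draw_params(rng: np.random.Generator, n: int):
    """(a, kappa) draws in the normalized low-seed regime: M(0) <= 5%,
    half-times of roughly 1-60 hours."""
    a = np.exp(rng.uniform(np.log(20.0), np.log(1000.0), size=n))
    kappa = np.exp(rng.uniform(np.log(0.002), np.log(0.05), size=n))
    return a, kappa


# ---------------------------------------------------------------------------
# kinetics / flux closed forms vs numerical oracles
# ---------------------------------------------------------------------------


def flux_closed_form_agreement(seed: int, n_draws: int = 100) -> dict:
    """Closed-form phi_Area/phi_Time/phi_Peak vs quadrature / grid search."""
    rng = np.random.default_rng(seed)
    a_s, k_s = _draw_params(rng, n_draws)
    area_err, time_steps, peak_err = [], [], []
    for a, k in zip(a_s, k_s):
        fit = _make_fit(a, k)
        prof = flx.compute_flux(fit, R_PLUS)  # grid [0, 5 t_half], dt = t_half/1000
        step = prof.t[1] - prof.t[0]
        quad = float(np.trapezoid(prof.phi, prof.t))
        area_err.append(abs(flx.flux_area(fit, R_PLUS) - quad) / quad)
        t_peak = flx.flux_peak_time(fit, R_PLUS)
        time_steps.append(abs(t_peak - prof.t[np.argmax(prof.phi)]) / step)
        # refine the grid to dt = 0.01 min around the coarse argmax
        t0 = prof.t[np.argmax(prof.phi)]
        fine = np.arange(max(0.0, t0 - 2 * step), t0 + 2 * step, 0.01)
        phi_max = float(flx.oligomer_flux(fine, a, k, fit.c, R_PLUS).max())
        peak_err.append(abs(flx.flux_peak_height(fit, R_PLUS) - phi_max) / phi_max)
    return {
        "n": n_draws,
        "area_max_rel_err": float(np.max(area_err)),
        "peak_time_max_grid_steps": float(np.max(time_steps)),
        "peak_height_max_rel_err": float(np.max(peak_err)),
    }


def amplification_fd_agreement(seed: int, n_draws: int = 100) -> dict:
    """Closed-form dP/dt at t_half vs finite differences of P(t)."""
    rng = np.random.default_rng(seed)
    a_s, k_s = _draw_params(rng, n_draws)
    errs = []
    for a, k in zip(a_s, k_s):
        th = kin._half_time_root(a, k, 0.3)
        h = th * 1e-5
        t = np.array([th - h, th + h])
        P = kin.fibril_number(t, a, k, 0.3, R_PLUS)
        fd = float((P[1] - P[0]) / (2 * h))
        closed = kin.amplification_at_half_time(a, k, 0.3, R_PLUS)
        errs.append(abs(closed - fd) / fd)
    return {"n": n_draws, "max_rel_err": float(np.max(errs))}


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


def logistic_recovery(seed: int, n_experiments: int = 50) -> dict:
    """Generalized-logistic kappa recovery from noisy 3-replicate experiments.

    Each experiment: three replicates at 2% normalized noise on a 0-2000 min
    grid, fitted jointly; plus one noiseless fit checked for exactness.
    """
    t = syn.default_time_grid(2000.0, 2.0)
    errs = []
    for i in range(n_experiments):
        truth = syn.KineticGroundTruth(
            a=50.0, kappa=0.02, noise_sd=0.02, n_replicates=3,
            seed=seed * 1000 + i * 7,
        )
        fit = kin.fit_logistic(syn.gen_tht_traces(truth, t))
        errs.append(abs(fit.kappa - truth.kappa) / truth.kappa)
    clean = kin.fit_logistic(
        syn.gen_tht_traces(
            syn.KineticGroundTruth(noise_sd=0.0, n_replicates=1, seed=seed), t
        )
    )
    return {
        "n": n_experiments,
        "kappa_median_rel_err": float(np.median(errs)),
        "noiseless_a_rel_err": abs(clean.a - 50.0) / 50.0,
        "noiseless_kappa_rel_err": abs(clean.kappa - 0.02) / 0.02,
    }


def elongation_recovery(seed: int, n_experiments: int = 50) -> dict:
    """Elongation-slope recovery: exact on noiseless data, and the median
    over noisy 3-replicate experiments (slope 0.002/min, noise 0.005)."""
    t = syn.default_time_grid(60.0, 1.0)
    exact = kin.fit_elongation(
        kin.ThTTrace(time=t, signal=0.002 * t, normalized=True)
    )
    slopes = []
    for i in range(n_experiments):
        reps = syn.gen_elongation_traces(
            slope=0.002, t_grid=t, noise_sd=0.005, n_replicates=3,
            seed=seed * 1000 + i * 11,
        )
        slopes.append(np.mean([kin.fit_elongation(r).slope for r in reps]))
    return {
        "n": n_experiments,
        "noiseless_rel_err": abs(exact.slope - 0.002) / 0.002,
        "median_slope_rel_err": abs(float(np.median(slopes)) - 0.002) / 0.002,
    }


# ---------------------------------------------------------------------------
# flux ordering and normalization identities
# ---------------------------------------------------------------------------


def inhibitor_ordering(seed: int, n_points: int = 12) -> dict:
    """A secondary-nucleation inhibitor (kappa below control) must lower
    phi_Peak and phi_Area and delay phi_Time, at every inhibition level."""
    rng = np.random.default_rng(seed)
    ctrl = flx.compute_flux(_make_fit(50.0, 0.02), R_PLUS)
    kappas = np.sort(rng.uniform(0.002, 0.019, size=n_points))
    ok = 0
    for k_i in kappas:
        rel = flx.normalize_metrics(
            {"control": [ctrl], "desab": [flx.compute_flux(_make_fit(50.0, k_i), R_PLUS)]}
        )["desab"]
        ok += (
            rel.phi_peak_rel[0] < 1.0
            and rel.phi_area_rel[0] < 1.0
            and rel.phi_time_rel[0] > 1.0
        )
    return {"n": n_points, "ordering_fraction": ok / n_points}


def control_normalization_identity(seed: int) -> dict:
    """All control-relative metrics must average exactly 1 on control data."""
    rng = np.random.default_rng(seed)
    fits = [_make_fit(a, k) for a, k in zip(*_draw_params(rng, 3))]
    profiles = {"control": [flx.compute_flux(f, R_PLUS) for f in fits]}
    rel = flx.normalize_metrics(profiles)["control"]
    el = kin.relative_elongation(
        {"control": [kin.ElongationFit(s, 0.0, 6, 1.0)
                     for s in rng.uniform(0.001, 0.003, 3)]}
    )["control"]
    amp = kin.relative_amplification(
        {"control": [kin.amplification_rate(f, R_PLUS) for f in fits]}
    )["control"]
    devs = [
        abs(np.mean(rel.phi_peak_rel) - 1.0),
        abs(np.mean(rel.phi_area_rel) - 1.0),
        abs(np.mean(rel.phi_time_rel) - 1.0),
        abs(np.mean(el) - 1.0),
        abs(np.mean(amp) - 1.0),
    ]
    return {"n": 5, "max_abs_deviation": float(np.max(devs))}


# ---------------------------------------------------------------------------
# binding
# ---------------------------------------------------------------------------


def binding_recovery(seed: int, n_experiments: int = 50) -> dict:
    """K_D recovery on the 16-point 1:1.75 dilution design.

    Truth K_D = 0.3 uM, B_Max = 10; noise 0.1 response units (1% of B_Max).
    """
    errs = []
    for i in range(n_experiments):
        curve = syn.gen_binding_curve(
            kd=0.3, bmax=10.0, top_conc=30.0, noise_sd=0.1,
            seed=seed * 1000 + i * 13,
        )
        errs.append(abs(bnd.fit_saturation(curve).kd - 0.3) / 0.3)
    clean = bnd.fit_saturation(
        syn.gen_binding_curve(kd=0.3, bmax=10.0, top_conc=30.0, noise_sd=0.0)
    )
    return {
        "n": n_experiments,
        "kd_median_rel_err": float(np.median(errs)),
        "noiseless_kd_rel_err": abs(clean.kd - 0.3) / 0.3,
    }


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------


def spot_detection_fidelity(
    seed: int, n_planted_fields: int = 3, n_blank_fields: int = 50
) -> dict:
    """Planted-truth recall/precision and blank-field false positives.

    Planted fields: 100 spots per 512x512 field, amplitude/read-noise = 10,
    50 frames averaged. Blanks: read noise only.
    """
    from scipy.spatial import cKDTree

    matched_tot = true_tot = det_tot = 0
    for i in range(n_planted_fields):
        s = seed * 100 + i
        pos = syn.random_spot_positions(100, (512, 512), seed=s)
        stack = syn.gen_tirf_stack(
            syn.SpotGroundTruth(
                positions=pos, amplitude=200.0, read_noise_sd=20.0,
                n_frames=50, seed=s,
            )
        )
        det = img.detect_spots(img.average_stack(stack)).coordinates()
        tree = cKDTree(det)
        used: set[int] = set()
        for p in pos:
            dist, idx = tree.query(p, k=min(4, len(det)))
            for d, j in zip(np.atleast_1d(dist), np.atleast_1d(idx)):
                if d <= 1.0 and j not in used:
                    used.add(int(j))
                    matched_tot += 1
                    break
        true_tot += len(pos)
        det_tot += len(det)
    blanks = []
    for i in range(n_blank_fields):
        stack = syn.gen_tirf_stack(
            syn.SpotGroundTruth(
                positions=np.empty((0, 2)), read_noise_sd=20.0, n_frames=50,
                seed=seed * 100 + 1000 + i,
            )
        )
        blanks.append(img.detect_spots(img.average_stack(stack)).count)
    return {
        "n": n_planted_fields * 100,
        "recall": matched_tot / true_tot,
        "precision": matched_tot / det_tot if det_tot else 0.0,
        "blank_fp_max": float(np.max(blanks)),
        "blank_fp_mean": float(np.mean(blanks)),
    }


def morphometrics_fidelity(
    seed: int, n_repeats: int = 31, disc_n_localizations: int = 2000
) -> dict:
    """Generator round trips for rod length, disc shape and rotation
    invariance (medians over independent aggregates)."""
    rod_err, blur_err, disc_ecc, disc_circ = [], [], [], []
    for i in range(n_repeats):
        s = seed * 100 + i
        rod = img.shape_metrics(
            syn.gen_localizations(
                syn.ShapeGroundTruth(kind="rod", length_nm=400.0,
                                     n_localizations=500, precision_nm=0.0,
                                     seed=s)
            )
        )
        rod_err.append(abs(rod.length_nm - 400.0) / 400.0)
        blur = img.shape_metrics(
            syn.gen_localizations(
                syn.ShapeGroundTruth(kind="rod", length_nm=200.0,
                                     n_localizations=500, precision_nm=20.0,
                                     seed=s)
            )
        )
        blur_err.append(abs(blur.length_nm - 200.0) / 200.0)
        disc = img.shape_metrics(
            syn.gen_localizations(
                syn.ShapeGroundTruth(kind="disc", diameter_nm=300.0,
                                     n_localizations=disc_n_localizations,
                                     precision_nm=0.0, seed=s)
            )
        )
        disc_ecc.append(disc.eccentricity)
        disc_circ.append(disc.circularity)
    # rotation invariance on one blurred rod
    rng = np.random.default_rng(seed)
    xy = syn.gen_localizations(
        syn.ShapeGroundTruth(kind="rod", length_nm=300.0, n_localizations=400,
                             precision_nm=15.0, seed=seed)
    ).xy()
    base = img.shape_metrics(xy)
    rot_dev = 0.0
    for _ in range(8):
        th = rng.uniform(0.0, 2 * np.pi)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        s = img.shape_metrics(xy @ rot.T)
        for v, v0 in (
            (s.length_nm, base.length_nm),
            (s.eccentricity, base.eccentricity),
            (s.circularity, base.circularity),
            (s.area_nm2, base.area_nm2),
        ):
            rot_dev = max(rot_dev, abs(v - v0) / abs(v0))
    return {
        "n": n_repeats,
        "rod_length_median_rel_err": float(np.median(rod_err)),
        "blurred_rod_length_median_rel_err": float(np.median(blur_err)),
        "disc_eccentricity_median": float(np.median(disc_ecc)),
        "disc_circularity_median": float(np.median(disc_circ)),
        "rotation_max_rel_change": float(rot_dev),
    }


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def statistical_calibration(seed: int, n_sims: int = 200) -> dict:
    """Null uniformity of the omnibus ANOVA p-value and the star mapping."""
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_sims):
        groups = {
            "control": rng.normal(0.0, 1.0, 6),
            "A": rng.normal(0.0, 1.0, 6),
            "B": rng.normal(0.0, 1.0, 6),
        }
        pvals.append(rep.anova_vs_control(groups).p_omnibus)
    ks_p = float(stats.kstest(pvals, "uniform").pvalue)
    probes = {
        0.5: "ns", 0.09: "*", 0.005: "**", 0.0005: "***", 0.00005: "****",
        0.1: "ns", 0.01: "*", 0.001: "**", 0.0001: "***",
    }
    correct = sum(rep.significance_stars(p) == lab for p, lab in probes.items())
    return {
        "n": n_sims,
        "null_ks_p": ks_p,
        "stars_correct_fraction": correct / len(probes),
    }
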