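"""Reusable validation experiments run on synthetic cohorts.

Each function here executes one of the package's calibration or recovery
studies end to end — Gaussian closed-form oracles for the divergence core,
FDR calibration and power for the edge-wise difference pattern, selection
recovery for the LASSO step, and parameter recovery for the survival stage —
and returns plain numbers. They are consumed both by the test suite and by
the acceptance script, so the study conditions live in their defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import network as knet
from . import prediction as kpred
from . import stats as kstats
from .synthetic import CohortSpec, HazardSpec, RegionSpec, simulate_cohort, simulate_conversion
from .io import global_normalize

__all__ = [
    "closed_form_symmetric_kl",
    "gaussian_kl_sweep",
    "identical_distribution_weights",
    "fdr_calibration",
    "selection_recovery",
    "cox_recovery",
    "cox_null_coverage",
    "km_logrank_null",
]


def closed_form_symmetric_kl(mu1: float, s1: float, mu2: float, s2: float) -> float:
    """Jeffreys divergence between two Gaussians, in closed form."""
    d2 = (mu1 - mu2) ** 2
    return (s1**2 + d2) / (2 * s2**2) + (s2**2 + d2) / (2 * s1**2) - 1.0


def gaussian_kl_sweep(
    seed: int = 0,
    n: int = 5000,
    dmus: tuple[float, ...] = (0.6, 1.2, 1.8, 2.4, 3.0),
    ratios: tuple[float, ...] = (1.0, 1.1, 1.2, 1.3, 1.4),
    grid_points: int = 512,
    n_draws: int = 6,
) -> pd.DataFrame:
    """KDE + trapezoid symmetric KL vs the Gaussian closed form over a 5x5 sweep.

    Means differ by ``dmu`` (in units of sigma1 = 1) up to 3 sigma and scales
    by moderate ``ratio`` — the regime of globally normalized PET intensities,
    and the one where a relative-error comparison is statistically meaningful
    (accuracy at the simultaneous extreme of location and scale separation is
    floor-dominated; see the methods note). Each cell averages ``n_draws``
    independent estimates of ``n`` samples per side, so the check measures
    estimator accuracy rather than single-draw sampling luck; the standard
    error of that average is reported per cell. Returns estimate, closed
    form, relative error and relative SE per cell.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for dmu in dmus:
        for ratio in ratios:
            draws = []
            for _ in range(n_draws):
                x = rng.normal(0.0, 1.0, size=n)
                y = rng.normal(dmu, ratio, size=n)
                h1 = knet.silverman_bandwidth(x)
                h2 = knet.silverman_bandwidth(y)
                pad = 3.0 * max(h1, h2)
                grid = np.linspace(min(x.min(), y.min()) - pad, max(x.max(), y.max()) + pad, grid_points)
                P = knet.estimate_pdf(x, grid_spec=grid, bandwidth=h1)
                Q = knet.estimate_pdf(y, grid_spec=grid, bandwidth=h2)
                draws.append(knet.symmetric_kl(P, Q))
            est = float(np.mean(draws))
            true = closed_form_symmetric_kl(0.0, 1.0, dmu, ratio)
            se = float(np.std(draws, ddof=1) / np.sqrt(n_draws))
            rows.append(
                {
                    "dmu": dmu,
                    "ratio": ratio,
                    "estimate": est,
                    "closed_form": true,
                    "rel_error": abs(est - true) / true,
                    "rel_se": se / true,
                }
            )
    return pd.DataFrame(rows)


def identical_distribution_weights(
    seed: int = 0, n_regions: int = 10, n_voxels: int = 5000
) -> np.ndarray:
    """Off-diagonal KLS weights of a subject whose regions share one law.

    With every region i.i.d. from the same Gaussian, all true divergences are
    zero, so weights should approach 1 as the voxel count grows.
    """
    spec = [RegionSpec(region_id=i + 1, mu=1.0, sigma=0.1, n_voxels=n_voxels) for i in range(n_regions)]
    from .synthetic import simulate_subject

    subj = simulate_subject(spec, jitter_sd=0.0, seed=seed)
    net = knet.build_individual_network(subj)
    return net.upper_values()


def _null_cohort_spec(seed: int, n_per_group: int, n_regions: int, n_voxels: int) -> CohortSpec:
    base = tuple(
        RegionSpec(region_id=i + 1, mu=1.0 + 0.02 * (i % 7), sigma=0.1, n_voxels=n_voxels)
        for i in range(n_regions)
    )
    return CohortSpec(
        base_regions=base,
        groups=(("A", n_per_group, ()), ("B", n_per_group, ())),
        subject_noise_sd=0.02,
        seed=seed,
    )


def _cohort_networks(spec: CohortSpec, grid_points: int, grid_mode: str = "pair") -> dict[str, list]:
    nets: dict[str, list] = {}
    for subj, label in simulate_cohort(spec):
        net = knet.build_individual_network(
            global_normalize(subj), grid_points=grid_points, grid_mode=grid_mode
        )
        nets.setdefault(label, []).append(net)
    return nets


def fdr_calibration(
    seed: int = 0,
    n_replicates: int = 200,
    n_per_group: int = 30,
    n_regions: int = 20,
    n_voxels: int = 40,
    grid_points: int = 256,
    alpha: float = 0.05,
    effect_sd: float = 3.0,
) -> dict[str, float]:
    """Null FDR calibration and injected-edge power for the difference pattern.

    Each replicate draws two groups from identical cohort specs, builds all
    KLS networks and runs the edge-wise Welch+BH pattern; the flagged-edge
    fraction estimates the null false-positive rate. The same networks are
    then reused with edge (1,2) of group B shifted by ``effect_sd`` pooled
    Fisher-Z standard deviations to measure detection power. Voxel count and
    KDE grid are scaled down relative to the package defaults, and densities
    are evaluated on a subject-wide shared grid; both remain well inside the
    regime where the Gaussian oracle tests pass.
    """
    root = np.random.SeedSequence(seed)
    fractions = np.empty(n_replicates)
    detected = np.zeros(n_replicates, dtype=bool)
    n_edges = n_regions * (n_regions - 1) // 2
    for rep, ss in enumerate(root.spawn(n_replicates)):
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        spec = _null_cohort_spec(rep_seed, n_per_group, n_regions, n_voxels)
        nets = _cohort_networks(spec, grid_points, grid_mode="global")
        pattern = kstats.edgewise_difference_pattern(nets["A"], nets["B"], alpha=alpha)
        fractions[rep] = len(pattern.significant_edges()) / n_edges

        # power: shift one edge of group B by effect_sd pooled Fisher-Z SDs
        za = np.array([kstats.fisher_z(m)[0, 1] for m in nets["A"]])
        zb = np.array([kstats.fisher_z(m)[0, 1] for m in nets["B"]])
        pooled_sd = np.sqrt((za.var(ddof=1) + zb.var(ddof=1)) / 2.0)
        shifted_b = []
        for m in nets["B"]:
            W = m.weights.copy()
            z = np.arctanh(np.clip(W[0, 1], -1 + 1e-7, 1 - 1e-7)) + effect_sd * pooled_sd
            W[0, 1] = W[1, 0] = np.tanh(z)
            shifted_b.append(knet.ConnectivityMatrix(weights=W, kind=m.kind, region_labels=m.region_labels))
        pattern2 = kstats.edgewise_difference_pattern(nets["A"], shifted_b, alpha=alpha)
        detected[rep] = pattern2.significant[0, 1]
    mc_error = float(fractions.std(ddof=1) / np.sqrt(n_replicates))
    return {
        "mean_flagged_fraction": float(fractions.mean()),
        "mc_error": mc_error,
        "alpha": alpha,
        "power": float(detected.mean()),
        "n_replicates": n_replicates,
    }


def selection_recovery(
    seed: int = 0,
    n_replicates: int = 50,
    n_subjects: int = 300,
    n_features: int = 457,
    n_informative: int = 5,
    effect: float = 1.0,
    n_folds: int = 10,
) -> dict[str, float]:
    """LASSO recovery of known informative features among many noise features.

    Each replicate draws standard-normal features, shifts the first
    ``n_informative`` columns by ``effect`` SD in the positive class, fits
    the MCE selector and counts recovered true features.
    """
    root = np.random.SeedSequence(seed)
    hits = np.empty(n_replicates)
    sizes = np.empty(n_replicates)
    truth = [f"f{j:03d}" for j in range(n_informative)]
    for rep, ss in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(ss)
        y = np.repeat([0, 1], n_subjects // 2)
        X = rng.normal(size=(n_subjects, n_features))
        X[y == 1, :n_informative] += effect
        cols = [f"f{j:03d}" for j in range(n_features)]
        feats = pd.DataFrame(X, columns=cols)
        model = kpred.fit_mce(feats, y, n_folds=n_folds, seed=int(ss.generate_state(1)[0] % (2**31)))
        sel = set(model.selected_features)
        hits[rep] = len(sel & set(truth))
        sizes[rep] = len(sel)
    return {
        "recovery_rate": float(np.mean(hits >= n_informative - 1)),
        "mean_true_recovered": float(hits.mean()),
        "median_selected": float(np.median(sizes)),
        "n_replicates": n_replicates,
    }


def _features_with_signal(rng: np.random.Generator, n: int, beta: dict[str, float]) -> pd.DataFrame:
    cols = sorted(beta) if beta else ["x"]
    X = rng.normal(size=(n, len(cols)))
    return pd.DataFrame(X, columns=cols)


def cox_recovery(
    seed: int = 0,
    n_subjects: int = 500,
    true_loghr: float = float(np.log(2.0)),
) -> dict[str, float]:
    """Single-covariate Efron Cox fit on data with a known per-SD log hazard."""
    rng = np.random.default_rng(seed)
    feats = _features_with_signal(rng, n_subjects, {"x": true_loghr})
    hz = HazardSpec(beta={"x": true_loghr}, baseline_rate=0.02, censor_time=36.0)
    surv = simulate_conversion(feats, hz, seed=seed + 1)
    df = pd.DataFrame(
        {
            "subject_id": surv["subject_id"],
            "time": surv["time_months"],
            "event": surv["event"],
            "x": feats["x"].to_numpy(),
        }
    )
    fit = kpred.fit_cox(df, ["x"], standardize=True)
    est = fit.coefficients["x"]
    se = (np.log(fit.ci_upper["x"]) - np.log(fit.ci_lower["x"])) / (2 * 1.959964)
    return {
        "true_loghr": true_loghr,
        "estimated_loghr": est,
        "se": float(se),
        "z_from_truth": float((est - true_loghr) / se),
        "hazard_ratio": fit.hazard_ratios["x"],
    }


def cox_null_coverage(seed: int = 0, n_replicates: int = 100, n_subjects: int = 150) -> dict[str, float]:
    """Fraction of null-model Wald 95% CIs that cover HR = 1."""
    root = np.random.SeedSequence(seed)
    cover = np.zeros(n_replicates, dtype=bool)
    hz = HazardSpec(beta={}, baseline_rate=0.03, censor_time=36.0)
    for rep, ss in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(ss)
        feats = pd.DataFrame({"x": rng.normal(size=n_subjects)})
        surv = simulate_conversion(feats, hz, seed=ss.spawn(1)[0])
        df = pd.DataFrame(
            {
                "subject_id": surv["subject_id"],
                "time": surv["time_months"],
                "event": surv["event"],
                "x": feats["x"].to_numpy(),
            }
        )
        fit = kpred.fit_cox(df, ["x"], standardize=True)
        cover[rep] = fit.ci_lower["x"] <= 1.0 <= fit.ci_upper["x"]
    return {"coverage": float(cover.mean()), "n_replicates": n_replicates}


def km_logrank_null(seed: int = 0, n_replicates: int = 200, n_subjects: int = 60) -> dict[str, float]:
    """Distribution of log-rank p-values when PI carries no information.

    Under the null the p-values should be uniform on (0, 1); returns the
    Kolmogorov-Smirnov p-value of that check along with the mean p.
    """
    from scipy import stats as sps

    root = np.random.SeedSequence(seed)
    pvals = np.empty(n_replicates)
    hz = HazardSpec(beta={}, baseline_rate=0.04, censor_time=36.0)
    for rep, ss in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(ss)
        feats = pd.DataFrame({"x": rng.normal(size=n_subjects)})
        surv = simulate_conversion(feats, hz, seed=ss.spawn(1)[0])
        df = pd.DataFrame(
            {
                "subject_id": surv["subject_id"],
                "time": surv["time_months"],
                "event": surv["event"],
            }
        )
        pi = rng.normal(size=n_subjects)  # uninformative prognostic index
        res = kpred.km_stratified(pi, df)
        pvals[rep] = res.logrank_p
    ks = sps.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "mean_logrank_p": float(pvals.mean()), "n_replicates": n_replicates}
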