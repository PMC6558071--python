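"""Marker-by-marker likelihood-ratio genome scan and QTL classification.

Per marker three nested likelihood ratios are computed against the full
model (per-class curve + per-class static mean, shared covariance):

    LR_overall  vs the no-QTL model (one shared mean set) — a marker is
                declared significant when LR_overall exceeds the empirical
                genome-wide permutation threshold (the 1-alpha quantile of
                the maximum LR over markers after jointly reshuffling each
                individual's whole (y, z) record against the genotypes);
    LR_growth   vs shared (a, b, r) with per-class static means — does the
                marker move the growth curve?
    LR_biomass  vs per-class curves with a shared static mean — does the
                marker move the terminal trait?

A significant marker is then classified: *growth* if only the curve
sub-test rejects, *biomass* if only the static sub-test rejects,
*pleiotropic* if both reject, and *covariation* if neither does — the
joint signal lives in the dynamic-static covariation rather than in either
marginal mean.  Sub-tests default to chi-square reference distributions
(df 3(J-1) and (J-1)); an exact marker-local permutation mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import LongitudinalDataset, MarkerPartition
from .growth import TimeGrid, logistic
from .likelihood import (
    JointModelFit,
    OptimOptions,
    fit_marker,
    fit_null,
    pack_theta,
)

__all__ = [
    "MarkerTestResult",
    "EffectTrajectory",
    "lr_overall",
    "test_growth",
    "test_biomass",
    "classify_qtl",
    "subtest_thresholds_chisq",
    "subtest_thresholds_permutation",
    "permutation_threshold",
    "batch_scan_max_lr",
    "scan_markers",
    "results_frame",
    "effect_and_heritability",
]

QTL_CLASSES = ("none", "growth", "biomass", "pleiotropic", "covariation", "unclassified")

# Optimizer budget for fits inside permutation scans: these start at a
# null-derived warm start on effect-free data, so a tighter evaluation cap
# than the default is used (see docs on numerical choices).
PERM_OPTIM = OptimOptions(fatol=1e-5, xatol=5e-4, maxfev_mult=120)


@dataclass
class MarkerTestResult:
    marker_id: str
    lr_overall: float | None
    lr_growth: float | None
    lr_biomass: float | None
    significant_overall: bool = False
    significant_growth: bool = False
    significant_biomass: bool = False
    qtl_class: str = "none"
    full_fit: JointModelFit | None = None
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class EffectTrajectory:
    times: np.ndarray
    effect: np.ndarray
    heritability: np.ndarray
    effect_z: float
    heritability_z: float


def _null_for(
    data: LongitudinalDataset,
    partition: MarkerPartition,
    include_static: bool,
    cross_structure: str,
    optim: OptimOptions,
) -> JointModelFit:
    """No-QTL fit on the individuals entering this marker's test (the
    dataset-level cached fit when no genotypes are missing)."""
    if partition.n == data.n:
        return fit_null(data, include_static, cross_structure, optim)
    sub = data.subset(partition.kept)
    return fit_null(sub, include_static, cross_structure, optim)


def _lr(full: JointModelFit, reduced: JointModelFit) -> float | None:
    if not (np.isfinite(full.log_lik) and np.isfinite(reduced.log_lik)):
        return None
    return max(0.0, 2.0 * (full.log_lik - reduced.log_lik))


def start_from_null(
    null_fit: JointModelFit,
    data: LongitudinalDataset,
    partition: MarkerPartition,
    model: str = "full",
    include_static: bool = True,
) -> np.ndarray | None:
    """Warm start for a marker fit assembled from the dataset-level no-QTL
    fit: shared curve/covariance estimates with per-class static means."""
    if not np.isfinite(null_fit.log_lik) or null_fit.theta is None:
        return None
    p, mz = null_fit.per_genotype[0]
    J = partition.J
    if include_static:
        zk = data.z[partition.kept]
        class_mz = [float(zk[partition.labels == j].mean()) for j in range(J)]
        cov = (
            null_fit.cov.sigma2_y,
            null_fit.cov.rho_y,
            null_fit.cov.phi,
            null_fit.cov.sigma2_z,
        )
    else:
        class_mz = None
        cov = (null_fit.sigma2_y, null_fit.rho_y)
    if model == "full":
        curves, mus = [p] * J, class_mz
    elif model == "growth_null":
        curves, mus = [p], class_mz
    elif model == "biomass_null":
        curves, mus = [p] * J, [mz] if mz is not None else None
    else:
        curves, mus = [p], [mz] if mz is not None else None
    return pack_theta(curves, mus, cov, model, include_static)


def lr_overall(
    data: LongitudinalDataset,
    partition: MarkerPartition,
    include_static: bool = True,
    cross_structure: str = "decay",
    optim: OptimOptions = OptimOptions(),
    start: np.ndarray | None = None,
) -> tuple[float | None, JointModelFit]:
    """Overall LR = 2 (loglik_full - loglik_null), clipped at zero.

    Returns (LR, full_fit); LR is None when either fit failed to converge
    to a finite optimum.
    """
    null = _null_for(data, partition, include_static, cross_structure, optim)
    full = fit_marker(
        data,
        partition,
        start=start,
        model="full",
        include_static=include_static,
        cross_structure=cross_structure,
        optim=optim,
    )
    return _lr(full, null), full


def test_growth(
    data: LongitudinalDataset,
    partition: MarkerPartition,
    full_fit: JointModelFit,
    cross_structure: str = "decay",
    optim: OptimOptions = OptimOptions(),
) -> float | None:
    """LR for the curve effect: full model vs shared (a, b, r) with
    genotype-specific static means (covariance re-estimated in both)."""
    reduced = fit_marker(
        data, partition, model="growth_null", cross_structure=cross_structure, optim=optim
    )
    return _lr(full_fit, reduced)


def test_biomass(
    data: LongitudinalDataset,
    partition: MarkerPartition,
    full_fit: JointModelFit,
    cross_structure: str = "decay",
    optim: OptimOptions = OptimOptions(),
) -> float | None:
    """LR for the static-trait effect: full model vs shared mu_z with
    genotype-specific curves."""
    reduced = fit_marker(
        data, partition, model="biomass_null", cross_structure=cross_structure, optim=optim
    )
    return _lr(full_fit, reduced)


def subtest_thresholds_chisq(J: int, alpha: float = 0.05) -> tuple[float, float]:
    """Chi-square critical values for the curve (df = 3(J-1)) and static
    (df = J-1) sub-tests."""
    return (
        float(sps.chi2.ppf(1 - alpha, 3 * (J - 1))),
        float(sps.chi2.ppf(1 - alpha, J - 1)),
    )


def subtest_thresholds_permutation(
    data: LongitudinalDataset,
    partition: MarkerPartition,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    cross_structure: str = "decay",
    optim: OptimOptions = PERM_OPTIM,
) -> tuple[float, float]:
    """Exact marker-local critical values for the two sub-tests.

    Reshuffles the genotype labels against the (intact) phenotype records,
    refits the full and both constrained models per permutation, and
    returns the empirical (1 - alpha) quantiles of the two sub-test LRs.
    Considerably slower than the chi-square reference; intended for
    follow-up of individual markers."""
    if n_perm < max(20, int(np.ceil(1.0 / alpha))):
        raise ValueError(f"n_perm={n_perm} too small for alpha={alpha}")
    rng = np.random.default_rng(seed)
    g0 = np.full(data.n, -1, dtype=int)
    g0[partition.kept] = partition.labels
    lg = np.empty(n_perm)
    lb = np.empty(n_perm)
    null = fit_null(data, True, cross_structure, optim)
    for p in range(n_perm):
        part_p = MarkerPartition.from_genotypes(g0[rng.permutation(data.n)])
        if part_p is None:  # pragma: no cover - classes are permutation-invariant
            lg[p] = lb[p] = np.nan
            continue
        s = start_from_null(null, data, part_p, "full", True)
        full = fit_marker(
            data, part_p, start=s, model="full",
            cross_structure=cross_structure, optim=optim,
        )
        lg[p] = test_growth(data, part_p, full, cross_structure, optim) or 0.0
        lb[p] = test_biomass(data, part_p, full, cross_structure, optim) or 0.0
    return (
        float(np.nanquantile(lg, 1.0 - alpha)),
        float(np.nanquantile(lb, 1.0 - alpha)),
    )


def classify_qtl(
    significant_overall: bool,
    lr_growth: float | None,
    lr_biomass: float | None,
    thr_growth: float,
    thr_biomass: float,
) -> str:
    """Deterministic classification of a marker from its three tests.

    Not significant overall -> "none".  Otherwise: curve sub-test alone
    rejects -> "growth"; static sub-test alone -> "biomass"; both ->
    "pleiotropic"; neither -> "covariation" (the joint signal is carried by
    the dynamic-static covariation, not by either marginal mean).
    """
    if not significant_overall:
        return "none"
    if lr_growth is None or lr_biomass is None:
        return "unclassified"
    g = lr_growth > thr_growth
    b = lr_biomass > thr_biomass
    if g and b:
        return "pleiotropic"
    if g:
        return "growth"
    if b:
        return "biomass"
    return "covariation"


def _binary_batchable(data: LongitudinalDataset, G: np.ndarray, min_class_size: int):
    """Columns eligible for the lockstep engine: biallelic {0, 1} codes, no
    missing calls, both classes at least min_class_size.  Class counts are
    invariant under permutation, so eligibility is checked once."""
    if not np.isin(G, (0, 1)).all():
        return None
    n1 = (G == 1).sum(axis=0)
    ok = (n1 >= min_class_size) & (G.shape[0] - n1 >= min_class_size)
    return np.flatnonzero(ok)


def _batch_perm_maxima(
    data: LongitudinalDataset,
    G: np.ndarray,
    cols: np.ndarray,
    n_perm: int,
    seed: int,
    include_static: bool,
) -> np.ndarray:
    """Per-permutation genome-wide maximum LR via the lockstep simplex
    engine (one problem per permutation x marker, sufficient-statistics
    likelihood)."""
    from ._batch import batch_fit, class_stats
    from .likelihood import variance_floors

    null = fit_null(data, include_static=include_static)
    Y = data.joint if include_static else data.y
    floors = variance_floors(Y, include_static)
    rng = np.random.default_rng(seed)
    ncs, Ss, Cds, Cos = [], [], [], []
    for _ in range(n_perm):
        order = rng.permutation(data.n)
        nc, S, Cd, Co = class_stats(Y, G[order][:, cols])
        ncs.append(nc)
        Ss.append(S)
        Cds.append(Cd)
        Cos.append(Co)
    nc = np.concatenate(ncs)
    S = np.concatenate(Ss)
    Cd = np.concatenate(Cds)
    Co = np.concatenate(Cos)

    p0, mz0 = null.per_genotype[0]
    if include_static:
        cov0 = (null.cov.sigma2_y, null.cov.rho_y, null.cov.phi, null.cov.sigma2_z)
        base = pack_theta([p0, p0], [mz0, mz0], cov0, "full", True)
        X0 = np.repeat(base[None, :], nc.shape[0], axis=0)
        muz = S[:, :, -1] / nc
        X0[:, 3] = muz[:, 0]
        X0[:, 7] = muz[:, 1]
    else:
        base = pack_theta([p0, p0], None, (null.sigma2_y, null.rho_y), "full", False)
        X0 = np.repeat(base[None, :], nc.shape[0], axis=0)
    ll, _, _ = batch_fit(
        nc, S, Cd, Co, data.grid.times, X0, include_static, var_floor=floors
    )
    LR = np.maximum(2.0 * (ll - null.log_lik), 0.0)
    return LR.reshape(n_perm, cols.size).max(axis=1)


def batch_scan_max_lr(
    data: LongitudinalDataset,
    G: np.ndarray,
    min_class_size: int = 5,
    include_static: bool = True,
) -> float:
    """Genome-wide maximum overall LR of one dataset, via the lockstep
    engine (biallelic complete markers only)."""
    from ._batch import batch_fit, class_stats
    from .likelihood import variance_floors

    G = np.asarray(G)
    if G.ndim == 1:
        G = G[:, None]
    cols = _binary_batchable(data, G, min_class_size)
    if cols is None or cols.size == 0:
        raise ValueError("markers are not eligible for the batch engine")
    null = fit_null(data, include_static=include_static)
    Y = data.joint if include_static else data.y
    floors = variance_floors(Y, include_static)
    nc, S, Cd, Co = class_stats(Y, G[:, cols])
    p0, mz0 = null.per_genotype[0]
    if include_static:
        cov0 = (null.cov.sigma2_y, null.cov.rho_y, null.cov.phi, null.cov.sigma2_z)
        base = pack_theta([p0, p0], [mz0, mz0], cov0, "full", True)
        X0 = np.repeat(base[None, :], nc.shape[0], axis=0)
        muz = S[:, :, -1] / nc
        X0[:, 3] = muz[:, 0]
        X0[:, 7] = muz[:, 1]
    else:
        base = pack_theta([p0, p0], None, (null.sigma2_y, null.rho_y), "full", False)
        X0 = np.repeat(base[None, :], nc.shape[0], axis=0)
    ll, _, _ = batch_fit(
        nc, S, Cd, Co, data.grid.times, X0, include_static, var_floor=floors
    )
    return float(np.maximum(2.0 * (ll - null.log_lik), 0.0).max())


def permutation_threshold(
    data: LongitudinalDataset,
    G: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_class_size: int = 5,
    include_static: bool = True,
    cross_structure: str = "decay",
    optim: OptimOptions = PERM_OPTIM,
    return_maxima: bool = False,
    engine: str = "auto",
):
    """Genome-wide empirical LR threshold by permutation.

    Each permutation jointly reshuffles the individuals' whole (y, z)
    records against the genotype rows (implemented by permuting the rows of
    ``G``, which is equivalent and lets the no-QTL fit be shared across
    permutations since it involves no genotypes), rescans every supplied
    marker, and records the genome-wide maximum LR; the threshold is the
    empirical (1 - alpha) quantile of those maxima.

    ``engine="auto"`` uses the lockstep simplex engine (covqtl._batch) when
    every marker is biallelic with complete calls and the decay covariance
    is in force, and the per-marker scipy path otherwise.
    """
    if n_perm < max(20, int(np.ceil(1.0 / alpha))):
        raise ValueError(
            f"n_perm={n_perm} too small to estimate the {1 - alpha:.3f} quantile"
        )
    G = np.asarray(G)
    if G.ndim == 1:
        G = G[:, None]

    if engine not in ("auto", "batch", "scipy"):
        raise ValueError("engine must be 'auto', 'batch' or 'scipy'")
    use_batch = engine == "batch"
    if engine == "auto" and cross_structure == "decay":
        cols = _binary_batchable(data, G, min_class_size)
        use_batch = cols is not None and cols.size > 0
    if use_batch:
        cols = _binary_batchable(data, G, min_class_size)
        if cols is None or cols.size == 0:
            raise ValueError("batch engine requires complete biallelic markers")
        maxima = _batch_perm_maxima(data, G, cols, n_perm, seed, include_static)
        thr = float(np.quantile(maxima, 1.0 - alpha))
        return (thr, maxima) if return_maxima else thr

    rng = np.random.default_rng(seed)
    null = fit_null(data, include_static, cross_structure, optim)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        order = rng.permutation(data.n)
        Gp = G[order]
        best = 0.0
        for m in range(Gp.shape[1]):
            part = MarkerPartition.from_genotypes(Gp[:, m], min_class_size)
            if part is None:
                continue
            nref = _null_for(data, part, include_static, cross_structure, optim)
            s = start_from_null(nref, data, part, "full", include_static)
            full = fit_marker(
                data,
                part,
                start=s,
                model="full",
                include_static=include_static,
                cross_structure=cross_structure,
                optim=optim,
            )
            lr = _lr(full, nref)
            if lr is not None and lr > best:
                best = lr
        maxima[p] = best
    thr = float(np.quantile(maxima, 1.0 - alpha))
    return (thr, maxima) if return_maxima else thr


def scan_markers(
    data: LongitudinalDataset,
    G: np.ndarray,
    marker_ids: list[str] | None = None,
    threshold: float | None = None,
    alpha: float = 0.05,
    min_class_size: int = 5,
    include_static: bool = True,
    cross_structure: str = "decay",
    optim: OptimOptions = OptimOptions(),
    subtests: bool = True,
    subtest_null: str = "chisq",
    subtest_perm: int = 100,
    seed: int = 0,
) -> list[MarkerTestResult]:
    """Scan every marker column of ``G``; marker order does not affect any
    individual result.  Sub-tests and classification are filled in when a
    genome-wide ``threshold`` is supplied.  ``subtest_null`` selects the
    sub-test reference: chi-square critical values (default) or exact
    marker-local permutation quantiles (slow; only applied to markers that
    pass the overall threshold)."""
    if subtest_null not in ("chisq", "permutation"):
        raise ValueError("subtest_null must be 'chisq' or 'permutation'")
    G = np.asarray(G)
    if G.ndim == 1:
        G = G[:, None]
    M = G.shape[1]
    if marker_ids is None:
        marker_ids = [f"m{m}" for m in range(M)]
    out: list[MarkerTestResult] = []
    for m in range(M):
        part = MarkerPartition.from_genotypes(G[:, m], min_class_size)
        if part is None:
            out.append(
                MarkerTestResult(
                    marker_ids[m], None, None, None, skipped=True,
                    skip_reason=f"fewer than 2 classes with >= {min_class_size} individuals",
                )
            )
            continue
        lr, full = lr_overall(data, part, include_static, cross_structure, optim)
        res = MarkerTestResult(marker_ids[m], lr, None, None, full_fit=full)
        if lr is None:
            res.skip_reason = "non-converged fit"
        elif threshold is not None:
            res.significant_overall = lr > threshold
        if subtests and lr is not None:
            res.lr_growth = test_growth(data, part, full, cross_structure, optim)
            res.lr_biomass = test_biomass(data, part, full, cross_structure, optim)
            if subtest_null == "permutation" and res.significant_overall:
                tg, tb = subtest_thresholds_permutation(
                    data, part, subtest_perm, alpha, seed + m, cross_structure
                )
            else:
                tg, tb = subtest_thresholds_chisq(part.J, alpha)
            if res.lr_growth is not None:
                res.significant_growth = res.lr_growth > tg
            if res.lr_biomass is not None:
                res.significant_biomass = res.lr_biomass > tb
            if threshold is not None:
                res.qtl_class = classify_qtl(
                    res.significant_overall, res.lr_growth, res.lr_biomass, tg, tb
                )
        out.append(res)
    return out


_RESULT_COLUMNS = (
    "marker_id", "lr_overall", "lr_growth", "lr_biomass",
    "significant_overall", "significant_growth", "significant_biomass",
    "qtl_class", "skipped", "skip_reason",
)


def results_frame(results: list[MarkerTestResult]) -> pd.DataFrame:
    """Tabular view of scan results (one row per marker)."""
    if not results:
        return pd.DataFrame(columns=list(_RESULT_COLUMNS))
    rows = []
    for r in results:
        row = {
            "marker_id": r.marker_id,
            "lr_overall": r.lr_overall,
            "lr_growth": r.lr_growth,
            "lr_biomass": r.lr_biomass,
            "significant_overall": r.significant_overall,
            "significant_growth": r.significant_growth,
            "significant_biomass": r.significant_biomass,
            "qtl_class": r.qtl_class,
            "skipped": r.skipped,
            "skip_reason": r.skip_reason,
        }
        if r.full_fit is not None and r.full_fit.cov is not None:
            row.update(
                sigma2_y=r.full_fit.cov.sigma2_y,
                rho_y=r.full_fit.cov.rho_y,
                phi=r.full_fit.cov.phi,
                sigma2_z=r.full_fit.cov.sigma2_z,
            )
            for j, (p, mz) in enumerate(r.full_fit.per_genotype, start=1):
                row[f"a_{j}"] = p.a
                row[f"b_{j}"] = p.b
                row[f"r_{j}"] = p.r
                row[f"mu_z{j}"] = mz
        rows.append(row)
    return pd.DataFrame(rows)


def effect_and_heritability(
    fit: JointModelFit,
    grid: TimeGrid,
    freqs: np.ndarray,
) -> EffectTrajectory:
    """Genetic effect and heritability trajectories from a converged fit.

    effect(t) is half the genotype mean difference for the biallelic (J=2)
    case; for J classes in general the genetic standard deviation
    sqrt(sigma_g^2(t)) is reported instead.  heritability(t) =
    sigma_g^2(t) / (sigma_g^2(t) + sigma2_y) with sigma_g^2(t) =
    sum_j p_j (g_j(t) - gbar(t))^2 and p_j the class frequencies; the
    static-trait analogue uses sigma2_z.
    """
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs / freqs.sum()
    J = fit.J
    if freqs.size != J:
        raise ValueError("one frequency per genotype class required")
    Gm = np.vstack([logistic(grid.times, p) for p, _ in fit.per_genotype])
    gbar = freqs @ Gm
    sig_g2 = freqs @ (Gm - gbar) ** 2
    herit = sig_g2 / (sig_g2 + fit.sigma2_y)
    if J == 2:
        effect = 0.5 * (Gm[0] - Gm[1])
    else:
        effect = np.sqrt(sig_g2)
    if fit.include_static and fit.cov is not None:
        mz = np.array([m for _, m in fit.per_genotype], dtype=float)
        mbar = float(freqs @ mz)
        sgz = float(freqs @ (mz - mbar) ** 2)
        effect_z = 0.5 * (mz[0] - mz[1]) if J == 2 else float(np.sqrt(sgz))
        herit_z = sgz / (sgz + fit.cov.sigma2_z)
    else:
        effect_z, herit_z = np.nan, np.nan
    return EffectTrajectory(
        times=grid.times.copy(),
        effect=effect,
        heritability=herit,
        effect_z=float(effect_z),
        heritability_z=float(herit_z),
    )
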