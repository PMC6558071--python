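"""Synthetic RIL datasets and the power study.

The generator emulates the study system behind the method: a recombinant
inbred line (RIL) population — effectively homozygous lines, two genotype
classes per marker — scored weekly for a growth trait (leaf number,
logistic trajectories over t = 1..9) and once, at the end of the life
cycle, for whole-plant dry weight.  Markers live on a single chromosome
with recombination fraction 0.05 between neighbours; one marker is causal.
Phenotypes are multivariate normal around the causal genotype's mean
vector (logistic curve + static mean) with the AR(1)-plus-cross
covariance; the scenario's phi sets the dynamic-static residual
correlation (0.65 / 0.4 / 0.2 strong-to-weak, 0 uncorrelated).

The longitudinal residual variance is solved so that the realized curve
heritability — the time-averaged genotype variance of the mean curves
against total variance — hits the requested level (0.05 or 0.10), and the
static means are split so the static trait carries the same heritability.

The power study compares the joint dynamic+static model against the
"traditional" pair: one-way ANOVA on the static trait plus univariate
functional mapping on the longitudinal trait (this package's machinery
with the static coordinate removed), declaring a traditional detection
when either rejects at its own 5% genome-wide threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq

from .covariance import CovParams, build_joint_cov
from .data import LongitudinalDataset, MarkerPartition
from .growth import LogisticParams, TimeGrid, logistic
from .likelihood import JointModelFit, OptimOptions, fit_marker, fit_null
from .scan import PERM_OPTIM, _lr, permutation_threshold

__all__ = [
    "ScenarioSpec",
    "PowerResult",
    "PHI_BY_SCENARIO",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "anova_statistics",
    "compute_cell_thresholds",
    "run_power_study",
    "type_i_error_study",
    "curve_recovery_report",
]

PHI_BY_SCENARIO = {1: 0.65, 2: 0.4, 3: 0.2, 4: 0.0}

# optimizer budget used uniformly inside a power-study cell (thresholds and
# replicate fits share it so detection is internally calibrated)
CELL_OPTIM = PERM_OPTIM


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative conditions for one simulation cell.

    phi        dynamic-static residual correlation (scenario 1-4)
    n          number of RILs
    h2         curve heritability; also used for the static-trait split
    n_markers  markers on the simulated chromosome (one causal)
    times      measurement grid (weeks)
    curve1/2   causal-genotype logistic parameters (leaf-number regime)
    rho_y      AR(1) correlation of longitudinal residuals
    sigma2_z   static-trait residual variance (dry-weight units squared)
    mu_z_center midpoint of the two static means (dry-weight scale)
    recomb     recombination fraction between adjacent markers
    """

    phi: float
    n: int
    h2: float
    n_markers: int = 1000
    times: tuple = tuple(range(1, 10))
    curve1: LogisticParams = LogisticParams(55.0, 12.0, 0.7)
    curve2: LogisticParams = LogisticParams(45.0, 12.0, 0.6)
    rho_y: float = 0.7
    sigma2_z: float = 1.0
    mu_z_center: float = 5.05
    recomb: float = 0.05
    causal_index: int | None = None
    scenario: int | None = None

    @staticmethod
    def for_scenario(k: int, n: int, h2: float, **kw) -> "ScenarioSpec":
        return ScenarioSpec(phi=PHI_BY_SCENARIO[k], n=n, h2=h2, scenario=k, **kw)

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(np.asarray(self.times, dtype=float))

    @property
    def causal(self) -> int:
        return self.n_markers // 2 if self.causal_index is None else self.causal_index

    # -- derived generative quantities -------------------------------------

    def genotype_curves(self) -> tuple[LogisticParams, LogisticParams]:
        if self.h2 == 0.0:
            return self.curve1, self.curve1
        return self.curve1, self.curve2

    def mu_z(self) -> tuple[float, float]:
        """Static means split to -+delta so the static-trait heritability
        (delta^2 / (delta^2 + sigma2_z) at RIL frequencies 1/2) equals h2.

        The split opposes the curve effect — the genotype with the taller,
        faster leaf-growth curve gets the smaller dry weight, mirroring the
        parental contrast of the working example (greater leaf number with
        the opposite dry-weight trend).  With phi > 0 this anti-alignment is
        what lets the joint test gain power from the dynamic-static
        correlation."""
        if self.h2 == 0.0:
            return self.mu_z_center, self.mu_z_center
        d = math.sqrt(self.sigma2_z * self.h2 / (1.0 - self.h2))
        return self.mu_z_center - d, self.mu_z_center + d

    def mean_curve_variance(self) -> float:
        """Time-averaged genotype variance of the two mean curves at RIL
        frequencies 1/2 (equals the squared half-difference averaged over
        the grid)."""
        t = np.asarray(self.times, dtype=float)
        g1 = logistic(t, self.curve1)
        g2 = logistic(t, self.curve2)
        return float(np.mean(((g1 - g2) / 2.0) ** 2))

    def sigma2_y(self) -> float:
        """Longitudinal residual variance solved numerically so the curve
        heritability sig_g2 / (sig_g2 + sigma2_y) equals h2.  Under h2 = 0
        the genotype curves coincide and the variance of the h2 = 0.05
        reference calibration is used (power is scale-invariant there)."""
        h2 = self.h2 if self.h2 > 0 else 0.05
        sg2 = self.mean_curve_variance()
        if sg2 <= 0:
            raise ValueError(
                "genotype curves are identical: requested heritability "
                f"{self.h2} is unattainable"
            )
        hi = sg2 * (1.0 / h2) * 10.0
        return float(brentq(lambda s: sg2 / (sg2 + s) - h2, 1e-12, hi, xtol=1e-12))

    def cov_params(self) -> CovParams:
        return CovParams(self.sigma2_y(), self.rho_y, self.phi, self.sigma2_z)


@dataclass
class PowerResult:
    scenario: int | None
    phi: float
    n: int
    h2: float
    method: str
    n_replicates: int
    detections: int
    n_nonconverged: int = 0
    threshold: float | None = None

    @property
    def power(self) -> float:
        return self.detections / self.n_replicates

    @property
    def mc_stderr(self) -> float:
        p = self.power
        return math.sqrt(p * (1.0 - p) / self.n_replicates)


def simulate_genotypes(
    n: int, n_markers: int, rng: np.random.Generator | int, recomb: float = 0.05
) -> np.ndarray:
    """RIL genotypes on one chromosome: each line is a Markov chain over
    {0, 1} starting from a fair coin, switching between adjacent markers
    with probability ``recomb`` (adjacent-marker correlation 1 - 2c)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if n < 1 or n_markers < 1:
        raise ValueError("n and n_markers must be >= 1")
    g0 = rng.integers(0, 2, size=n, dtype=np.int8)
    if n_markers == 1:
        return g0[:, None]
    switches = (rng.random((n, n_markers - 1)) < recomb).astype(np.int8)
    cum = np.cumsum(switches, axis=1, dtype=np.int64) % 2
    G = np.empty((n, n_markers), dtype=np.int8)
    G[:, 0] = g0
    G[:, 1:] = (g0[:, None] + cum) % 2
    return G


def simulate_phenotypes(
    G: np.ndarray, spec: ScenarioSpec, rng: np.random.Generator | int
) -> LongitudinalDataset:
    """Draw each individual's stacked (y, z) from the multivariate normal
    with its causal-genotype mean vector and the scenario covariance."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    G = np.asarray(G)
    grid = spec.grid
    T = len(grid)
    causal = G[:, spec.causal]
    c1, c2 = spec.genotype_curves()
    mz1, mz2 = spec.mu_z()
    mu = np.vstack(
        [
            np.append(logistic(grid.times, c1), mz1),
            np.append(logistic(grid.times, c2), mz2),
        ]
    )
    S = build_joint_cov(spec.cov_params(), T)
    E = rng.standard_normal((G.shape[0], T + 1)) @ S.cholesky.T
    Y = mu[causal] + E
    return LongitudinalDataset(y=Y[:, :T], z=Y[:, T], grid=grid)


def simulate_dataset(
    spec: ScenarioSpec, seed: int
) -> tuple[np.ndarray, LongitudinalDataset]:
    """One replicate: genotypes then phenotypes from a single seed."""
    rng = np.random.default_rng(seed)
    G = simulate_genotypes(spec.n, spec.n_markers, rng, spec.recomb)
    data = simulate_phenotypes(G, spec, rng)
    return G, data


# ---------------------------------------------------------------------------
# comparator: one-way ANOVA on the static trait
# ---------------------------------------------------------------------------


def anova_statistics(z: np.ndarray, G: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistics of the static trait against every marker
    column (binary genotypes), vectorised."""
    z = np.asarray(z, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n = z.size
    n1 = G.sum(axis=0)
    n0 = n - n1
    valid = (n1 > 0) & (n0 > 0)
    s1 = G.T @ z
    zbar = z.mean()
    ss_tot = float(((z - zbar) ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m0 = (z.sum() - s1) / n0
        ssb = n1 * (m1 - zbar) ** 2 + n0 * (m0 - zbar) ** 2
        F = ssb / ((ss_tot - ssb) / (n - 2))
    F[~valid] = 0.0
    return F


def anova_max_threshold(
    z: np.ndarray,
    G: np.ndarray,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide 1-alpha quantile of the maximum ANOVA F under
    permutation of the static trait against the genotypes."""
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        maxima[p] = anova_statistics(z[rng.permutation(z.size)], G).max()
    return float(np.quantile(maxima, 1.0 - alpha))


# ---------------------------------------------------------------------------
# thresholds and the power study
# ---------------------------------------------------------------------------


def _scan_subset(n_markers: int, n_scan: int, causal: int) -> np.ndarray:
    """Evenly spaced marker columns used for permutation threshold scans."""
    cols = np.unique(np.round(np.linspace(0, n_markers - 1, n_scan)).astype(int))
    return cols


@dataclass
class CellThresholds:
    joint: float
    fm: float
    anova: float
    n_perm: int
    n_scan_markers: int


def compute_cell_thresholds(
    spec: ScenarioSpec,
    seed: int,
    alpha: float = 0.05,
    n_perm: int = 100,
    n_scan_markers: int = 100,
    anova_perms: int = 500,
    optim: OptimOptions = CELL_OPTIM,
) -> CellThresholds:
    """Detection thresholds for one simulation cell, computed once from a
    reference replicate (permutation scans over an evenly spaced marker
    subset) and shared across replicates."""
    G, data = simulate_dataset(spec, seed)
    cols = _scan_subset(spec.n_markers, n_scan_markers, spec.causal)
    Gs = G[:, cols]
    thr_joint = permutation_threshold(
        data, Gs, n_perm=n_perm, alpha=alpha, seed=seed + 1, optim=optim
    )
    thr_fm = permutation_threshold(
        data, Gs, n_perm=n_perm, alpha=alpha, seed=seed + 2,
        include_static=False, optim=optim,
    )
    thr_anova = anova_max_threshold(data.z, G, anova_perms, alpha, seed + 3)
    return CellThresholds(thr_joint, thr_fm, thr_anova, n_perm, len(cols))


def _causal_lr(
    data: LongitudinalDataset,
    g: np.ndarray,
    include_static: bool,
    optim: OptimOptions,
) -> float | None:
    part = MarkerPartition.from_genotypes(g)
    if part is None:
        return None
    null = fit_null(data, include_static=include_static, optim=optim)
    full = fit_marker(
        data, part, model="full", include_static=include_static, optim=optim
    )
    return _lr(full, null)


def _batched_replicates(
    spec: ScenarioSpec,
    rep_seeds: list[int],
    methods: tuple[str, ...],
    thresholds: CellThresholds,
    traditional_rule: str,
) -> tuple[dict, dict]:
    """Causal-marker fits for all replicates through the lockstep engine:
    per replicate the full and no-QTL models (joint and, when requested,
    longitudinal-only) are one problem each in four batched simplex runs."""
    from ._batch import batch_fit, class_stats, pooled_stats
    from .likelihood import variance_floors
    from .likelihood import warm_start as _ws

    det = {m: 0 for m in methods}
    nonconv = {m: 0 for m in methods}
    need_trad = "traditional" in methods
    need_joint = "joint" in methods

    stats = {k: [] for k in ("jf", "jn", "ff", "fn")}
    starts = {k: [] for k in ("jf", "jn", "ff", "fn")}
    floors = {k: [] for k in ("jf", "jn", "ff", "fn")}
    anova_F: list[float] = []
    valid: list[int] = []
    times = None
    for i, rseed in enumerate(rep_seeds):
        G, data = simulate_dataset(spec, rseed)
        g = G[:, spec.causal]
        part = MarkerPartition.from_genotypes(g)
        if part is None or part.J != 2:
            for m in methods:
                nonconv[m] += 1
            continue
        valid.append(i)
        times = data.grid.times
        th_full = _ws(data, part, "full", True)
        th_null = _ws(data, None, "null", True)
        stats["jf"].append(class_stats(data.joint, g[:, None].astype(float)))
        stats["jn"].append(pooled_stats(data.joint))
        starts["jf"].append(th_full)
        starts["jn"].append(th_null)
        fj = variance_floors(data.joint, True)
        floors["jf"].append(fj)
        floors["jn"].append(fj)
        if need_trad:
            stats["ff"].append(class_stats(data.y, g[:, None].astype(float)))
            stats["fn"].append(pooled_stats(data.y))
            fy = variance_floors(data.y, False)
            floors["ff"].append(fy)
            floors["fn"].append(fy)
            starts["ff"].append(th_full[[0, 1, 2, 4, 5, 6, 8, 9]])
            starts["fn"].append(th_null[[0, 1, 2, 4, 5]])
            anova_F.append(float(anova_statistics(data.z, g)[0]))

    def _run(key: str, include_static: bool):
        nc = np.concatenate([s[0] for s in stats[key]])
        S = np.concatenate([s[1] for s in stats[key]])
        Cdm = np.concatenate([s[2] for s in stats[key]])
        Com = np.concatenate([s[3] for s in stats[key]])
        X0 = np.vstack(starts[key])
        fl = np.asarray(floors[key]).mean(axis=0)
        ll, _, conv = batch_fit(
            nc, S, Cdm, Com, times, X0, include_static, var_floor=tuple(fl)
        )
        return ll, conv

    if valid:
        if need_joint:
            ll_f, cv_f = _run("jf", True)
            ll_n, cv_n = _run("jn", True)
            lr = np.maximum(2.0 * (ll_f - ll_n), 0.0)
            finite = np.isfinite(lr)
            nonconv["joint"] += int((~finite).sum())
            det["joint"] += int((lr[finite] > thresholds.joint).sum())
        if need_trad:
            ll_f, _ = _run("ff", False)
            ll_n, _ = _run("fn", False)
            lr = np.maximum(2.0 * (ll_f - ll_n), 0.0)
            finite = np.isfinite(lr)
            nonconv["traditional"] += int((~finite).sum())
            fm_hit = finite & (lr > thresholds.fm)
            an_hit = np.asarray(anova_F) > thresholds.anova
            hit = (fm_hit | an_hit) if traditional_rule == "either" else (fm_hit & an_hit)
            det["traditional"] += int(hit.sum())
    return det, nonconv


def run_power_study(
    spec: ScenarioSpec,
    n_replicates: int = 200,
    methods: tuple[str, ...] = ("joint", "traditional"),
    seed: int = 0,
    alpha: float = 0.05,
    threshold_mode: str = "shared",
    n_perm: int = 100,
    n_scan_markers: int = 100,
    traditional_rule: str = "either",
    optim: OptimOptions = CELL_OPTIM,
    thresholds: CellThresholds | None = None,
    engine: str = "batch",
) -> list[PowerResult]:
    """Estimate detection power at the causal marker for one cell.

    Per replicate a fresh dataset is simulated and detection is declared
    when the causal-marker statistic exceeds its genome-wide 5% threshold
    (joint LR for the joint model; for the traditional pair, either the
    ANOVA F on the static trait or the univariate functional-mapping LR on
    the longitudinal trait, each at its own threshold — set
    ``traditional_rule="both"`` for the conjunction).  Thresholds are
    computed once per cell from a reference replicate (``shared`` mode) or
    per replicate (``per-replicate``, much slower).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if traditional_rule not in ("either", "both"):
        raise ValueError("traditional_rule must be 'either' or 'both'")
    ss = np.random.SeedSequence(seed)
    thr_seed, rep_seed0 = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))

    if threshold_mode == "shared":
        if thresholds is None:
            thresholds = compute_cell_thresholds(
                spec, thr_seed, alpha, n_perm, n_scan_markers, optim=optim
            )
    elif threshold_mode != "per-replicate":
        raise ValueError("threshold_mode must be 'shared' or 'per-replicate'")

    rep_ss = np.random.SeedSequence(rep_seed0).spawn(n_replicates)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in rep_ss]

    if engine == "batch" and threshold_mode == "shared":
        det, nonconv = _batched_replicates(
            spec, rep_seeds, methods, thresholds, traditional_rule
        )
    else:
        det = {m: 0 for m in methods}
        nonconv = {m: 0 for m in methods}
        for rseed in rep_seeds:
            G, data = simulate_dataset(spec, rseed)
            if threshold_mode == "per-replicate":
                thresholds = compute_cell_thresholds(
                    spec, rseed + 7, alpha, n_perm, n_scan_markers, optim=optim
                )
            g = G[:, spec.causal]
            if "joint" in methods:
                lr = _causal_lr(data, g, True, optim)
                if lr is None:
                    nonconv["joint"] += 1
                elif lr > thresholds.joint:
                    det["joint"] += 1
            if "traditional" in methods:
                lr_fm = _causal_lr(data, g, False, optim)
                F = float(anova_statistics(data.z, g)[0])
                if lr_fm is None:
                    nonconv["traditional"] += 1
                    fm_hit = False
                else:
                    fm_hit = lr_fm > thresholds.fm
                an_hit = F > thresholds.anova
                hit = (fm_hit or an_hit) if traditional_rule == "either" else (fm_hit and an_hit)
                if hit:
                    det["traditional"] += 1

    thr_by_method = {"joint": thresholds.joint, "traditional": thresholds.fm}
    return [
        PowerResult(
            scenario=spec.scenario,
            phi=spec.phi,
            n=spec.n,
            h2=spec.h2,
            method=m,
            n_replicates=n_replicates,
            detections=det[m],
            n_nonconverged=nonconv[m],
            threshold=thr_by_method[m],
        )
        for m in methods
    ]


def type_i_error_study(
    n: int = 100,
    n_markers: int = 100,
    n_replicates: int = 100,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    phi: float = 0.65,
) -> dict:
    """Genome-wide size control under the global null (no QTL anywhere).

    The permutation threshold is computed once from a reference replicate,
    then fresh null datasets are scanned; the type-I error is the fraction
    whose genome-wide maximum LR exceeds the threshold.
    """
    from .scan import batch_scan_max_lr, permutation_threshold

    spec = ScenarioSpec(phi=phi, n=n, h2=0.0, n_markers=n_markers)
    ss = np.random.SeedSequence(seed).spawn(n_replicates + 1)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    G_ref, data_ref = simulate_dataset(spec, seeds[0])
    thr = permutation_threshold(
        data_ref, G_ref, n_perm=n_perm, alpha=alpha, seed=seeds[0] + 1
    )
    hits = 0
    for s in seeds[1:]:
        G, data = simulate_dataset(spec, s)
        if batch_scan_max_lr(data, G) > thr:
            hits += 1
    return {
        "threshold": thr,
        "n_replicates": n_replicates,
        "hits": hits,
        "type_i_error": hits / n_replicates,
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# curve recovery (estimation quality at the causal marker)
# ---------------------------------------------------------------------------


def _num_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


def _curve_se(
    fit: JointModelFit,
    data: LongitudinalDataset,
    part: MarkerPartition,
    times: np.ndarray,
) -> np.ndarray | None:
    """Delta-method pointwise standard errors of each genotype's fitted
    curve, from the numerical Hessian of the negative log-likelihood."""
    from .likelihood import neg_log_lik

    if fit.theta is None:
        return None
    f = lambda th: neg_log_lik(th, data, part, model="full")
    H = _num_hessian(f, fit.theta)
    try:
        C = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        C = np.linalg.pinv(H)
    J = fit.J
    se = np.empty((J, times.size))
    for j, (p, _) in enumerate(fit.per_genotype):
        base = 4 * j
        Cj = C[base : base + 3, base : base + 3]
        ert = np.exp(-p.r * times)
        denom = 1.0 + p.b * ert
        grad = np.vstack(
            [1.0 / denom, -p.a * ert / denom**2, p.a * p.b * times * ert / denom**2]
        )
        var = np.einsum("kt,kl,lt->t", grad, Cj, grad)
        se[j] = np.sqrt(np.maximum(var, 0.0))
    return se


def curve_recovery_report(
    spec: ScenarioSpec,
    n_replicates: int = 200,
    seed: int = 0,
    level: float = 0.95,
    optim: OptimOptions = OptimOptions(fatol=1e-6, xatol=1e-4, maxfev_mult=400),
) -> dict:
    """Fit the joint model at the causal marker across replicates and report
    the relative bias of the genotype asymptotes and the empirical coverage
    of pointwise delta-method confidence bands around the fitted curves."""
    zq = float(sps.norm.ppf(0.5 + level / 2.0))
    c1, c2 = spec.genotype_curves()
    truth_curves = [c1, c2]
    times = spec.grid.times
    truth = np.vstack([logistic(times, c) for c in truth_curves])
    a_true = np.array([c.a for c in truth_curves])

    rep_ss = np.random.SeedSequence(seed).spawn(n_replicates)
    rel_bias_a = []
    covered = 0
    total = 0
    n_failed = 0
    for i in range(n_replicates):
        rseed = int(rep_ss[i].generate_state(1)[0] % (2**31 - 1))
        G, data = simulate_dataset(spec, rseed)
        part = MarkerPartition.from_genotypes(G[:, spec.causal])
        if part is None:
            n_failed += 1
            continue
        fit = fit_marker(data, part, model="full", optim=optim)
        if not np.isfinite(fit.log_lik):
            n_failed += 1
            continue
        # generator labels class 0 as genotype 1; partition classes are in
        # genotype-code order, so they align
        a_hat = np.array([p.a for p, _ in fit.per_genotype])
        rel_bias_a.append((a_hat - a_true) / a_true)
        se = _curve_se(fit, data, part, times)
        if se is None:
            n_failed += 1
            continue
        est = np.vstack([logistic(times, p) for p, _ in fit.per_genotype])
        inside = np.abs(est - truth) <= zq * se
        covered += int(inside.sum())
        total += inside.size
    rel_bias_a = np.array(rel_bias_a)
    return {
        "n_replicates": n_replicates,
        "n_failed": n_failed,
        "mean_abs_rel_bias_a": float(np.mean(np.abs(rel_bias_a))) if rel_bias_a.size else math.nan,
        "mean_rel_bias_a": float(np.mean(rel_bias_a)) if rel_bias_a.size else math.nan,
        "band_coverage": covered / total if total else math.nan,
        "level": level,
    }
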