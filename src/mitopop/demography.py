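"""Demographic inference from a single-locus sample.

Implements the sudden-expansion mismatch-distribution analysis (tau,
theta0, theta1 with SSD and Harpending's raggedness goodness-of-fit, both
tested by parametric bootstrap), the Fu's Fs and Ramos-Onsins & Rozas R2
neutrality tests with coalescent-simulated null distributions, and the
conversion of tau to calendar time through a divergence-calibrated
substitution rate (t = tau / 2u).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alignment_io import Alignment, _MISSING, collapse_haplotypes
from . import coalsim

THETA1_CAP = 1e5


# --- mismatch distribution ---------------------------------------------------


def pairwise_differences(aln: Alignment) -> np.ndarray:
    """Raw difference counts (pairwise deletion) for all n(n-1)/2 pairs."""
    enc = aln.encoded()
    ok = enc != _MISSING
    out = []
    for i in range(aln.n):
        both = ok[i] & ok[i + 1 :]
        out.extend((both & (enc[i] != enc[i + 1 :])).sum(axis=1).tolist())
    return np.array(out, dtype=int)


def mismatch_histogram(aln: Alignment) -> np.ndarray:
    """Relative frequency of pairwise difference counts, classes 0..max."""
    if aln.n < 2:
        raise ValueError("mismatch histogram requires n >= 2")
    diffs = pairwise_differences(aln)
    return _hist_from_diffs(diffs)


def _hist_from_diffs(diffs: np.ndarray) -> np.ndarray:
    counts = np.bincount(diffs)
    return counts / counts.sum()


def equilibrium_mismatch(theta: float, n_classes: int) -> np.ndarray:
    """Stationary mismatch probabilities F_i(theta) = theta^i/(theta+1)^(i+1)."""
    i = np.arange(n_classes)
    if theta == 0.0:
        out = np.zeros(n_classes)
        out[0] = 1.0
        return out
    return np.exp(i * math.log(theta) - (i + 1) * math.log(theta + 1.0))


def expected_mismatch(
    tau: float, theta0: float, theta1: float, n_classes: int, fold_tail: bool = True
) -> np.ndarray:
    """Sudden-expansion mismatch expectation over classes 0..n_classes-1.

    F_i = Fhat_i(theta1) + e^(-tau (theta1+1)/theta1) * sum_{j<=i} tau^j/j!
    * [Fhat_{i-j}(theta0) - Fhat_{i-j}(theta1)] — the transient pairwise-
    difference distribution a time tau (in mutational units) after a step
    change from theta0 to theta1; the extra tau/theta1 term in the
    exponent is the pair's chance of escaping coalescence during the
    recent epoch (it vanishes in the large-theta1 limit). At tau = 0 this
    reduces to the stationary spectrum at theta0. With ``fold_tail`` the
    probability mass beyond the last class is folded into it so the vector
    sums to 1.
    """
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise ValueError("tau, theta0, theta1 must be non-negative")
    f0 = equilibrium_mismatch(theta0, n_classes)
    f1 = equilibrium_mismatch(theta1, n_classes)
    j = np.arange(n_classes)
    decay = tau * (theta1 + 1.0) / theta1 if theta1 > 0 else math.inf
    if tau > 0:
        log_pois = -decay + j * np.log(tau) - np.array(
            [math.lgamma(x + 1) for x in j]
        )
    else:
        log_pois = np.where(j == 0, 0.0, -np.inf)
    pois = np.exp(log_pois)
    F = f1 + np.convolve(pois, f0 - f1)[:n_classes]
    F = np.clip(F, 0.0, None)
    if fold_tail:
        F[-1] = max(1.0 - F[:-1].sum(), 0.0)
    return F


def raggedness(freqs: np.ndarray) -> float:
    """Harpending's raggedness index: sum of squared successive differences."""
    f = np.asarray(freqs, dtype=float)
    return float(np.sum(np.diff(f) ** 2))


def _ssd(obs: np.ndarray, tau: float, theta0: float, theta1: float) -> float:
    exp = expected_mismatch(tau, theta0, theta1, len(obs))
    return float(np.sum((obs - exp) ** 2))


def _fit_params(obs: np.ndarray, polish_from=None) -> tuple[float, float, float, float]:
    """Minimize SSD over (tau, theta0, theta1 >= theta0 <= cap).

    Coarse grid seeding followed by Nelder-Mead in a square-root
    parametrization that enforces positivity and theta0 <= theta1.
    """
    mean_d = float(np.arange(len(obs)) @ obs)
    seeds = []
    if polish_from is not None:
        seeds.append(polish_from)
    taus = [0.0, 0.5 * mean_d, mean_d, 1.5 * mean_d, 2.0 * mean_d, 3.0 * mean_d]
    theta0s = [0.01, 0.5, 2.0, max(mean_d / 2, 0.01)]
    theta1s = [max(mean_d, 1.0), 10 * max(mean_d, 1.0), 1e4]
    for t in taus:
        for t0 in theta0s:
            for t1 in theta1s:
                if t0 <= t1:
                    seeds.append((t, t0, t1))
    best = min(seeds, key=lambda p: _ssd(obs, *p))

    def unpack(x):
        tau = x[0] ** 2
        theta0 = x[1] ** 2
        theta1 = min(theta0 + x[2] ** 2, THETA1_CAP)
        return tau, theta0, theta1

    def objective(x):
        return _ssd(obs, *unpack(x))

    x0 = np.array(
        [math.sqrt(best[0]), math.sqrt(best[1]), math.sqrt(max(best[2] - best[1], 1e-8))]
    )
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-12})
    tau, theta0, theta1 = unpack(res.x)
    return tau, theta0, theta1, float(res.fun)


@dataclass
class MismatchFit:
    observed: np.ndarray
    tau: float
    theta0: float
    theta1: float
    SSD: float
    p_SSD: float
    rg: float
    p_rg: float
    tau_CI: tuple[float, float]
    degenerate: bool = False


def fit_sudden_expansion(
    hist: np.ndarray, n: int, seed: int | None = None, n_boot: int = 1000
) -> MismatchFit:
    """Fit the sudden-expansion model to an observed mismatch spectrum.

    ``hist`` is the relative-frequency spectrum for a sample of ``n``
    sequences. p_SSD and p_rg come from a parametric bootstrap: coalescent
    samples are simulated under the fitted expansion, each is refitted, and
    the p-value is the fraction of simulated statistics at least as large
    as the observed one ((b+1)/(m+1) corrected). The tau confidence
    interval is the bootstrap 2.5/97.5 percentile range.
    """
    obs = np.asarray(hist, dtype=float)
    if not math.isclose(obs.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("histogram must be a relative-frequency spectrum summing to 1")
    if len(obs) < 2 or np.count_nonzero(obs) < 2:
        return MismatchFit(obs, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 1.0, (0.0, 0.0),
                           degenerate=True)
    tau, theta0, theta1, ssd = _fit_params(obs)
    rg_obs = raggedness(obs)

    rng = np.random.default_rng(seed)
    model = coalsim.DemographyModel(
        kind="sudden_expansion", theta0=max(theta0, 1e-6), theta1=max(theta1, 1e-6),
        tau=tau,
    )
    cfg = coalsim.SimConfig(n=n, L=1)
    taus, ssd_ge, rg_ge = [], 0, 0
    for _ in range(n_boot):
        tree = coalsim.simulate_genealogy(model, cfg, rng)
        mat = coalsim.mutate_infinite_sites(tree, cfg, rng)
        diffs = _matrix_pairwise_diffs(mat)
        sim_obs = _hist_from_diffs(diffs)
        t_i, t0_i, t1_i, ssd_i = _fit_params(sim_obs, polish_from=(tau, theta0, theta1))
        taus.append(t_i)
        if ssd_i >= ssd:
            ssd_ge += 1
        if raggedness(sim_obs) >= rg_obs:
            rg_ge += 1
    p_ssd = (ssd_ge + 1) / (n_boot + 1)
    p_rg = (rg_ge + 1) / (n_boot + 1)
    lo, hi = (np.percentile(taus, [2.5, 97.5]) if taus else (tau, tau))
    return MismatchFit(obs, tau, theta0, theta1, ssd, p_ssd, rg_obs, p_rg,
                       (float(lo), float(hi)))


def _matrix_pairwise_diffs(mat: np.ndarray) -> np.ndarray:
    """Pairwise difference counts between rows of a binary matrix."""
    n = mat.shape[0]
    out = []
    m = mat.astype(np.int32)
    for i in range(n):
        out.extend(np.abs(m[i + 1 :] - m[i]).sum(axis=1).tolist())
    return np.array(out, dtype=int)


# --- Fu's Fs ----------------------------------------------------------------

_stirling_cache: dict[int, list[float]] = {}


def _log_stirling_row(n: int) -> list[float]:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n.

    Exact big-integer recurrence |s(n+1,k)| = n|s(n,k)| + |s(n,k-1)|,
    then log (so no precision loss before the final float conversion).
    """
    if n in _stirling_cache:
        return _stirling_cache[n]
    row = [1]
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(m + 1):
            new[k] = (m - 1) * (row[k] if k <= m - 1 else 0) + (row[k - 1] if k >= 1 else 0)
        row = new
    logs = [math.log(v) if v > 0 else -math.inf for v in row]
    _stirling_cache[n] = logs
    return logs


def log_ewens_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | theta, n) for k = 0..n under the Ewens distribution:
    Pr(K=k) = |s(n,k)| theta^k / (theta (theta+1) ... (theta+n-1))."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    logs = _log_stirling_row(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    k = np.arange(n + 1)
    return np.array(logs) + k * math.log(theta) - log_rising


@dataclass
class FuFsResult:
    Fs: float
    p_Fs: float
    k_obs: int
    theta_hat: float
    S_prime: float
    saturated: bool = False


def fs_statistic(n: int, theta: float, k_obs: int) -> tuple[float, float, bool]:
    """(Fs, S', saturated): S' = Pr(K >= k_obs | theta, n), Fs = ln(S'/(1-S'))."""
    logp = log_ewens_pmf(n, theta)
    log_sp = logsumexp(logp[k_obs:])
    log_1msp = logsumexp(logp[:k_obs]) if k_obs >= 1 else -math.inf
    sp = math.exp(log_sp)
    if not (math.isfinite(log_sp) and math.isfinite(log_1msp)):
        return (math.inf if log_1msp == -math.inf else -math.inf), sp, True
    return float(log_sp - log_1msp), sp, False


def fs_null_pvalue(n: int, fs_obs: float, theta: float, rng, n_sim: int) -> float:
    """p = fraction of constant-size coalescent samples (rate theta) whose
    Fs, recomputed from each sample's own k_bar and haplotype count, is
    <= the observed value ((b+1)/(m+1) corrected)."""
    model = coalsim.DemographyModel(kind="constant", theta0=theta)
    cfg = coalsim.SimConfig(n=n, L=1)
    le = 0
    for _ in range(n_sim):
        tree = coalsim.simulate_genealogy(model, cfg, rng)
        mat = coalsim.mutate_infinite_sites(tree, cfg, rng)
        if mat.shape[1] == 0:
            fs_i = math.inf  # monomorphic sample: maximally non-expansion-like
        else:
            kb_i = float(np.mean(_matrix_pairwise_diffs(mat)))
            k_i = len({tuple(r) for r in mat})
            fs_i, _, _ = fs_statistic(n, kb_i, k_i) if kb_i > 0 else (math.inf, 1.0, True)
        if fs_i <= fs_obs:
            le += 1
    return (le + 1) / (n_sim + 1)


def fu_fs(aln: Alignment, seed: int | None = None, n_sim: int = 1000) -> FuFsResult:
    """Fu's Fs with its coalescent-simulated p-value.

    theta is estimated by the mean pairwise difference k_bar; the null
    distribution simulates constant-size samples at that theta and
    recomputes Fs from each simulated sample's own k_bar and haplotype
    count. p = fraction of simulated Fs <= observed ((b+1)/(m+1)).
    """
    if aln.n < 2:
        raise ValueError("Fu's Fs requires n >= 2")
    k_bar = float(np.mean(pairwise_differences(aln)))
    if k_bar == 0.0:
        raise ValueError("Fs undefined: no pairwise differences (k_bar = 0)")
    k_obs = collapse_haplotypes(aln).n_haplotypes
    fs, sp, saturated = fs_statistic(aln.n, k_bar, k_obs)
    rng = np.random.default_rng(seed)
    p = fs_null_pvalue(aln.n, fs, k_bar, rng, n_sim)
    return FuFsResult(Fs=fs, p_Fs=p, k_obs=k_obs,
                      theta_hat=k_bar, S_prime=sp, saturated=saturated)


# --- Ramos-Onsins & Rozas R2 ------------------------------------------------


@dataclass
class R2Result:
    R2: float
    p_R2: float
    U: np.ndarray
    S: int
    k_bar: float


def _singletons_per_sequence(aln: Alignment) -> tuple[np.ndarray, int]:
    """(U_i vector, S): U_i counts sites where sequence i carries a base of
    sample frequency exactly 1; S counts variable sites. Ambiguous bases
    are ignored per site."""
    enc = aln.encoded()
    n, L = enc.shape
    U = np.zeros(n, dtype=int)
    S = 0
    for site in range(L):
        col = enc[:, site]
        valid = col != _MISSING
        if not valid.any():
            continue
        vals, counts = np.unique(col[valid], return_counts=True)
        if len(vals) < 2:
            continue
        S += 1
        for v, c in zip(vals, counts):
            if c == 1:
                U[np.where(valid & (col == v))[0][0]] += 1
    return U, S


def r2_from_components(U: np.ndarray, k_bar: float, S: int) -> float:
    n = len(U)
    return float(math.sqrt(np.mean((U - k_bar / 2.0) ** 2)) / S)


def r2_test(aln: Alignment, seed: int | None = None, n_sim: int = 1000) -> R2Result:
    """Ramos-Onsins & Rozas R2 with a fixed-S coalescent null.

    R2 = sqrt(mean_i (U_i - k_bar/2)^2) / S where U_i is the number of
    singleton sites carried by sequence i (minority-base convention; no
    outgroup polarization). The null fixes the observed number of
    segregating sites and simulates constant-size genealogies;
    p = fraction of simulated R2 <= observed ((b+1)/(m+1))."""
    if aln.n < 2:
        raise ValueError("R2 requires n >= 2")
    U, S = _singletons_per_sequence(aln)
    if S == 0:
        raise ValueError("R2 undefined: no segregating sites")
    k_bar = float(np.mean(pairwise_differences(aln)))
    r2 = r2_from_components(U, k_bar, S)
    rng = np.random.default_rng(seed)
    p = r2_null_pvalue(aln.n, r2, S, rng, n_sim)
    return R2Result(R2=r2, p_R2=p, U=U, S=S, k_bar=k_bar)


def r2_matrix_components(mat: np.ndarray) -> tuple[np.ndarray, float, int]:
    """(U, k_bar, S) for a binary infinite-sites matrix, minority-base
    singleton convention (columns at derived count 1 or n-1)."""
    n, s = mat.shape
    ones = mat.sum(axis=0)
    U = (mat[:, ones == 1] == 1).sum(axis=1) + (mat[:, ones == n - 1] == 0).sum(axis=1)
    k_bar = float(np.mean(_matrix_pairwise_diffs(mat)))
    return U, k_bar, s


def r2_null_pvalue(n: int, r2_obs: float, S: int, rng, n_sim: int) -> float:
    """p = fraction of fixed-S constant-size coalescent samples with
    R2 <= observed ((b+1)/(m+1) corrected)."""
    model = coalsim.DemographyModel(kind="constant", theta0=1.0)
    cfg = coalsim.SimConfig(n=n, L=1, fixed_S=S)
    le = 0
    for _ in range(n_sim):
        tree = coalsim.simulate_genealogy(model, cfg, rng)
        mat = coalsim.mutate_infinite_sites(tree, cfg, rng)
        if mat.shape[1] == 0:
            continue
        U_i, kb_i, s_i = r2_matrix_components(mat)
        if r2_from_components(U_i, kb_i, s_i) <= r2_obs:
            le += 1
    return (le + 1) / (n_sim + 1)


# --- expansion-time dating ---------------------------------------------------


@dataclass
class RateCalibration:
    """Substitution rate calibrated from a dated clade divergence.

    mu (per site per lineage per year) = clade_divergence_K2P / (2 T);
    u (per sequence per generation)    = 2 mu L generation_time.
    The dating equation is then t = tau / (2u) generations.
    """

    clade_divergence_K2P: float
    divergence_time: float  # years
    L: int = 1140
    generation_time: float = 1.0  # years

    def __post_init__(self) -> None:
        if min(self.clade_divergence_K2P, self.divergence_time, self.L,
               self.generation_time) <= 0:
            raise ValueError("all calibration fields must be positive")

    @property
    def mu(self) -> float:
        return self.clade_divergence_K2P / (2.0 * self.divergence_time)

    @property
    def u(self) -> float:
        return 2.0 * self.mu * self.L * self.generation_time


def date_expansion(
    tau: float, cal: RateCalibration, tau_CI: tuple[float, float] | None = None
) -> tuple[float, tuple[float, float] | None]:
    """Convert tau (and optionally its CI) to years: t = tau/(2u) generations
    times the generation time."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    factor = cal.generation_time / (2.0 * cal.u)
    t = tau * factor
    ci = None
    if tau_CI is not None:
        lo, hi = tau_CI
        ci = (lo * factor, hi * factor)
    return t, ci


def years_to_mya(t_years: float, decimals: int = 3) -> float:
    return round(t_years / 1e6, decimals)
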