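"""Phylogenetic signal statistics for species-level toxicity traits.

Implements the comparative half of the analysis: per-species aggregation of
literature LC50 records, an exposure-duration check, Pagel's lambda by
profile maximum likelihood with a likelihood-ratio test against lambda = 0,
Blomberg's K with a tip-shuffling randomization test, and the Mantel
matrix-correlation test between patristic distance and pairwise trait
difference.  A random-walk Brownian-motion process on the tree is the null
evolutionary model throughout: under it the trait vector is multivariate
normal with covariance sigma^2 * C, where C holds shared root-to-MRCA path
lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .tree import DistanceMatrix, PhyloCovariance, PhyloTree, grafen_branch_lengths, patristic_distances, phylo_vcv, prune_to_taxa

logger = logging.getLogger("evotox")

TRAIT_COLUMNS = ("species", "study", "lc50_mg_l", "duration_h", "phylum", "class", "group")


# ---------------------------------------------------------------------------
# Trait dataset
# ---------------------------------------------------------------------------

def load_trait_csv(path) -> pd.DataFrame:
    """Read a trait table (species, study, lc50_mg_l, duration_h, phylum, class, group)."""
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait CSV missing columns: {missing}")
    validate_trait_records(df)
    return df


def validate_trait_records(records: pd.DataFrame) -> None:
    if len(records) == 0:
        raise ValueError("empty trait table")
    lc50 = pd.to_numeric(records["lc50_mg_l"], errors="coerce")
    if lc50.isna().any() or (lc50 <= 0).any():
        bad = records.loc[lc50.isna() | (lc50 <= 0), "species"].tolist()
        raise ValueError(f"non-positive or missing LC50 for: {bad}")


def aggregate_species(records: pd.DataFrame) -> pd.Series:
    """One trait value per species: mean within study, then mean across studies.

    Multiple estimates reported by a single study are first averaged to a
    study-level mean; species means are then means of the study means, so a
    study contributing many estimates does not dominate.
    """
    validate_trait_records(records)
    study_means = records.groupby(["species", "study"], sort=True)["lc50_mg_l"].mean()
    values = study_means.groupby("species").mean()
    values.name = "lc50_mg_l"
    return values


@dataclass(frozen=True)
class DurationTestResult:
    f_stat: float
    df: tuple[int, int]
    p_value: float
    group_sizes: dict


def duration_effect_test(records: pd.DataFrame) -> DurationTestResult:
    """One-way OLS F test of LC50 on exposure-duration category.

    Used to justify pooling estimates from different acute exposure windows
    into a single per-species trait.
    """
    groups = {int(d): g["lc50_mg_l"].to_numpy(float) for d, g in records.groupby("duration_h")}
    k = len(groups)
    n = sum(len(v) for v in groups.values())
    if k < 2:
        raise ValueError("need at least two duration groups")
    if n - k < 1:
        raise ValueError("no residual degrees of freedom")
    grand = np.concatenate(list(groups.values())).mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df1, df2 = k - 1, n - k
    if ssb <= 1e-12 * max(1.0, abs(grand)) ** 2:
        f = 0.0
    else:
        msw = ssw / df2
        f = np.inf if msw == 0 else (ssb / df1) / msw
    p = float(stats.f.sf(f, df1, df2))
    return DurationTestResult(float(f), (df1, df2), p, {d: len(v) for d, v in groups.items()})


# ---------------------------------------------------------------------------
# Brownian-motion likelihood machinery
# ---------------------------------------------------------------------------

def lambda_max(C: PhyloCovariance) -> float:
    """Largest feasible Pagel's lambda: max diagonal over max off-diagonal."""
    c = C.matrix
    off = c[~np.eye(c.shape[0], dtype=bool)]
    m = float(np.max(np.abs(off))) if off.size else 0.0
    return np.inf if m == 0 else float(np.max(np.diag(c))) / m


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Scale off-diagonal covariance by ``lam``; the diagonal is untouched."""
    if lam < 0 or lam > lambda_max(C) + 1e-12:
        raise ValueError(f"lambda {lam} outside feasible range [0, {lambda_max(C)}]")
    c = C.matrix * lam
    np.fill_diagonal(c, np.diag(C.matrix))
    return PhyloCovariance(C.labels, c)


def bm_profile_loglik(x: np.ndarray, C: PhyloCovariance) -> tuple[float, float, float]:
    """Profile log-likelihood of a Brownian model with covariance sigma^2 C.

    The GLS mean and the ML variance (divisor n) are profiled out
    analytically; returns ``(logL, mu_hat, sigma2_hat)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(x)):
        raise ValueError("trait vector must be finite")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; Brownian variance is unidentified")
    try:
        cf = cho_factor(C.matrix, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular phylogenetic covariance: {exc}") from None
    ones = np.ones(n)
    ci_x = cho_solve(cf, x)
    ci_1 = cho_solve(cf, ones)
    mu = float(ones @ ci_x / (ones @ ci_1))
    r = x - mu
    sigma2 = float(r @ cho_solve(cf, r) / n)
    if sigma2 <= 0:
        raise ValueError("zero GLS residual variance")
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return float(loglik), mu, sigma2


@dataclass(frozen=True)
class LambdaResult:
    lambda_hat: float
    loglik: float
    loglik_zero: float
    p_value: float
    n_species: int


def _align_trait_tree(x, tree: PhyloTree) -> tuple[np.ndarray, PhyloTree, list[str]]:
    """Intersect a labelled trait vector with the tree; prune as needed."""
    if isinstance(x, Mapping):
        x = pd.Series(x)
    if isinstance(x, pd.Series):
        tips = tree.tip_labels
        common = [t for t in tips if t in x.index]
        dropped = sorted(set(x.index) - set(tips))
        if len(common) < len(tips):
            if len(common) < 2:
                raise ValueError("fewer than 2 species shared between trait vector and tree")
            tree = prune_to_taxa(tree, common)
        vec = x.loc[list(tree.tip_labels)].to_numpy(float)
        return vec, tree, dropped
    vec = np.asarray(x, dtype=float)
    if vec.size != tree.n_tips:
        raise ValueError("unlabelled trait vector length must equal the number of tips")
    return vec, tree, []


def estimate_lambda(x, tree: PhyloTree, tol: float = 1e-8) -> LambdaResult:
    """ML estimate of Pagel's lambda with a chi-square(1) LR test of signal.

    The profile likelihood is maximized over the feasible interval
    ``[0, lambda_max]`` by bounded scalar optimization restarted on three
    subintervals (the profile can be multimodal near the boundary), and the
    interval endpoints are checked explicitly.
    """
    vec, tree, _ = _align_trait_tree(x, tree)
    if tree.n_tips < 4:
        raise ValueError("need at least 4 species for lambda estimation")
    C = phylo_vcv(tree)
    # search on [0, min(1, lambda_max)]: lambda is defined as scaling the
    # between-species correlation from none (0) to full Brownian motion (1),
    # and the algebraic feasibility bound (which makes C exactly singular)
    # can exceed 1 on trees with near-identical tips
    hi = lambda_max(C)
    hi = 1.0 if not np.isfinite(hi) else min(1.0, hi * (1.0 - 1e-6))

    def negll(lam: float) -> float:
        try:
            return -bm_profile_loglik(vec, lambda_transform(C, lam))[0]
        except ValueError:
            return np.inf  # numerically singular covariance near the bound

    candidates = [(0.0, negll(0.0)), (hi, negll(hi))]
    edges = np.linspace(0.0, hi, 4)
    for a, b in zip(edges[:-1], edges[1:]):
        res = minimize_scalar(negll, bounds=(a, b), method="bounded", options={"xatol": tol})
        candidates.append((float(res.x), float(res.fun)))
    lam_hat, nll = min(candidates, key=lambda t: t[1])
    loglik = -nll
    loglik0 = -candidates[0][1]
    lr = max(0.0, 2.0 * (loglik - loglik0))
    p = float(stats.chi2.sf(lr, df=1))
    return LambdaResult(lam_hat, loglik, loglik0, p, tree.n_tips)


def blomberg_k(x, tree: PhyloTree) -> float:
    """Blomberg's K: observed versus Brownian-expected phylogenetic dependence.

    K = (MSE0/MSE) / E_BM[MSE0/MSE], with MSE0 the ordinary mean square about
    the GLS mean, MSE the phylogenetically corrected mean square, and the
    Brownian expectation [tr(C) - n / sum(C^-1)] / (n - 1).  K equals 1 under
    Brownian motion on the given tree and 1 exactly on a star phylogeny.
    """
    vec, tree, _ = _align_trait_tree(x, tree)
    if tree.n_tips < 4:
        raise ValueError("need at least 4 species")
    C = phylo_vcv(tree)
    return _blomberg_k_from_cov(vec, C.matrix)


def _blomberg_k_from_cov(vec: np.ndarray, c: np.ndarray) -> float:
    n = vec.size
    if np.ptp(vec) == 0:
        raise ValueError("trait is constant")
    cf = cho_factor(c, lower=True)
    ones = np.ones(n)
    ci_1 = cho_solve(cf, ones)
    denom_1 = float(ones @ ci_1)
    mu = float(ones @ cho_solve(cf, vec) / denom_1)
    r = vec - mu
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ cho_solve(cf, r)) / (n - 1)
    expected = (float(np.trace(c)) - n / denom_1) / (n - 1)
    return (mse0 / mse) / expected


@dataclass(frozen=True)
class KTestResult:
    k_stat: float
    p_value: float
    n_perm: int
    seed: int


def permutation_test_k(x, tree: PhyloTree, n_perm: int = 999, seed: int = 0) -> KTestResult:
    """Randomization test for K: shuffle trait values across tips.

    Signal is summarized by the phylogenetic mean square error (smaller MSE =
    more signal); the one-tailed p-value uses +1 smoothing:
    ``p = (1 + #{MSE_perm <= MSE_obs}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    vec, tree, _ = _align_trait_tree(x, tree)
    C = phylo_vcv(tree)
    c = C.matrix
    n = vec.size
    cf = cho_factor(c, lower=True)
    ones = np.ones(n)
    ci_1 = cho_solve(cf, ones)
    denom_1 = float(ones @ ci_1)

    def mse(v: np.ndarray) -> float:
        mu = float(ones @ cho_solve(cf, v) / denom_1)
        r = v - mu
        return float(r @ cho_solve(cf, r)) / (n - 1)

    obs = mse(vec)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if mse(rng.permutation(vec)) <= obs + 1e-12:
            count += 1
    k = _blomberg_k_from_cov(vec, c)
    return KTestResult(k, (1 + count) / (1 + n_perm), n_perm, seed)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int
    n: int


def trait_distance_matrix(species_values: pd.Series) -> DistanceMatrix:
    """Pairwise absolute trait differences (1-D Euclidean distance)."""
    if len(species_values) < 2:
        raise ValueError("need at least 2 species")
    v = species_values.to_numpy(float)
    return DistanceMatrix(tuple(species_values.index), np.abs(v[:, None] - v[None, :]))


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999, seed: int = 0) -> MantelResult:
    """One-tailed Mantel test for positive matrix association.

    Pearson correlation of the upper triangles; the null distribution comes
    from applying a single random label permutation simultaneously to the
    rows and columns of ``d2``.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels and order")
    n = len(d1.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    if n == 3:
        logger.warning("Mantel test with n=3 has almost no permutation resolution")
    iu = np.triu_indices(n, 1)
    v1 = d1.values[iu]
    m2 = d2.values
    v2 = m2[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero variance in a distance matrix; Mantel r undefined")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        vp = m2[np.ix_(p, p)][iu]
        if np.corrcoef(v1, vp)[0, 1] >= r_obs - 1e-12:
            count += 1
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm, seed, n)


# ---------------------------------------------------------------------------
# Suite over taxonomic groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalResult:
    group: str
    n_species: int
    lambda_hat: float
    loglik_lambda: float
    loglik_zero: float
    p_lambda: float
    k_stat: float
    p_k: float
    mantel_r: float
    mantel_p: float
    n_perm: int
    seed: int
    trait_scale: str


@dataclass
class SignalSuiteResult:
    table: pd.DataFrame
    results: list = field(default_factory=list)
    skipped_groups: list = field(default_factory=list)
    species_not_in_tree: list = field(default_factory=list)


def run_signal_suite(
    species_values: pd.Series,
    tree: PhyloTree,
    groups: Optional[Sequence[tuple[str, Iterable[str]]]] = None,
    n_perm: int = 999,
    seed: int = 0,
    trait_scale: str = "raw",
    regrafen_after_prune: bool = False,
    rho: float = 1.0,
) -> SignalSuiteResult:
    """Lambda, K and Mantel statistics for each configured species group.

    Groups with fewer than 4 species present in the tree are skipped with a
    logged warning.  Species in the trait table but absent from the tree are
    reported, never silently dropped.  ``trait_scale='log10'`` analyses
    log10(LC50); the default analyses raw mg/L values.
    """
    if groups is None:
        groups = [("all", list(species_values.index))]
    if len(groups) == 0:
        raise ValueError("empty group list")
    if trait_scale not in ("raw", "log10"):
        raise ValueError("trait_scale must be 'raw' or 'log10'")
    values = species_values.astype(float)
    if trait_scale == "log10":
        values = np.log10(values)

    if not tree.has_branch_lengths:
        tree = grafen_branch_lengths(tree, rho=rho)
    tip_set = set(tree.tip_labels)
    missing = sorted(set(values.index) - tip_set)
    if missing:
        logger.warning("species absent from the tree (dropped): %s", missing)

    out = SignalSuiteResult(table=pd.DataFrame(), species_not_in_tree=missing)
    seeds = np.random.SeedSequence(seed).spawn(len(groups))
    rows = []
    for (name, members), ss in zip(groups, seeds):
        members = [m for m in members if m in tip_set and m in values.index]
        if len(members) < 4:
            logger.warning("group %r skipped: only %d usable species", name, len(members))
            out.skipped_groups.append((name, len(members)))
            continue
        sub = prune_to_taxa(tree, members)
        if regrafen_after_prune:
            sub = grafen_branch_lengths(sub, rho=rho)
        gvals = values.loc[list(sub.tip_labels)]
        gseed = int(ss.generate_state(1)[0] % (2**31 - 1))
        lam = estimate_lambda(gvals, sub)
        ktest = permutation_test_k(gvals, sub, n_perm=n_perm, seed=gseed)
        mant = mantel_test(
            patristic_distances(sub), trait_distance_matrix(gvals), n_perm=n_perm, seed=gseed
        )
        res = SignalResult(
            group=name,
            n_species=len(members),
            lambda_hat=lam.lambda_hat,
            loglik_lambda=lam.loglik,
            loglik_zero=lam.loglik_zero,
            p_lambda=lam.p_value,
            k_stat=ktest.k_stat,
            p_k=ktest.p_value,
            mantel_r=mant.r,
            mantel_p=mant.p_value,
            n_perm=n_perm,
            seed=gseed,
            trait_scale=trait_scale,
        )
        out.results.append(res)
        rows.append(res.__dict__)
    out.table = pd.DataFrame(rows)
    return out
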