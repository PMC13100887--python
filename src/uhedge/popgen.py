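"""Individual and population genetic statistics.

Covers the summary statistics of a reduced-representation SNP study along an
urbanisation gradient: individual standardised heterozygosity (Hs), observed
and expected heterozygosity with the small-sample (2n/(2n-1)) correction,
allelic richness rarefied to a common gene count, private alleles,
Weir-Cockerham theta (overall and pairwise, with a locus-bootstrap CI),
Queller-Goodnight pairwise relatedness, Euclidean genetic distance between
individuals, PCA, the second-difference (Evanno) statistic for choosing the
number of clusters from replicate clustering log-likelihoods, pairwise
rank-sum comparisons with Benjamini-Hochberg correction, and global/local
Moran's I with an Hs-versus-urbanisation linear model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .connectivity import PairwiseDistanceMatrix
from .genotype_io import MISSING, GenotypeMatrix


class PopgenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# individual heterozygosity
# ---------------------------------------------------------------------------

def standardized_heterozygosity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual heterozygosity standardised by the sample mean.

    Returns a table with heterozygous-site count, non-missing site count,
    the proportion heterozygous, and Hs = proportion / mean(proportion);
    mean(Hs) over included individuals is exactly 1.  Individuals with no
    non-missing sites are excluded with a warning.
    """
    het = (gm.genotypes == 1).sum(axis=1)
    called = (gm.genotypes != MISSING).sum(axis=1)
    ok = called > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} individuals have no called sites; excluded")
    if ok.sum() < 2:
        raise PopgenError("need at least two individuals with called sites")
    prop = np.full(len(gm.samples), np.nan)
    prop[ok] = het[ok] / called[ok]
    hs = prop / np.nanmean(prop[ok])
    df = pd.DataFrame(
        {
            "het_sites": het,
            "called_sites": called,
            "prop_het": prop,
            "hs": hs,
        },
        index=pd.Index(gm.samples, name="id"),
    )
    return df.loc[np.asarray(ok)]


# ---------------------------------------------------------------------------
# population diversity
# ---------------------------------------------------------------------------

def _pop_arrays(gm: GenotypeMatrix, pops: pd.Series):
    """Per-population (n, alt_count, het_count) arrays over loci."""
    labels = pd.Series(pops).reindex(gm.samples)
    if labels.isna().any():
        raise PopgenError("every sample needs a population label")
    out = {}
    for pop in pd.unique(labels):
        idx = np.nonzero((labels == pop).to_numpy())[0]
        g = gm.genotypes[idx]
        nonmiss = g != MISSING
        n = nonmiss.sum(axis=0)
        alt = np.where(g == MISSING, 0, g).sum(axis=0)
        het = (g == 1).sum(axis=0)
        out[pop] = (idx, n.astype(float), alt.astype(float), het.astype(float))
    return out


def ho_he(gm: GenotypeMatrix, pops: pd.Series) -> pd.DataFrame:
    """Observed and expected heterozygosity per population.

    Ho averages the observed heterozygote fraction over loci; He averages
    2p(1-p) corrected by 2n/(2n-1); Fis = 1 - Ho/He.  Loci monomorphic in a
    population contribute zero to both means.
    """
    arrays = _pop_arrays(gm, pops)
    rows = []
    for pop, (idx, n, alt, het) in arrays.items():
        if idx.size == 0:
            raise PopgenError(f"population {pop!r} is empty")
        use = n > 0
        if not use.any():
            raise PopgenError(f"population {pop!r} has no called genotypes")
        p = np.zeros_like(n)
        p[use] = alt[use] / (2 * n[use])
        ho = float(np.mean(het[use] / n[use]))
        corr = np.ones_like(n)
        corr[use] = 2 * n[use] / np.maximum(2 * n[use] - 1, 1)
        he = float(np.mean(2 * p[use] * (1 - p[use]) * corr[use]))
        fis = 1 - ho / he if he > 0 else np.nan
        rows.append({"population": pop, "n": idx.size, "ho": ho, "he": he, "fis": fis})
    return pd.DataFrame(rows).set_index("population")


def rarefied_allelic_richness(
    gm: GenotypeMatrix, pops: pd.Series, g: int | None = None
) -> pd.Series:
    """Allelic richness rarefied to ``g`` genes per population.

    For a locus with N non-missing genes of which N_a copies are allele a,
    the expected allele count in a sample of g genes is
    ``sum_a [1 - C(N - N_a, g) / C(N, g)]``; the population value averages
    over loci with N >= g.  Default g is twice the smallest population size
    (two genes per diploid).
    """
    arrays = _pop_arrays(gm, pops)
    if g is None:
        g = 2 * min(idx.size for idx, *_ in arrays.values())
    if g < 2:
        raise PopgenError("rarefaction size g must be at least 2 genes")

    def _log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = {}
    for pop, (idx, n, alt, het) in arrays.items():
        genes = 2 * n
        usable = genes >= g
        if not usable.any():
            out[pop] = np.nan
            continue
        N = genes[usable]
        counts = np.stack([N - alt[usable], alt[usable]])  # ref, alt copies
        ar = np.zeros(N.shape)
        for a in range(2):
            Na = counts[a]
            rem = N - Na
            term = np.zeros_like(N)
            has = rem >= g  # C(rem, g) nonzero only when rem >= g
            term[has] = np.exp(_log_comb(rem[has], g) - _log_comb(N[has], g))
            ar += np.where(Na > 0, 1 - term, 0.0)
            # alleles absent from the sample (Na == 0) contribute exactly 0:
            # 1 - C(N, g)/C(N, g) = 0, handled by the Na > 0 guard above
        out[pop] = float(ar.mean())
    return pd.Series(out, name="ar")


def private_alleles(gm: GenotypeMatrix, pops: pd.Series) -> pd.Series:
    """Count alleles observed in exactly one population (over all loci)."""
    arrays = _pop_arrays(gm, pops)
    if len(arrays) < 2:
        raise PopgenError("private alleles need at least two populations")
    names = list(arrays)
    ref_present = []
    alt_present = []
    for pop in names:
        _, n, alt, _ = arrays[pop]
        alt_present.append(alt > 0)
        ref_present.append((2 * n - alt) > 0)
    alt_present = np.stack(alt_present)  # pops x loci
    ref_present = np.stack(ref_present)
    counts = {}
    for k, pop in enumerate(names):
        only_alt = alt_present[k] & (alt_present.sum(axis=0) == 1)
        only_ref = ref_present[k] & (ref_present.sum(axis=0) == 1)
        counts[pop] = int(only_alt.sum() + only_ref.sum())
    return pd.Series(counts, name="private_alleles")


def diversity_summary(
    gm: GenotypeMatrix, pops: pd.Series, rarefaction_g: int | None = None
) -> pd.DataFrame:
    """Per-population table: n, private alleles, Ar, Ho, He, Fis."""
    hh = ho_he(gm, pops)
    ar = rarefied_allelic_richness(gm, pops, rarefaction_g)
    pa = private_alleles(gm, pops)
    out = hh.join(ar).join(pa)
    return out[["n", "private_alleles", "ar", "ho", "he", "fis"]]


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    estimate: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    scope: str = "overall"
    n_loci_used: int = 0


def _wc_components(gm: GenotypeMatrix, pops: pd.Series):
    """Per-locus variance components (a, b, c) of the 1984 theta estimator."""
    arrays = _pop_arrays(gm, pops)
    n_mat = np.stack([v[1] for v in arrays.values()])  # pops x loci
    alt = np.stack([v[2] for v in arrays.values()])
    het = np.stack([v[3] for v in arrays.values()])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_mat > 0, alt / (2 * n_mat), 0.0)
        h = np.where(n_mat > 0, het / n_mat, 0.0)
    present = n_mat > 0
    r = present.sum(axis=0).astype(float)
    nsum = n_mat.sum(axis=0)
    ok = (r >= 2) & (nsum > r)  # need >= 2 pops and nbar > 1
    nbar = np.where(ok, nsum / np.maximum(r, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n_mat**2).sum(axis=0) / np.maximum(nsum, 1)) / np.maximum(r - 1, 1)
        pbar = (n_mat * p).sum(axis=0) / np.maximum(nsum, 1)
        s2 = (n_mat * (p - pbar) ** 2).sum(axis=0) / (np.maximum(r - 1, 1) * nbar)
        hbar = (n_mat * h).sum(axis=0) / np.maximum(nsum, 1)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    ok &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (nc > 0)
    return a[ok], b[ok], c[ok]


def wc_fst(
    gm: GenotypeMatrix,
    pops: pd.Series,
    pairwise: bool = False,
    n_boot: int = 0,
    seed: int | None = None,
) -> FstResult | pd.DataFrame:
    """Weir-Cockerham theta as a ratio of summed variance components.

    ``pairwise=True`` returns a symmetric population-by-population frame;
    ``n_boot > 0`` adds a seeded percentile bootstrap CI over loci.
    """
    labels = pd.Series(pops).reindex(gm.samples)
    if pairwise:
        names = list(pd.unique(labels))
        mat = pd.DataFrame(0.0, index=names, columns=names)
        for p1, p2 in itertools.combinations(names, 2):
            idx = np.nonzero(labels.isin([p1, p2]).to_numpy())[0]
            sub = gm.take_samples(idx)
            res = wc_fst(sub, labels.iloc[idx], n_boot=0)
            mat.loc[p1, p2] = mat.loc[p2, p1] = res.estimate
        return mat
    a, b, c = _wc_components(gm, labels)
    denom = (a + b + c).sum()
    if a.size == 0 or denom == 0:
        return FstResult(np.nan, scope="overall", n_loci_used=0)
    theta = float(a.sum() / denom)
    lo = hi = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        thetas = np.empty(n_boot)
        for i in range(n_boot):
            pick = rng.integers(0, a.size, a.size)
            d = (a[pick] + b[pick] + c[pick]).sum()
            thetas[i] = a[pick].sum() / d if d != 0 else np.nan
        lo, hi = (float(v) for v in np.nanpercentile(thetas, [2.5, 97.5]))
    return FstResult(theta, lo, hi, scope="overall", n_loci_used=int(a.size))


# ---------------------------------------------------------------------------
# pairwise relatedness (Queller & Goodnight)
# ---------------------------------------------------------------------------

def qg_relatedness(gm: GenotypeMatrix) -> pd.DataFrame:
    """Queller-Goodnight pairwise relatedness on biallelic dosages.

    Reference allele frequencies are recomputed for each pair from all other
    individuals, and the two directional estimates are averaged.  Pairs with
    no usable loci (or an undefined denominator) are NaN.
    """
    if gm.n_samples < 3:
        raise PopgenError("relatedness needs at least three individuals")
    g = gm.genotypes.astype(float)
    miss = gm.genotypes == MISSING
    g_filled = np.where(miss, 0.0, g)
    alt_total = g_filled.sum(axis=0)
    n_total = (~miss).sum(axis=0).astype(float)
    n = gm.n_samples
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~miss[i] & ~miss[j]
            n_excl = n_total - (~miss[i]).astype(float) - (~miss[j]).astype(float)
            usable = shared & (n_excl > 0)
            if not usable.any():
                continue
            p = (alt_total - g_filled[i] - g_filled[j])[usable] / (2 * n_excl[usable])
            gi, gj = g[i, usable], g[j, usable]

            def _direction(gx, gy):
                num = np.zeros_like(gx)
                den = np.zeros_like(gx)
                hom_alt = gx == 2
                hom_ref = gx == 0
                num[hom_alt] = gy[hom_alt] - 2 * p[hom_alt]
                den[hom_alt] = 2 - 2 * p[hom_alt]
                num[hom_ref] = (2 - gy[hom_ref]) - 2 * (1 - p[hom_ref])
                den[hom_ref] = 2 * p[hom_ref]
                return num.sum(), den.sum()

            n1, d1 = _direction(gi, gj)
            n2, d2 = _direction(gj, gi)
            vals = [nm / dn for nm, dn in ((n1, d1), (n2, d2)) if dn != 0]
            if vals:
                out[i, j] = out[j, i] = float(np.mean(vals))
    return pd.DataFrame(out, index=gm.samples, columns=gm.samples)


# ---------------------------------------------------------------------------
# genetic distance and PCA
# ---------------------------------------------------------------------------

def genetic_distance(gm: GenotypeMatrix) -> PairwiseDistanceMatrix:
    """Euclidean distance on genotype dosages with missing-data rescaling.

    Squared differences are summed over loci called in both individuals and
    scaled by L / L_shared so pairs with different amounts of missing data
    stay comparable; pairs sharing no loci are NaN with a warning.
    """
    if gm.n_samples < 2:
        raise PopgenError("need at least two individuals")
    g = gm.genotypes.astype(float)
    g[gm.genotypes == MISSING] = np.nan
    n, L = g.shape
    vals = np.zeros((n, n))
    flagged = False
    for i in range(n):
        diff = g[i] - g  # broadcast, nan where either missing
        shared = np.sum(~np.isnan(diff), axis=1).astype(float)
        ss = np.nansum(diff**2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals[i] = np.sqrt(ss * L / shared)
        if (shared == 0).any():
            flagged = True
    np.fill_diagonal(vals, 0.0)
    if flagged:
        warnings.warn("some pairs share no called loci; distance undefined (NaN)")
    return PairwiseDistanceMatrix("genetic", list(gm.samples), vals, units="dosage")


def pca(gm: GenotypeMatrix, scale: bool = False, n_components: int | None = None):
    """PCA of the genotype matrix with per-locus mean imputation.

    Returns (coordinates, explained variance ratio); axes ordered by
    variance, sign unconstrained.
    """
    if gm.n_samples < 2:
        raise PopgenError("PCA needs at least two individuals")
    g = gm.genotypes.astype(float)
    g[gm.genotypes == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    idx = np.where(np.isnan(g))
    g[idx] = mean[idx[1]]
    g -= mean
    if scale:
        sd = g.std(axis=0, ddof=0)
        g /= np.where(sd > 0, sd, 1.0)
    u, s, _ = np.linalg.svd(g, full_matrices=False)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    coords = u * s
    if n_components is not None:
        coords = coords[:, :n_components]
        ratio = ratio[:n_components]
    return coords, ratio


# ---------------------------------------------------------------------------
# cluster-number (Evanno) post-processing
# ---------------------------------------------------------------------------

def evanno_delta_k(table: pd.DataFrame) -> pd.DataFrame:
    """Second-difference statistic over replicate clustering log-likelihoods.

    Input columns: K, replicate, lnP.  For interior K,
    ``delta_k = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))``;
    the end K values and zero-sd rows are NaN (flagged in ``defined``).
    """
    need = {"K", "replicate", "lnP"}
    if not need <= set(table.columns):
        raise PopgenError(f"table must have columns {sorted(need)}")
    grp = table.groupby("K")["lnP"]
    ks = np.array(sorted(grp.groups))
    if ks.size < 3 or np.any(np.diff(ks) != 1):
        raise PopgenError("need at least three consecutive K values")
    if (grp.count() < 2).any():
        raise PopgenError("need at least two replicates per K")
    mean = grp.mean().loc[ks].to_numpy()
    sd = grp.std(ddof=1).loc[ks].to_numpy()
    lprime = np.full(ks.size, np.nan)
    lprime[1:] = np.diff(mean)
    ldoub = np.full(ks.size, np.nan)
    ldoub[1:-1] = np.abs(mean[2:] - 2 * mean[1:-1] + mean[:-2])
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = ldoub / sd
    delta[sd == 0] = np.nan
    return pd.DataFrame(
        {
            "K": ks,
            "mean_lnP": mean,
            "sd_lnP": sd,
            "lprime": lprime,
            "abs_lsecond": ldoub,
            "delta_k": delta,
            "defined": ~np.isnan(delta),
        }
    )


# ---------------------------------------------------------------------------
# pairwise population comparisons
# ---------------------------------------------------------------------------

def compare_populations(values_by_pop: dict[str, np.ndarray]) -> pd.DataFrame:
    """Two-sided rank-sum tests between all population pairs on per-locus
    statistic vectors, Benjamini-Hochberg adjusted across the pairs."""
    names = list(values_by_pop)
    if any(len(values_by_pop[p]) < 2 for p in names):
        raise PopgenError("each population needs at least two values")
    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        va = np.asarray(values_by_pop[a], dtype=float)
        vb = np.asarray(values_by_pop[b], dtype=float)
        pooled = np.concatenate([va, vb])
        if np.all(pooled == pooled[0]):
            raw.append(1.0)
            continue
        raw.append(float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue))
    adj = multipletests(raw, method="fdr_bh")[1] if raw else []
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), p in zip(pairs, adj):
        out.loc[a, b] = out.loc[b, a] = p
    return out


# ---------------------------------------------------------------------------
# spatial autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class SpatialAutocorrResult:
    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    local: np.ndarray = field(default_factory=lambda: np.empty(0))
    defined: bool = True


def knn_weights(coords: np.ndarray, k: int = 8) -> np.ndarray:
    """Row-standardised k-nearest-neighbour weights (ties by index order)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k >= n:
        k = n - 1
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    w = np.zeros((n, n))
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    for i in range(n):
        w[i, nn[i]] = 1.0
    return w / w.sum(axis=1, keepdims=True)


def distance_band_weights(coords: np.ndarray, band_m: float) -> np.ndarray:
    """Row-standardised binary weights within a distance band."""
    d = cdist(coords, coords)
    w = ((d > 0) & (d <= band_m)).astype(float)
    rs = w.sum(axis=1, keepdims=True)
    if (rs == 0).any():
        raise PopgenError("distance band leaves some observations with no neighbour")
    return w / rs


def morans_i(
    values: np.ndarray,
    coords: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    scheme: str = "knn",
    k: int = 8,
    band_m: float | None = None,
) -> SpatialAutocorrResult:
    """Global and local Moran's I with a normal-approximation p-value.

    Weights may be given directly, or built from coordinates with the
    ``knn`` (default, row-standardised 8 nearest neighbours) or
    ``distance_band`` scheme.  Constant inputs are flagged undefined.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise PopgenError("Moran's I needs at least four observations")
    if weights is None:
        if coords is None:
            raise PopgenError("either weights or coordinates are required")
        if scheme == "knn":
            weights = knn_weights(np.asarray(coords), k)
        elif scheme == "distance_band":
            if band_m is None:
                raise PopgenError("distance_band scheme needs band_m")
            weights = distance_band_weights(np.asarray(coords), band_m)
        else:
            raise PopgenError(f"unknown weight scheme {scheme!r}")
    w = np.asarray(weights, dtype=float)
    z = x - x.mean()
    m2 = (z**2).sum() / n
    if m2 == 0:
        return SpatialAutocorrResult(
            np.nan, -1 / (n - 1), np.nan, np.nan, np.nan, np.full(n, np.nan), False
        )
    s0 = w.sum()
    lag = w @ z
    I = (n / s0) * float(z @ lag) / float((z**2).sum())
    e = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e**2
    zscore = (I - e) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(zscore))
    local = (z / m2) * lag
    return SpatialAutocorrResult(float(I), e, float(var), float(zscore), float(p), local)


def fit_hs_urban(
    hs: pd.Series | np.ndarray,
    urban: pd.Series | np.ndarray,
    coords: np.ndarray | None = None,
    weight_kwargs: dict | None = None,
):
    """OLS of individual heterozygosity on urban proportion, plus residual
    spatial autocorrelation under the same weight scheme.

    Returns (fit dict, SpatialAutocorrResult or None).
    """
    import statsmodels.api as sm

    y = np.asarray(hs, dtype=float)
    x = np.asarray(urban, dtype=float)
    if y.size != x.size:
        raise PopgenError("response and predictor lengths differ")
    if y.size < 3:
        raise PopgenError("need at least three observations")
    if np.all(x == x[0]):
        raise PopgenError("urban proportion is constant; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    fit = {
        "intercept": float(model.params[0]),
        "slope": float(model.params[1]),
        "slope_p": float(model.pvalues[1]),
        "r_squared": float(model.rsquared),
    }
    autocorr = None
    if coords is not None:
        autocorr = morans_i(model.resid, coords=coords, **(weight_kwargs or {}))
    return fit, autocorr
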