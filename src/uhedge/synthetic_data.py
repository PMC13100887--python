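"""Synthetic landscapes, pedigrees, and genotypes with known ground truth.

Every generator is a pure function of its parameters and a seed, so each
downstream stage (filtering, diversity statistics, differentiation, landscape
model selection) can be validated against the truth that produced the data.

Three genotype models are provided:

* an island model (Balding-Nichols): population allele frequencies drawn
  around a shared ancestral frequency with variance ``Fst * p * (1 - p)``,
  giving direct control over the expected differentiation;
* an isolation-by-resistance model: location-level allele-frequency
  deviations on the logit scale with covariance ``sigma2 * exp(-d/phi)`` in
  commute distance ``d`` over a resistance surface, so genetic distance grows
  with landscape cost by construction;
* fair Mendelian transmission down an explicit pedigree, for validating
  relatedness estimators against known relationship classes.

A degrader turns any genotype matrix into annotated VCF-style variant records
(per-genotype depths, site quality, mapping quality, missingness) so the
post-calling filter chain has realistic inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.special import expit, logit

from .connectivity import build_transition_graph, commute_distance
from .genotype_io import MISSING, GenotypeMatrix, VariantRecord
from .resistance import LandcoverRaster, ResistanceSurface


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# landscape generation
# ---------------------------------------------------------------------------

@dataclass
class ClassSpec:
    """One landcover class: an area class (smoothed-noise patches) or a
    linear feature (a strip of the given width spanning the grid)."""

    name: str
    weight: float = 1.0
    kind: str = "patch"  # patch | linear
    orientation: str = "vertical"  # linear only
    width: int = 1  # cells, linear only
    wander: int = 0  # max +-cells of centreline drift per row/col


@dataclass
class LandscapeSpec:
    nrows: int = 32
    ncols: int = 32
    resolution: float = 5.0
    classes: list[ClassSpec] = field(default_factory=list)
    smoothing_sigma: float = 3.0  # cells; patch granularity
    origin: tuple[float, float] = (0.0, 0.0)


def generate_landscape(spec: LandscapeSpec, seed: int) -> LandcoverRaster:
    """Generate a categorical landcover raster.

    Patch classes partition the grid by thresholding one smoothed Gaussian
    noise field at quantiles proportional to the class weights; linear
    classes are drawn on top as strips at least one cell wide that span the
    grid (optionally wandering).  Deterministic per (spec, seed).
    """
    if spec.nrows < 8 or spec.ncols < 8:
        raise SyntheticError("grid must be at least 8x8")
    if spec.resolution <= 0:
        raise SyntheticError("resolution must be positive")
    if not spec.classes:
        raise SyntheticError("class list is empty")
    patches = [c for c in spec.classes if c.kind == "patch"]
    linears = [c for c in spec.classes if c.kind == "linear"]
    if patches and sum(c.weight for c in patches) <= 0:
        raise SyntheticError("patch class weights must sum to > 0")

    rng = np.random.default_rng(seed)
    codes = np.zeros((spec.nrows, spec.ncols), dtype=np.int32)
    legend = {0: "Unclassified"}
    code_of = {c.name: i + 1 for i, c in enumerate(spec.classes)}
    for c in spec.classes:
        legend[code_of[c.name]] = c.name

    if patches:
        fld = ndimage.gaussian_filter(
            rng.normal(size=(spec.nrows, spec.ncols)), spec.smoothing_sigma
        )
        w = np.array([c.weight for c in patches], dtype=float)
        cum = np.cumsum(w) / w.sum()
        qs = np.quantile(fld, cum[:-1]) if len(patches) > 1 else np.array([])
        assign = np.digitize(fld, qs)
        for k, c in enumerate(patches):
            codes[assign == k] = code_of[c.name]

    for c in linears:
        width = max(1, int(c.width))
        if c.orientation == "vertical":
            span, across = spec.nrows, spec.ncols
        else:
            span, across = spec.ncols, spec.nrows
        center = int(rng.integers(width // 2, max(across - width // 2, width // 2 + 1)))
        for t in range(span):
            if c.wander:
                center += int(rng.integers(-c.wander, c.wander + 1))
                center = int(np.clip(center, width // 2, across - 1 - width // 2))
            lo = max(0, center - width // 2)
            hi = min(across, lo + width)
            if c.orientation == "vertical":
                codes[t, lo:hi] = code_of[c.name]
            else:
                codes[lo:hi, t] = code_of[c.name]
    return LandcoverRaster(codes, spec.resolution, spec.origin, legend)


def sample_locations(
    surface: ResistanceSurface,
    n_locations: int,
    seed: int,
    min_separation_cells: float | None = None,
) -> pd.DataFrame:
    """Pick spread-out traversable cell centres as sampling locations.

    Greedy farthest-point selection from a seeded random start, restricted to
    the largest 8-connected traversable component (so walled-off pockets are
    never sampled); returns an (id, x, y, row, col) frame.
    """
    rng = np.random.default_rng(seed)
    labels, ncomp = ndimage.label(~surface.barrier, structure=np.ones((3, 3)))
    if ncomp == 0:
        raise SyntheticError("surface has no traversable cells")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, ncomp + 1))
    main = 1 + int(np.argmax(sizes))
    rr, cc = np.nonzero(labels == main)
    if rr.size < n_locations:
        raise SyntheticError("not enough traversable cells for the locations")
    pts = np.column_stack([rr, cc]).astype(float)
    chosen = [int(rng.integers(rr.size))]
    d = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    while len(chosen) < n_locations:
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    if min_separation_cells is not None:
        sep = min(
            np.linalg.norm(pts[a] - pts[b])
            for i, a in enumerate(chosen)
            for b in chosen[i + 1 :]
        )
        if sep < min_separation_cells:
            raise SyntheticError("locations could not be separated enough")
    rows = []
    for k, i in enumerate(chosen):
        r, c = int(pts[i, 0]), int(pts[i, 1])
        x, y = surface.cell_center(r, c)
        rows.append({"id": f"loc{k + 1}", "x": x, "y": y, "row": r, "col": c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# island-model genotypes
# ---------------------------------------------------------------------------

def simulate_island_genotypes(
    n_pops: int,
    n_per_pop: int,
    n_loci: int,
    fst_target: float,
    seed: int,
) -> tuple[GenotypeMatrix, pd.Series]:
    """Balding-Nichols island model.

    Ancestral frequencies are Uniform(0.1, 0.9); each population's frequency
    is Beta-distributed with mean p and variance ``fst_target * p * (1-p)``;
    genotypes are Binomial(2, p_pop).  ``fst_target = 0`` collapses to
    panmixia.
    """
    if not 0 <= fst_target < 1:
        raise SyntheticError("fst_target must be in [0, 1)")
    if min(n_pops, n_per_pop, n_loci) < 1:
        raise SyntheticError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=n_loci)
    if fst_target == 0:
        p_pop = np.tile(p_anc, (n_pops, 1))
    else:
        shape = (1 - fst_target) / fst_target
        p_pop = rng.beta(p_anc * shape, (1 - p_anc) * shape, size=(n_pops, n_loci))
    geno = np.empty((n_pops * n_per_pop, n_loci), dtype=np.int8)
    samples, labels = [], []
    for k in range(n_pops):
        block = rng.binomial(2, p_pop[k], size=(n_per_pop, n_loci)).astype(np.int8)
        geno[k * n_per_pop : (k + 1) * n_per_pop] = block
        samples += [f"P{k + 1}_I{i + 1:03d}" for i in range(n_per_pop)]
        labels += [f"P{k + 1}"] * n_per_pop
    loci = _synthetic_loci(n_loci)
    gm = GenotypeMatrix(samples, loci, geno)
    return gm, pd.Series(labels, index=samples, name="population")


def _synthetic_loci(n_loci: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [f"uce-{j + 1}" for j in range(n_loci)],
            "pos": np.full(n_loci, 500),
            "ref": "A",
            "alt": "T",
            "locus_id": [f"uce-{j + 1}" for j in range(n_loci)],
        }
    )


# ---------------------------------------------------------------------------
# isolation-by-resistance genotypes
# ---------------------------------------------------------------------------

def simulate_ibr_genotypes(
    locations: pd.DataFrame,
    surface: ResistanceSurface,
    n_loci: int,
    phi: float | None = None,
    sigma2: float = 1.0,
    seed: int = 0,
    n_per_location: int = 1,
    epsilon: float = 1e-4,
    scatter_cells: int = 2,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Genotypes whose structure follows commute distance on a surface.

    Per locus, location-level logit-frequency deviations are drawn from a
    zero-mean Gaussian with covariance ``sigma2 * exp(-d_ij / phi)`` where d
    is pairwise commute distance; back-transformed frequencies are clipped to
    [0.01, 0.99] and genotypes drawn Binomial(2, p).  ``phi`` defaults to the
    median pairwise commute distance.  Individuals sharing a location are
    scattered over distinct traversable cells within ``scatter_cells`` of the
    location centre (samples never share exact coordinates in the field).
    Returns the matrix and a metadata frame (id, x, y, location).
    """
    if sigma2 < 0:
        raise SyntheticError("sigma2 must be nonnegative")
    locs = locations.reset_index(drop=True)
    for _, row in locs.iterrows():
        r, c = _cell_of(surface, row["x"], row["y"])
        if surface.barrier[r, c]:
            raise SyntheticError(f"location {row['id']!r} lies on a barrier cell")
    g = build_transition_graph(surface, epsilon=epsilon)
    cd = commute_distance(g, locs)
    d = cd.values
    offdiag = d[np.triu_indices_from(d, k=1)]
    if phi is None:
        phi = float(np.median(offdiag))
    if phi <= 0:
        raise SyntheticError("phi must be positive")
    cov = sigma2 * np.exp(-d / phi)
    # exponential kernels on graph distances can be mildly non-PSD: clip
    evals, evecs = np.linalg.eigh(cov)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))

    rng = np.random.default_rng(seed)
    n_loc = len(locs)
    p_anc = rng.uniform(0.1, 0.9, size=n_loci)
    z = root @ rng.standard_normal(size=(n_loc, n_loci))
    freq = np.clip(expit(logit(p_anc)[None, :] + z), 0.01, 0.99)

    samples, meta_rows, rows = [], [], []
    nr, nc = surface.shape
    comp, _ = ndimage.label(~surface.barrier, structure=np.ones((3, 3)))
    for li, row in locs.iterrows():
        r0, c0 = _cell_of(surface, row["x"], row["y"])
        # distinct traversable cells near the location centre, nearest first
        radius = scatter_cells
        while True:
            cand = [
                (max(abs(dr), abs(dc)), dr * dr + dc * dc, r0 + dr, c0 + dc)
                for dr in range(-radius, radius + 1)
                for dc in range(-radius, radius + 1)
                if 0 <= r0 + dr < nr and 0 <= c0 + dc < nc
                and comp[r0 + dr, c0 + dc] == comp[r0, c0]
            ]
            if len(cand) >= n_per_location or radius > max(nr, nc):
                break
            radius += 1
        if len(cand) < n_per_location:
            raise SyntheticError(
                f"location {row['id']!r} has too few traversable cells nearby"
            )
        cand.sort()
        cells = [c[2:] for c in cand[:n_per_location]]
        for i in range(n_per_location):
            sid = f"{row['id']}_I{i + 1}"
            x, y = surface.cell_center(*cells[i])
            samples.append(sid)
            meta_rows.append({"id": sid, "x": x, "y": y, "location": row["id"]})
            rows.append(rng.binomial(2, freq[li]).astype(np.int8))
    gm = GenotypeMatrix(samples, _synthetic_loci(n_loci), np.stack(rows))
    return gm, pd.DataFrame(meta_rows)


def _cell_of(surface: ResistanceSurface, x: float, y: float) -> tuple[int, int]:
    x0, y0 = surface.origin
    col = int((x - x0) // surface.resolution)
    row = int((y0 - y) // surface.resolution)
    nr, nc = surface.shape
    if not (0 <= row < nr and 0 <= col < nc):
        raise SyntheticError(f"point ({x}, {y}) outside the surface")
    return row, col


# ---------------------------------------------------------------------------
# pedigree genotypes
# ---------------------------------------------------------------------------

@dataclass
class PedigreeSpec:
    """Ordered pedigree entries (id, dam, sire) plus optional clone pairs.

    Founders have both parents ``None``; parents must precede offspring.
    ``clones`` lists (new_id, source_id) duplicates (identical genotypes).
    """

    entries: list[tuple[str, str | None, str | None]]
    founder_freqs: np.ndarray | None = None
    clones: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for iid, dam, sire in self.entries:
            for par in (dam, sire):
                if par is not None and par not in seen:
                    raise SyntheticError(
                        f"parent {par!r} of {iid!r} not defined earlier (cycle or ordering)"
                    )
            if iid in seen:
                raise SyntheticError(f"duplicate individual {iid!r}")
            seen.add(iid)
        for new, src in self.clones:
            if src not in seen:
                raise SyntheticError(f"clone source {src!r} unknown")
            seen.add(new)

    def parents(self) -> dict[str, tuple[str | None, str | None]]:
        return {iid: (dam, sire) for iid, dam, sire in self.entries}


def simulate_pedigree_genotypes(
    ped: PedigreeSpec, n_loci: int, seed: int
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Mendelian genotype simulation down a pedigree.

    Founder alleles are Bernoulli draws from the founder frequencies
    (Uniform(0.1, 0.9) per locus if unspecified); each offspring receives one
    allele from each parent by a fair coin per locus.  Returns the matrix and
    a pair table with true relationship classes.
    """
    rng = np.random.default_rng(seed)
    if ped.founder_freqs is None:
        p = rng.uniform(0.1, 0.9, size=n_loci)
    else:
        p = np.asarray(ped.founder_freqs, dtype=float)
        if p.shape != (n_loci,):
            raise SyntheticError("founder_freqs length must equal n_loci")
        if np.any((p <= 0) | (p >= 1)):
            raise SyntheticError("founder frequencies must lie in (0, 1)")
    alleles: dict[str, np.ndarray] = {}  # id -> (2, n_loci) 0/1
    for iid, dam, sire in ped.entries:
        if dam is None and sire is None:
            alleles[iid] = (rng.random(size=(2, n_loci)) < p).astype(np.int8)
        else:
            if dam is None or sire is None:
                raise SyntheticError(f"{iid!r} must have both parents or neither")
            a1 = alleles[dam][rng.integers(0, 2, size=n_loci), np.arange(n_loci)]
            a2 = alleles[sire][rng.integers(0, 2, size=n_loci), np.arange(n_loci)]
            alleles[iid] = np.stack([a1, a2]).astype(np.int8)
    for new, src in ped.clones:
        alleles[new] = alleles[src].copy()
    ids = list(alleles)
    geno = np.stack([alleles[i].sum(axis=0) for i in ids]).astype(np.int8)
    gm = GenotypeMatrix(ids, _synthetic_loci(n_loci), geno)
    return gm, true_relationships(ped)


def true_relationships(ped: PedigreeSpec) -> pd.DataFrame:
    """Classify all pairs: clone, parent_offspring, full_sib, half_sib,
    unrelated (founder pairs with no shared parent), or other."""
    parents = ped.parents()
    clone_of = {new: src for new, src in ped.clones}
    for new, src in ped.clones:
        parents[new] = parents[src]
    ids = [e[0] for e in ped.entries] + [c[0] for c in ped.clones]
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pa, pb = parents[a], parents[b]
            if clone_of.get(a) == b or clone_of.get(b) == a:
                label = "clone"
            elif a in pb or b in pa:
                label = "parent_offspring"
            elif None not in pa and pa == pb:
                label = "full_sib"
            elif None not in pa and None not in pb and len(set(pa) & set(pb)) == 1:
                label = "half_sib"
            elif pa == (None, None) and pb == (None, None):
                label = "unrelated"
            else:
                label = "other"
            rows.append({"id_a": a, "id_b": b, "relationship": label})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF-style degradation
# ---------------------------------------------------------------------------

@dataclass
class DepthModel:
    """Simulated sequencing annotations: Poisson read depths around
    ``mean_depth``, site qualities around ``qual_mean``, constant mapping
    quality."""

    mean_depth: float = 30.0
    qual_mean: float = 60.0
    qual_sd: float = 5.0
    mapping_quality: float = 60.0


def degrade_to_vcf_records(
    gm: GenotypeMatrix,
    missing_rate: float = 0.0,
    depth_model: DepthModel | None = None,
    seed: int = 0,
) -> tuple[list[str], list[VariantRecord]]:
    """Attach simulated depth/quality annotations and random missingness.

    ``missing_rate`` may be a scalar or a per-sample vector; masked genotypes
    get depth 0.  Output records are valid VCF fodder for the filter chain.
    """
    dm = depth_model or DepthModel()
    rates = np.broadcast_to(np.asarray(missing_rate, dtype=float), (gm.n_samples,))
    if np.any((rates < 0) | (rates >= 1)):
        raise SyntheticError("missing rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records = []
    for j in range(gm.n_loci):
        gts = gm.genotypes[:, j].copy()
        drop = rng.random(gm.n_samples) < rates
        gts[drop] = MISSING
        depths = rng.poisson(dm.mean_depth, size=gm.n_samples).astype(np.int32)
        depths[gts == MISSING] = 0
        qual = max(0.0, rng.normal(dm.qual_mean, dm.qual_sd))
        loc = gm.loci.iloc[j]
        records.append(
            VariantRecord(
                chrom=str(loc["chrom"]),
                pos=int(loc["pos"]),
                ref=str(loc["ref"]),
                alts=(str(loc["alt"]),),
                qual=float(qual),
                mapping_quality=dm.mapping_quality,
                genotypes=gts,
                depths=depths,
                locus_id=str(loc["locus_id"]),
                snp_id=f"snp{j + 1}",
            )
        )
    return list(gm.samples), records


# ---------------------------------------------------------------------------
# scenario bundling
# ---------------------------------------------------------------------------

#: default landscape emulating an urban mosaic: garden/greenspace matrix,
#: building patches (barriers), impervious cover, and two crossing
#: high-resistance linear features (street and railway)
def default_landscape_spec(nrows: int = 24, ncols: int = 24, resolution: float = 5.0) -> LandscapeSpec:
    return LandscapeSpec(
        nrows=nrows,
        ncols=ncols,
        resolution=resolution,
        smoothing_sigma=2.0,
        classes=[
            ClassSpec("Private Garden", weight=0.35),
            ClassSpec("Buildings", weight=0.15),
            ClassSpec("Impervious", weight=0.25),
            ClassSpec("Parks and Playspace", weight=0.25),
            ClassSpec("Large street", kind="linear", orientation="vertical", width=1, wander=1),
            ClassSpec("Railways", kind="linear", orientation="horizontal", width=1, wander=1),
        ],
    )


@dataclass
class SyntheticScenario:
    """Full parameterisation of one generated dataset.

    Defaults mirror a desk-scale urban field study: ~70 diploid individuals
    in 4-8 spatial clusters, ~1400 biallelic SNPs, 5% missingness, moderate
    differentiation.
    """

    seed: int = 0
    n_pops: int = 7
    n_individuals_per_pop: int = 10
    n_loci: int = 1400
    fst_target: float = 0.10
    ibr_scale_phi: float | None = None  # default: median commute distance
    ibr_sigma2: float = 1.0
    missing_rate: float = 0.05
    landscape: LandscapeSpec = field(default_factory=default_landscape_spec)

    def __post_init__(self) -> None:
        if min(self.n_pops, self.n_individuals_per_pop, self.n_loci) < 1:
            raise SyntheticError("counts must be >= 1")
        if not 0 <= self.fst_target < 1:
            raise SyntheticError("fst_target must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise SyntheticError("missing_rate must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        raw = yaml.safe_load(open(path)) or {}
        ls = raw.pop("landscape", None)
        scenario = cls(**raw)
        if ls is not None:
            classes = [ClassSpec(**c) for c in ls.pop("classes", [])]
            scenario.landscape = LandscapeSpec(classes=classes, **ls)
        return scenario
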