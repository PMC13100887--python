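"""Genotype containers, VCF/CSV I/O, and the post-variant-calling filter chain.

Filtering follows the standard two-level convention for reduced-representation
SNP data: individual genotype calls below the depth floor are first masked to
missing, then site-level rules (quality, mean depth, mapping quality, minor
allele count, call rate, biallelic-only, one SNP per capture locus) act on the
masked matrix, in that order.  Each step's input/output counts are recorded in
a :class:`FilterReport` so a run can be audited like a bioinformatic
filtering-table supplement.

Sample curation utilities cover the common field-study situations: removal of
individuals with excess missing data, single-linkage grouping of samples into
localities by a distance radius, and thinning of an over-sampled site to its
most recent samples while excluding first-degree relatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

MISSING = -1


class VcfParseError(ValueError):
    pass


class FilterError(ValueError):
    pass


@dataclass
class VariantRecord:
    """One SNP site with the annotations the filter chain consumes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    mapping_quality: float
    genotypes: np.ndarray  # (n_samples,) alt-allele dosage 0/1/2, MISSING
    depths: np.ndarray  # (n_samples,) per-genotype read depth
    locus_id: str | None = None  # capture-locus (UCE region) identifier
    snp_id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfParseError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alts:
            raise VcfParseError("ref and alt alleles must be non-empty")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)

    @property
    def biallelic(self) -> bool:
        return len(self.alts) == 1

    def mean_depth(self) -> float:
        return float(np.mean(self.depths))


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, alt-dosage coded 0/1/2 with -1 missing."""

    samples: list[str]
    loci: pd.DataFrame  # columns: chrom, pos, ref, alt, locus_id
    genotypes: np.ndarray  # (n_samples, n_loci) int8

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError("sample ids do not match genotype rows")
        if len(self.loci) != m:
            raise ValueError("locus table does not match genotype columns")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def sample_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def locus_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.samples[i] for i in index], self.loci.copy(), self.genotypes[index]
        )

    def take_loci(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            list(self.samples), self.loci.iloc[index], self.genotypes[:, index]
        )

    def alt_frequencies(self) -> np.ndarray:
        """Per-locus alternate-allele frequency among non-missing genes."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        return (g.sum(axis=0) / (2.0 * g.count(axis=0))).filled(np.nan)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.genotypes.astype(int),
            index=pd.Index(self.samples, name="id"),
            columns=[f"{c}:{p}" for c, p in zip(self.loci["chrom"], self.loci["pos"])],
        )
        df.replace(MISSING, "NA").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        chrom, pos = [], []
        for col in df.columns:
            c, _, p = str(col).rpartition(":")
            chrom.append(c or "unknown")
            pos.append(int(p) if p.isdigit() else len(pos) + 1)
        loci = pd.DataFrame(
            {"chrom": chrom, "pos": pos, "ref": "A", "alt": "T",
             "locus_id": [f"{c}:{p}" for c, p in zip(chrom, pos)]}
        )
        geno = df.to_numpy(dtype=float)
        geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
        return cls([str(s) for s in df.index], loci, geno)


# ---------------------------------------------------------------------------
# VCF I/O — written by hand (simple, dependency-light), read back via cyvcf2
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth across samples">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=LOCUS,Number=1,Type=String,Description="Capture locus identifier">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(samples: list[str], records: list[VariantRecord], path) -> None:
    """Write diploid biallelic-coded records as plain-text VCF 4.2."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(r.chrom for r in records):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for r in records:
            info = f"DP={int(r.depths.sum())};MQ={r.mapping_quality:g}"
            if r.locus_id is not None:
                info += f";LOCUS={r.locus_id}"
            cells = [
                f"{_GT_STRING.get(int(g), './.')}:{int(d)}"
                for g, d in zip(r.genotypes, r.depths)
            ]
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.snp_id}\t{r.ref}\t{','.join(r.alts)}\t"
                f"{r.qual:g}\t.\t{info}\tGT:DP\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF into VariantRecords; rejects non-diploid genotype calls."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for var in vcf:
        gts = np.full(len(samples), MISSING, dtype=np.int8)
        for i, call in enumerate(var.genotypes):
            alleles = call[:-1]  # last element is the phasing flag
            if len(alleles) != 2:
                raise VcfParseError(
                    f"non-diploid genotype for sample {samples[i]!r} at "
                    f"{var.CHROM}:{var.POS}"
                )
            if -1 in alleles:
                continue
            gts[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
        try:
            dp = var.format("DP")
            depths = np.where(dp is None, 0, dp).reshape(-1).astype(np.int32)
            depths = np.where(depths < 0, 0, depths)
        except (KeyError, TypeError):
            depths = np.zeros(len(samples), dtype=np.int32)
        mq = var.INFO.get("MQ")
        locus = var.INFO.get("LOCUS")
        records.append(
            VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alts=tuple(var.ALT),
                qual=float(var.QUAL) if var.QUAL is not None else np.nan,
                mapping_quality=float(mq) if mq is not None else np.nan,
                genotypes=gts,
                depths=depths,
                locus_id=str(locus) if locus is not None else None,
                snp_id=var.ID or ".",
            )
        )
    return samples, records


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Thresholds of the post-calling filter chain (defaults are the standard
    reduced-representation values: DP>=5 genotypes, QUAL>=20, mean depth>=10,
    MQ>=30, MAC>=3, 95% call rate, biallelic, one SNP per capture locus)."""

    min_genotype_depth: int = 5
    min_site_quality: float = 20.0
    min_mean_depth: float = 10.0
    min_mapping_quality: float = 30.0
    min_mac: int = 3
    max_site_missing: float = 0.05
    max_individual_missing: float = 0.20
    biallelic_only: bool = True
    one_snp_per_locus: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_site_missing <= 1:
            raise ValueError("max_site_missing must be in [0,1]")
        if not 0 <= self.max_individual_missing <= 1:
            raise ValueError("max_individual_missing must be in [0,1]")
        for name in ("min_genotype_depth", "min_site_quality", "min_mean_depth",
                     "min_mapping_quality", "min_mac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class FilterReport:
    """Ordered per-rule record counts plus individuals removed with reasons."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)
    individuals_removed: dict[str, str] = field(default_factory=dict)

    def add(self, rule: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise FilterError(f"rule {rule!r} increased record count")
        if self.steps and self.steps[-1][2] != n_in:
            raise FilterError(f"rule {rule!r} input differs from previous output")
        self.steps.append((rule, n_in, n_out))

    def counts(self) -> list[int]:
        if not self.steps:
            return []
        return [self.steps[0][1]] + [s[2] for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "records_in", "records_out"])

    def to_json_dict(self) -> dict:
        return {
            "steps": [
                {"rule": r, "in": i, "out": o} for r, i, o in self.steps
            ],
            "individuals_removed": self.individuals_removed,
        }


def _mac(genotypes: np.ndarray) -> int:
    """Minor allele count among non-missing genes (alt-dosage coding)."""
    ok = genotypes != MISSING
    alt = int(genotypes[ok].sum())
    total = 2 * int(ok.sum())
    return min(alt, total - alt)


def apply_filter_chain(
    samples: list[str],
    records: list[VariantRecord],
    cfg: FilterConfig | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the site-level filter chain and assemble a genotype matrix.

    Order: genotype-depth mask -> site quality -> site mean depth -> mapping
    quality -> MAC -> call rate -> biallelic-only -> one SNP per locus.  The
    depth mask sets individual calls to missing; all later statistics (MAC,
    call rate, mean depth) are computed on the masked genotypes.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()
    n0 = len(records)

    masked: list[VariantRecord] = []
    for r in records:
        gts = r.genotypes.copy()
        low = (r.depths < cfg.min_genotype_depth) & (gts != MISSING)
        gts[low] = MISSING
        masked.append(replace(r, genotypes=gts, depths=r.depths.copy()))
    report.add("genotype_depth_mask", n0, len(masked))

    def _site_pass(rule, records_in, predicate):
        kept = [r for r in records_in if predicate(r)]
        report.add(rule, len(records_in), len(kept))
        return kept

    recs = masked
    if not all(np.isfinite(r.qual) for r in recs) and cfg.min_site_quality > 0:
        raise FilterError("site quality filter enabled but QUAL missing on records")
    recs = _site_pass("site_quality", recs, lambda r: r.qual >= cfg.min_site_quality)
    recs = _site_pass("mean_depth", recs, lambda r: r.mean_depth() >= cfg.min_mean_depth)
    if not all(np.isfinite(r.mapping_quality) for r in recs) and cfg.min_mapping_quality > 0:
        raise FilterError("mapping quality filter enabled but MQ missing on records")
    recs = _site_pass(
        "mapping_quality", recs, lambda r: r.mapping_quality >= cfg.min_mapping_quality
    )
    recs = _site_pass("minor_allele_count", recs, lambda r: _mac(r.genotypes) >= cfg.min_mac)
    min_call = 1.0 - cfg.max_site_missing
    recs = _site_pass(
        "call_rate",
        recs,
        lambda r: np.mean(r.genotypes != MISSING) >= min_call,
    )
    if cfg.biallelic_only:
        recs = _site_pass("biallelic_only", recs, lambda r: r.biallelic)
    if cfg.one_snp_per_locus:
        if any(r.locus_id is None for r in recs):
            raise FilterError("one-SNP-per-locus enabled but records lack locus ids")
        keep_idx = _thin_indices(recs)
        kept = [recs[i] for i in sorted(keep_idx)]
        report.add("one_snp_per_locus", len(recs), len(kept))
        recs = kept

    loci = pd.DataFrame(
        {
            "chrom": [r.chrom for r in recs],
            "pos": [r.pos for r in recs],
            "ref": [r.ref for r in recs],
            "alt": [r.alts[0] if r.alts else "." for r in recs],
            "locus_id": [r.locus_id or f"{r.chrom}:{r.pos}" for r in recs],
        }
    )
    geno = (
        np.stack([r.genotypes for r in recs], axis=1)
        if recs
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(list(samples), loci, geno), report


def _thin_indices(records: list[VariantRecord]) -> list[int]:
    """One SNP per locus: keep the highest call rate, then the lowest pos."""
    best: dict[str, tuple[float, int, int]] = {}
    for i, r in enumerate(records):
        call = float(np.mean(r.genotypes != MISSING))
        key = r.locus_id
        cand = (-call, r.pos, i)
        if key not in best or cand < best[key]:
            best[key] = cand
    return [i for _, _, i in best.values()]


def thin_one_snp_per_locus(gm: GenotypeMatrix, locus_ids=None) -> GenotypeMatrix:
    """Matrix-level thinning with the same tie-break as the chain step."""
    ids = list(gm.loci["locus_id"]) if locus_ids is None else list(locus_ids)
    if len(ids) != gm.n_loci or any(pd.isna(i) for i in ids):
        raise FilterError("every SNP must carry a locus id")
    call = gm.locus_call_rate()
    best: dict[str, tuple[float, int, int]] = {}
    for j, lid in enumerate(ids):
        cand = (-call[j], int(gm.loci["pos"].iloc[j]), j)
        if lid not in best or cand < best[lid]:
            best[lid] = cand
    keep = sorted(i for _, _, i in best.values())
    return gm.take_loci(keep)


def remove_high_missing_individuals(
    gm: GenotypeMatrix, max_individual_missing: float = 0.20
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop individuals whose missing fraction strictly exceeds the threshold."""
    if not 0 <= max_individual_missing <= 1:
        raise FilterError("threshold must be in [0,1]")
    rates = gm.sample_missing_rate()
    keep = np.nonzero(rates <= max_individual_missing)[0]
    removed = [gm.samples[i] for i in np.nonzero(rates > max_individual_missing)[0]]
    if keep.size == 0:
        raise FilterError("all individuals exceed the missingness threshold")
    return gm.take_samples(keep), removed


def remove_heterozygosity_outliers(
    gm: GenotypeMatrix, z_threshold: float = 3.0
) -> tuple[GenotypeMatrix, list[str]]:
    """Optional rule: drop individuals with heterozygosity z-score > threshold.

    Off by default in the chain; exposed for datasets where contamination
    shows up as unusually high individual heterozygosity.
    """
    het = np.ma.masked_equal(gm.genotypes, MISSING)
    prop = (het == 1).sum(axis=1) / het.count(axis=1)
    z = (prop - prop.mean()) / (prop.std() if prop.std() > 0 else 1.0)
    keep = np.nonzero(z <= z_threshold)[0]
    removed = [gm.samples[i] for i in np.nonzero(z > z_threshold)[0]]
    if keep.size == 0:
        raise FilterError("all individuals flagged as heterozygosity outliers")
    return gm.take_samples(keep), removed


# ---------------------------------------------------------------------------
# sample metadata and curation
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Sample metadata CSV: id, x, y (projected metres), location, date."""
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "x", "y"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df


def group_by_location(metadata: pd.DataFrame, radius_m: float = 1000.0) -> pd.Series:
    """Single-linkage clustering of samples into localities.

    Two samples share a label iff they are connected by a chain of pairwise
    distances <= radius_m.  Samples with missing coordinates are left
    unlabelled (NaN) with a warning.
    """
    xy = metadata[["x", "y"]].to_numpy(dtype=float)
    ok = ~np.isnan(xy).any(axis=1)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} samples lack coordinates and are unlabelled")
    labels = pd.Series(np.nan, index=metadata["id"].to_numpy(), dtype=object, name="location")
    pts = xy[ok]
    if pts.shape[0] == 1:
        labels.iloc[np.nonzero(ok)[0][0]] = "L1"
        return labels
    if pts.shape[0] == 0:
        return labels
    z = linkage(pdist(pts), method="single")
    cl = fcluster(z, t=radius_m, criterion="distance")
    # stable label numbering by first appearance
    remap: dict[int, str] = {}
    for c in cl:
        if c not in remap:
            remap[c] = f"L{len(remap) + 1}"
    labels.iloc[np.nonzero(ok)[0]] = [remap[c] for c in cl]
    return labels


def subset_oversampled_site(
    gm: GenotypeMatrix,
    metadata: pd.DataFrame,
    relatedness: pd.DataFrame,
    site: str,
    n_keep: int = 5,
    first_degree_threshold: float = 0.35,
) -> tuple[GenotypeMatrix, list[str]]:
    """Thin one over-sampled site to its most recent unrelated samples.

    Greedy by descending collection date; a candidate is skipped when its
    relatedness to any already-kept sample is >= the first-degree threshold.
    Samples outside ``site`` are untouched.  Returns the reduced matrix and
    the ids removed.
    """
    meta = metadata.set_index("id")
    if "location" not in meta.columns or site not in set(meta["location"]):
        raise ValueError(f"site {site!r} absent from metadata locations")
    site_ids = [s for s in gm.samples if s in meta.index and meta.loc[s, "location"] == site]
    if any(pd.isna(meta.loc[s].get("date")) for s in site_ids):
        raise ValueError("collection dates required for all samples at the site")
    order = sorted(site_ids, key=lambda s: meta.loc[s, "date"], reverse=True)
    kept: list[str] = []
    for s in order:
        if len(kept) >= n_keep:
            break
        if any(float(relatedness.loc[s, k]) >= first_degree_threshold for k in kept):
            continue
        kept.append(s)
    removed = [s for s in site_ids if s not in kept]
    keep_idx = [i for i, s in enumerate(gm.samples) if s not in removed]
    return gm.take_samples(keep_idx), removed
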