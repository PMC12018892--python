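"""Genotype matrices, VCF input/output, and RADseq-style site filtering.

Genotypes are held as a dense samples x sites matrix of small integer codes:
``0`` homozygous reference, ``1`` heterozygous, ``2`` homozygous alternate and
``-1`` missing.  Only biallelic SNPs are represented; multi-allelic and
non-SNP records are dropped (and counted) on read.  The filtering pipeline
reproduces the standard vcftools/Stacks post-processing of a reduced
representation SNP panel: per-genotype depth masking, site mean-depth bounds,
per-population locus presence, site missingness, and a minor-allele-frequency
floor, applied in that fixed order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FilterSpec",
    "FilterReport",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "apply_filters",
    "sample_heterozygosity",
]


class VcfParseError(RuntimeError):
    """Raised when a VCF cannot be parsed; reports the failing record index."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP-sites genotype matrix.

    Parameters
    ----------
    samples:
        Ordered sample identifiers (rows).
    sites:
        Ordered ``(chrom, pos, ref, alt)`` keys (columns); ``(chrom, pos)``
        must be unique.
    genotypes:
        ``int8`` array of shape ``(n_samples, n_sites)`` over
        ``{0, 1, 2, MISSING}``.
    depths:
        Optional per-genotype read depths, same shape, non-negative.
    populations:
        Optional sample -> population-label map (used by the locus presence
        filter).
    """

    samples: list[str]
    sites: list[tuple[str, int, str, str]]
    genotypes: np.ndarray
    depths: np.ndarray | None = None
    populations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        keys = {(c, p) for c, p, _, _ in self.sites}
        if len(keys) != len(self.sites):
            raise ValueError("duplicate (chrom, pos) site keys")
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
            if self.depths.shape != self.genotypes.shape:
                raise ValueError("depth matrix shape mismatch")
            if (self.depths < 0).any():
                raise ValueError("depths must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_mask(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[s for s, keep in zip(self.sites, mask) if keep],
            genotypes=self.genotypes[:, mask].copy(),
            depths=None if self.depths is None else self.depths[:, mask].copy(),
            populations=None if self.populations is None else dict(self.populations),
        )

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(n) for n in names]
        return GenotypeMatrix(
            samples=list(names),
            sites=list(self.sites),
            genotypes=self.genotypes[idx].copy(),
            depths=None if self.depths is None else self.depths[idx].copy(),
            populations=None
            if self.populations is None
            else {n: self.populations[n] for n in names if n in self.populations},
        )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records and non-SNP variants are dropped; the number of
    dropped records is logged.  Missing genotypes (``./.``) are preserved as
    ``MISSING``.  ``DP`` FORMAT values are collected when present on every
    kept record.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # htslib raises bare Exceptions
        raise VcfParseError(f"{path}: cannot open/parse VCF header: {exc}") from exc

    samples = list(vcf.samples)
    sites: list[tuple[str, int, str, str]] = []
    geno_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    have_depth = True
    dropped = 0
    record_idx = 0
    try:
        for var in vcf:
            record_idx += 1
            alts = var.ALT
            if (
                len(alts) != 1
                or len(var.REF) != 1
                or len(alts[0]) != 1
                or alts[0] not in "ACGT"
                or var.REF not in "ACGT"
            ):
                dropped += 1
                continue
            gts = np.asarray(var.gt_types, dtype=np.int8)
            gts[gts == 3] = MISSING
            geno_cols.append(gts)
            sites.append((var.CHROM, var.POS, var.REF, alts[0]))
            if have_depth:
                try:
                    dp = var.format("DP")
                except KeyError:
                    dp = None
                if dp is None:
                    have_depth = False
                else:
                    dp = dp.reshape(-1).astype(np.int64)
                    dp[dp < 0] = 0  # htslib encodes missing DP as a sentinel
                    depth_cols.append(dp)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"{path}: malformed VCF near record {record_idx + 1}: {exc}"
        ) from exc
    if dropped:
        logger.info("read_vcf(%s): dropped %d multi-allelic/non-SNP records", path, dropped)
    genotypes = (
        np.stack(geno_cols, axis=1)
        if geno_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    depths = (
        np.stack(depth_cols, axis=1)
        if (have_depth and depth_cols and len(depth_cols) == len(sites))
        else None
    )
    return GenotypeMatrix(samples=samples, sites=sites, genotypes=genotypes, depths=depths)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write a VCF v4.2 with GT (and DP when available) FORMAT fields.

    Output is byte-deterministic for a given matrix, which the synthetic
    data generator relies on for seed-reproducibility checks.
    """
    path = Path(path)
    chroms: list[str] = []
    for chrom, _, _, _ in gm.sites:
        if chrom not in chroms:
            chroms.append(chrom)
    fmt = "GT:DP" if gm.depths is not None else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=nestkin\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depths is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, (chrom, pos, ref, alt) in enumerate(gm.sites):
            fields = [chrom, str(pos), ".", ref, alt, ".", "PASS", ".", fmt]
            col = gm.genotypes[:, j]
            if gm.depths is not None:
                dpcol = gm.depths[:, j]
                fields.extend(
                    f"{_GT_STRINGS[int(g)]}:{int(d)}" for g, d in zip(col, dpcol)
                )
            else:
                fields.extend(_GT_STRINGS[int(g)] for g in col)
            fh.write("\t".join(fields) + "\n")
    return path


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds for the post-calling SNP filters.

    Defaults follow the standard vcftools invocation for a ddRAD panel:
    MAF >= 0.05, at most 20% missing calls per site, per-genotype and
    per-site-mean depth within [10, 120] (inclusive), and a locus present
    in at least 60% of individuals within each population.
    """

    maf_min: float = 0.05
    max_missing_fraction: float = 0.2
    dp_min: float | None = 10
    dp_max: float | None = 120
    locus_presence_r: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.maf_min <= 0.5:
            raise ValueError("maf_min must be in (0, 0.5]")
        if not 0 <= self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must be in [0, 1)")
        if self.dp_min is not None and self.dp_max is not None and self.dp_min > self.dp_max:
            raise ValueError("dp_min must not exceed dp_max")
        if not 0 <= self.locus_presence_r <= 1:
            raise ValueError("locus_presence_r must be in [0, 1]")


@dataclass
class FilterReport:
    """Sites/genotypes removed at each filtering step."""

    n_input_sites: int
    genotypes_masked_depth: int = 0
    sites_removed_mean_depth: int = 0
    sites_removed_missingness: int = 0
    sites_removed_maf: int = 0
    n_output_sites: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_sites", self.n_input_sites),
            ("genotypes_masked_depth", self.genotypes_masked_depth),
            ("sites_removed_mean_depth", self.sites_removed_mean_depth),
            ("sites_removed_missingness", self.sites_removed_missingness),
            ("sites_removed_maf", self.sites_removed_maf),
            ("output_sites", self.n_output_sites),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def _site_maf(genotypes: np.ndarray) -> np.ndarray:
    """Per-site minor allele frequency over non-missing calls (NaN if none)."""
    called = genotypes >= 0
    n_called = called.sum(axis=0)
    alt = np.where(called, genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return np.minimum(f, 1.0 - f)


def apply_filters(gm: GenotypeMatrix, spec: FilterSpec) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the depth / presence / MAF filters in their fixed order.

    Order of operations (and the report's step counts):

    1. per-genotype DP outside ``[dp_min, dp_max]`` -> call set to missing;
    2. drop sites whose mean DP across samples is outside the bounds;
    3. drop sites failing the per-population presence rule
       (``locus_presence_r``) or the overall ``max_missing_fraction``;
    4. drop sites with MAF below ``maf_min``, computed on the calls that
       survive the depth masking.

    Filtering is idempotent, and step counts sum to
    ``n_input_sites - n_output_sites``.
    """
    report = FilterReport(n_input_sites=gm.n_sites)
    genotypes = gm.genotypes.copy()
    depth_filtering = spec.dp_min is not None or spec.dp_max is not None
    if depth_filtering and gm.depths is None:
        raise ValueError("depth filters requested but the matrix has no depths")

    # step 1: per-genotype depth masking
    if depth_filtering:
        lo = -np.inf if spec.dp_min is None else spec.dp_min
        hi = np.inf if spec.dp_max is None else spec.dp_max
        out_of_range = (gm.depths < lo) | (gm.depths > hi)
        newly = out_of_range & (genotypes != MISSING)
        report.genotypes_masked_depth = int(newly.sum())
        genotypes[newly] = MISSING

    keep = np.ones(gm.n_sites, dtype=bool)

    # step 2: site mean depth
    if depth_filtering and gm.n_sites:
        mean_dp = gm.depths.mean(axis=0)
        lo = -np.inf if spec.dp_min is None else spec.dp_min
        hi = np.inf if spec.dp_max is None else spec.dp_max
        bad = (mean_dp < lo) | (mean_dp > hi)
        report.sites_removed_mean_depth = int((bad & keep).sum())
        keep &= ~bad

    # step 3: presence within populations + overall missingness
    if gm.n_sites:
        called = genotypes >= 0
        pops: dict[str, list[int]]
        if gm.populations:
            pops = {}
            for i, s in enumerate(gm.samples):
                pops.setdefault(gm.populations.get(s, "pop1"), []).append(i)
        else:
            pops = {"pop1": list(range(gm.n_samples))}
        present_ok = np.ones(gm.n_sites, dtype=bool)
        for idx in pops.values():
            frac = called[idx].mean(axis=0)
            present_ok &= frac >= spec.locus_presence_r
        miss_frac = 1.0 - called.mean(axis=0)
        ok = present_ok & (miss_frac <= spec.max_missing_fraction)
        report.sites_removed_missingness = int((~ok & keep).sum())
        keep &= ok

    # step 4: MAF on remaining calls
    if gm.n_sites:
        maf = _site_maf(genotypes)
        ok = ~(maf < spec.maf_min)  # NaN-MAF sites were dropped at step 3
        report.sites_removed_maf = int((~ok & keep).sum())
        keep &= ok

    out = GenotypeMatrix(
        samples=list(gm.samples),
        sites=[s for s, k in zip(gm.sites, keep) if k],
        genotypes=genotypes[:, keep],
        depths=None if gm.depths is None else gm.depths[:, keep].copy(),
        populations=None if gm.populations is None else dict(gm.populations),
    )
    report.n_output_sites = out.n_sites
    if out.n_sites == 0:
        warnings.warn("all sites removed by filtering", stacklevel=2)
    return out, report


def sample_heterozygosity(gm: GenotypeMatrix) -> pd.Series:
    """Per-sample heterozygosity as a percentage of non-missing calls.

    Samples with no non-missing calls are reported as NaN and flagged with
    a warning so they can be excluded from downstream summaries.
    """
    called = gm.genotypes >= 0
    n_called = called.sum(axis=1)
    n_het = (gm.genotypes == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_called > 0, 100.0 * n_het / n_called, np.nan)
    empty = [s for s, n in zip(gm.samples, n_called) if n == 0]
    if empty:
        warnings.warn(f"samples with no called genotypes: {empty}", stacklevel=2)
    return pd.Series(pct, index=pd.Index(gm.samples, name="sample"), name="het_pct")
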