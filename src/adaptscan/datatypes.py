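"""Shared data model for the selection-scan pipeline.

Every container validates its own invariants on construction (or via
:meth:`validate`), so downstream statistics can assume well-formed input.
Haplotype matrices are stored REF/ALT-polarized (0 = reference allele,
1 = alternate, -1 = missing call); ancestral/derived recoding is the job of
the selection statistics, not of parsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "GenotypeMatrix",
    "PopulationPanel",
    "GwasRecord",
    "GeneMap",
    "TermMap",
    "EnvTable",
]


class ValidationError(ValueError):
    """An input violated a data-model invariant."""


@dataclass
class GenotypeMatrix:
    """Phased biallelic haplotypes plus per-variant metadata.

    Attributes
    ----------
    variant_ids : array of str
        SNP identifiers, one per variant (column).
    chrom, pos : arrays
        Chromosome label and 1-based physical position per variant.
        Positions are strictly increasing within each chromosome.
    ref_allele, alt_allele : arrays of single-character strings
    ancestral_allele : array of str or None
        Per-variant ancestral base (from the VCF ``AA`` INFO key); ``"."``
        where unknown. ``None`` when no variant carried the annotation.
    haplotypes : int8 array, shape (2 * n_samples, n_variants)
        Row ``2i`` and ``2i+1`` are the two haplotypes of sample ``i``.
        Entries 0/1 (REF/ALT); -1 marks a missing call.
    sample_ids : array of str
    phased : bool
    """

    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    haplotypes: np.ndarray
    sample_ids: np.ndarray
    ancestral_allele: np.ndarray | None = None
    phased: bool = True

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.ancestral_allele is not None:
            self.ancestral_allele = np.asarray(self.ancestral_allele, dtype=object)
        self.validate()

    # -- basic geometry -----------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def validate(self) -> None:
        m = self.n_variants
        for name in ("chrom", "pos", "ref_allele", "alt_allele"):
            if len(getattr(self, name)) != m:
                raise ValidationError(f"{name} has length {len(getattr(self, name))}, expected {m}")
        if self.ancestral_allele is not None and len(self.ancestral_allele) != m:
            raise ValidationError("ancestral_allele length mismatch")
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != m:
            raise ValidationError(f"haplotype matrix shape {self.haplotypes.shape} does not match {m} variants")
        if self.phased and self.haplotypes.shape[0] != 2 * self.n_samples:
            raise ValidationError("phased matrix must have 2 rows per sample")
        bad = ~np.isin(self.haplotypes, (-1, 0, 1))
        if bad.any():
            raise ValidationError("haplotype entries must be in {-1, 0, 1}")
        for alleles in (self.ref_allele, self.alt_allele):
            if any(not isinstance(a, str) or len(a) != 1 for a in alleles):
                raise ValidationError("alleles must be single-character strings")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(f"positions not strictly increasing on chromosome {c}")

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the variants selected by ``index``."""
        aa = None if self.ancestral_allele is None else self.ancestral_allele[index]
        return GenotypeMatrix(
            variant_ids=self.variant_ids[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref_allele=self.ref_allele[index],
            alt_allele=self.alt_allele[index],
            haplotypes=self.haplotypes[:, index],
            sample_ids=self.sample_ids,
            ancestral_allele=aa,
            phased=self.phased,
        )

    def drop_missing(self) -> tuple["GenotypeMatrix", int]:
        """Drop variants with any missing haplotype call.

        Returns the filtered matrix and the number of dropped variants.
        Haplotype statistics (nSL) require complete columns; frequency and
        Fst statistics tolerate missingness with pairwise-complete counts.
        """
        keep = ~(self.haplotypes == -1).any(axis=0)
        return self.take_variants(keep), int((~keep).sum())

    def haplotype_rows(self, sample_index: np.ndarray) -> np.ndarray:
        """Row indices of the two haplotypes of each selected sample."""
        sample_index = np.asarray(sample_index)
        return np.ravel(np.column_stack((2 * sample_index, 2 * sample_index + 1)))


@dataclass
class PopulationPanel:
    """Sample→population and population→super-population assignment."""

    sample_to_pop: dict[str, str]
    pop_to_superpop: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, p in self.sample_to_pop.items():
            if not p:
                raise ValidationError(f"sample {s!r} has an empty population code")

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def populations(self) -> list[str]:
        return sorted(set(self.sample_to_pop.values()))

    def sample_indices(self, sample_ids: Sequence[str], pop: str) -> np.ndarray:
        """Indices (into ``sample_ids``) of samples assigned to ``pop``."""
        if pop not in set(self.sample_to_pop.values()):
            raise ValidationError(f"population {pop!r} not present in panel")
        members = {s for s, p in self.sample_to_pop.items() if p == pop}
        return np.array([i for i, s in enumerate(sample_ids) if s in members], dtype=np.int64)


@dataclass(frozen=True)
class GwasRecord:
    """One SNP row of a GWAS summary-statistics table.

    ``beta`` is the effect of ``effect_allele`` (A1) in trait units
    (diopters for a refractive-error GWAS); ``se`` its standard error.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"{self.rsid}: p={self.p} outside (0, 1]")
        if not self.se > 0:
            raise ValidationError(f"{self.rsid}: se={self.se} must be > 0")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele identical")


@dataclass
class GeneMap:
    """Gene symbol → set of member SNP identifiers."""

    gene_to_snps: dict[str, set[str]]

    def __post_init__(self) -> None:
        for g, snps in self.gene_to_snps.items():
            if not snps:
                raise ValidationError(f"gene {g!r} has an empty SNP set")
            self.gene_to_snps[g] = set(snps)

    def genes_of(self, snp: str) -> list[str]:
        return sorted(g for g, s in self.gene_to_snps.items() if snp in s)

    def sizes(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.gene_to_snps.items()}


@dataclass
class TermMap:
    """Annotation term → set of member gene symbols (e.g. GO BP terms)."""

    term_to_genes: dict[str, set[str]]
    term_name: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, genes in self.term_to_genes.items():
            if not genes:
                raise ValidationError(f"term {t!r} has an empty gene set")
            self.term_to_genes[t] = set(genes)


@dataclass
class EnvTable:
    """Population code → vector of environmental values.

    ``variables`` names the columns of each population's vector (latitude
    and longitude in degrees, temperature, sunshine duration, ...).
    """

    variables: list[str]
    pop_to_env: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        k = len(self.variables)
        for pop, v in self.pop_to_env.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (k,):
                raise ValidationError(f"population {pop!r}: expected {k} values, got {v.shape}")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"population {pop!r}: non-finite environmental value")
            self.pop_to_env[pop] = v

    def matrix(self, populations: Sequence[str]) -> np.ndarray:
        """(n_pops, n_vars) matrix in the given population order."""
        missing = [p for p in populations if p not in self.pop_to_env]
        if missing:
            raise ValidationError(f"populations missing from environment table: {missing}")
        return np.vstack([self.pop_to_env[p] for p in populations])


def as_gwas_lookup(records: Sequence[GwasRecord]) -> Mapping[str, GwasRecord]:
    """Index GWAS records by rsid (duplicates rejected)."""
    out: dict[str, GwasRecord] = {}
    for r in records:
        if r.rsid in out:
            raise ValidationError(f"duplicate rsid {r.rsid!r}")
        out[r.rsid] = r
    return out
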