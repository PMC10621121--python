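"""Readers and writers for the file formats the pipeline touches.

VCF parsing goes through :mod:`cyvcf2`; all tabular formats are plain
tab- or comma-delimited text with a header (the delimiter is sniffed from
the first line). Writers emit the same dialects, so every format
round-trips losslessly for the retained fields.

Coordinates are 1-based inclusive throughout, matching VCF; region strings
are ``chrom:start-end`` (inclusive on both ends).
"""

from __future__ import annotations

import csv
import logging
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

from .datatypes import (
    EnvTable,
    GeneMap,
    GenotypeMatrix,
    GwasRecord,
    PopulationPanel,
    TermMap,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_panel",
    "write_panel",
    "read_gwas_table",
    "write_gwas_table",
    "read_gene_map",
    "write_gene_map",
    "read_term_map",
    "write_term_map",
    "read_env_table",
    "write_env_table",
]

_BASES = {"A", "C", "G", "T"}


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 1, 2**62
    start, _, end = span.partition("-")
    return chrom, int(start), int(end)


def read_vcf(
    path: str | os.PathLike,
    region: str | None = None,
    samples: Sequence[str] | None = None,
    require_phased: bool = False,
) -> GenotypeMatrix:
    """Read phased biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are dropped (count logged). The
    ancestral allele is parsed from the ``AA`` INFO key when present.

    Parameters
    ----------
    region : optional ``chrom:start-end`` (1-based inclusive) filter.
    samples : optional subset of sample ids to retain, in file order.
    require_phased : raise if any retained genotype is unphased — set this
        when the matrix will feed haplotype statistics (nSL).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    if samples is not None:
        vcf.set_samples(list(samples))
    sample_ids = list(vcf.samples)
    want = _parse_region(region) if region else None

    ids, chroms, poss, refs, alts, aas, cols = [], [], [], [], [], [], []
    n_dropped = 0
    any_aa = False
    for v in vcf:
        if want is not None:
            c, s, e = want
            if v.CHROM != c or not (s <= v.POS <= e):
                continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        gts = v.genotypes  # per sample: [allele0, allele1, phased]
        col = np.empty(2 * len(sample_ids), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if require_phased and not g[2] and -1 not in (a0, a1):
                raise ValidationError(
                    f"unphased genotype at {v.CHROM}:{v.POS} ({v.ID or '.'}) "
                    f"in sample {sample_ids[i]}; phased input required for haplotype statistics"
                )
            col[2 * i] = a0
            col[2 * i + 1] = a1
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        aa = v.INFO.get("AA")
        if aa is not None:
            any_aa = True
            aa = str(aa).split("|")[0].upper()
        aas.append(aa if aa else ".")
        cols.append(col)
    if n_dropped:
        logger.info("read_vcf(%s): dropped %d multi-allelic/non-SNP records", path, n_dropped)
    haps = np.column_stack(cols) if cols else np.empty((2 * len(sample_ids), 0), dtype=np.int8)
    return GenotypeMatrix(
        variant_ids=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        haplotypes=haps,
        sample_ids=np.array(sample_ids, dtype=object),
        ancestral_allele=np.array(aas, dtype=object) if any_aa else None,
        phased=True,
    )


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF v4.2 file."""
    sep = "|" if gm.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if gm.ancestral_allele is not None:
            fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, gm.sample_ids)) + "\n")
        H = gm.haplotypes
        for j in range(gm.n_variants):
            info = "."
            if gm.ancestral_allele is not None and gm.ancestral_allele[j] != ".":
                info = f"AA={gm.ancestral_allele[j]}"
            gts = []
            for i in range(gm.n_samples):
                a0, a1 = H[2 * i, j], H[2 * i + 1, j]
                gts.append(f"{'.' if a0 < 0 else a0}{sep}{'.' if a1 < 0 else a1}")
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t{gm.variant_ids[j]}\t{gm.ref_allele[j]}\t"
                f"{gm.alt_allele[j]}\t.\t.\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

def _sniff_rows(path: str | os.PathLike) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Header + (line number, fields) rows; delimiter sniffed from line 1."""
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ValidationError(f"{path}: empty file")
        delim = "\t" if first.count("\t") >= first.count(",") else ","
        header = next(csv.reader([first], delimiter=delim))
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            rows.append((lineno, next(csv.reader([line], delimiter=delim))))
    return [h.strip() for h in header], rows


def read_panel(path: str | os.PathLike) -> PopulationPanel:
    """Read a 1KGP-style sample panel (sample, pop, optional super-pop)."""
    header, rows = _sniff_rows(path)
    # 1KGP panel files are space-delimited without a real dialect; accept
    # whitespace-split lines when the sniffed delimiter found one column.
    if len(header) == 1:
        with open(path) as fh:
            lines = [ln.split() for ln in fh if ln.strip()]
        header, rows = lines[0], list(enumerate(lines[1:], start=2))
    sample_to_pop: dict[str, str] = {}
    pop_to_superpop: dict[str, str] = {}
    for lineno, f in rows:
        if len(f) < 2:
            raise ValidationError(f"{path}:{lineno}: expected at least sample and population columns")
        sample, pop = f[0].strip(), f[1].strip()
        if sample in sample_to_pop:
            raise ValidationError(f"{path}:{lineno}: duplicate sample {sample!r}")
        sample_to_pop[sample] = pop
        if len(f) >= 3 and f[2].strip():
            pop_to_superpop[pop] = f[2].strip()
    return PopulationPanel(sample_to_pop, pop_to_superpop)


def write_panel(panel: PopulationPanel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpop\tsuper_pop\n")
        for s, p in panel.sample_to_pop.items():
            fh.write(f"{s}\t{p}\t{panel.pop_to_superpop.get(p, '')}\n")


DEFAULT_GWAS_COLUMNS = {
    "rsid": "rsid", "effect_allele": "A1", "other_allele": "A2",
    "beta": "beta", "se": "se", "p": "p",
}


def read_gwas_table(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
) -> list[GwasRecord]:
    """Read GWAS summary statistics.

    ``column_map`` maps the canonical field names (rsid, effect_allele,
    other_allele, beta, se, p) to the file's header names; defaults to
    rsid/A1/A2/beta/se/p.
    """
    cmap = dict(DEFAULT_GWAS_COLUMNS)
    if column_map:
        cmap.update(column_map)
    header, rows = _sniff_rows(path)
    try:
        idx = {k: header.index(v) for k, v in cmap.items()}
    except ValueError as e:
        raise ValidationError(f"{path}: missing column ({e})") from None
    out: list[GwasRecord] = []
    seen: set[str] = set()
    for lineno, f in rows:
        try:
            rec = GwasRecord(
                rsid=f[idx["rsid"]],
                effect_allele=f[idx["effect_allele"]].upper(),
                other_allele=f[idx["other_allele"]].upper(),
                beta=float(f[idx["beta"]]),
                se=float(f[idx["se"]]),
                p=float(f[idx["p"]]),
            )
        except (ValidationError, ValueError, IndexError) as e:
            raise ValidationError(f"{path}:{lineno}: {e}") from None
        if rec.rsid in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate rsid {rec.rsid!r}")
        seen.add(rec.rsid)
        out.append(rec)
    return out


def write_gwas_table(records: Iterable[GwasRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tA1\tA2\tbeta\tse\tp\n")
        for r in records:
            fh.write(f"{r.rsid}\t{r.effect_allele}\t{r.other_allele}\t{r.beta!r}\t{r.se!r}\t{r.p!r}\n")


def read_gene_map(path: str | os.PathLike) -> GeneMap:
    """Read gene→SNP assignments (columns: gene, snp — one pair per row,
    or gene + comma-separated snps)."""
    header, rows = _sniff_rows(path)
    gene_to_snps: dict[str, set[str]] = {}
    for lineno, f in rows:
        if len(f) < 2:
            raise ValidationError(f"{path}:{lineno}: expected gene and snp columns")
        gene = f[0].strip()
        snps = [s.strip() for s in f[1].split(";")] if ";" in f[1] else [f[1].strip()]
        bucket = gene_to_snps.setdefault(gene, set())
        for s in snps:
            if not s:
                raise ValidationError(f"{path}:{lineno}: empty SNP id for gene {gene!r}")
            bucket.add(s)
    return GeneMap(gene_to_snps)


def write_gene_map(gene_map: GeneMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsnp\n")
        for g in sorted(gene_map.gene_to_snps):
            for s in sorted(gene_map.gene_to_snps[g]):
                fh.write(f"{g}\t{s}\n")


def read_term_map(path: str | os.PathLike) -> TermMap:
    """Read term→gene assignments (columns: term, gene, optional name)."""
    header, rows = _sniff_rows(path)
    term_to_genes: dict[str, set[str]] = {}
    term_name: dict[str, str] = {}
    for lineno, f in rows:
        if len(f) < 2:
            raise ValidationError(f"{path}:{lineno}: expected term and gene columns")
        term, gene = f[0].strip(), f[1].strip()
        if not gene:
            raise ValidationError(f"{path}:{lineno}: empty gene for term {term!r}")
        term_to_genes.setdefault(term, set()).add(gene)
        if len(f) >= 3 and f[2].strip():
            term_name[term] = f[2].strip()
    return TermMap(term_to_genes, term_name)


def write_term_map(term_map: TermMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("term\tgene\tname\n")
        for t in sorted(term_map.term_to_genes):
            for g in sorted(term_map.term_to_genes[t]):
                fh.write(f"{t}\t{g}\t{term_map.term_name.get(t, '')}\n")


def read_env_table(path: str | os.PathLike) -> EnvTable:
    """Read a population→environment table (first column: population code;
    remaining numeric columns: one environmental variable each)."""
    header, rows = _sniff_rows(path)
    if len(header) < 2:
        raise ValidationError(f"{path}: need a population column plus at least one variable")
    variables = header[1:]
    pop_to_env: dict[str, np.ndarray] = {}
    for lineno, f in rows:
        pop = f[0].strip()
        if pop in pop_to_env:
            raise ValidationError(f"{path}:{lineno}: duplicate population {pop!r}")
        try:
            pop_to_env[pop] = np.array([float(x) for x in f[1:]], dtype=float)
        except ValueError as e:
            raise ValidationError(f"{path}:{lineno}: {e}") from None
    return EnvTable(variables, pop_to_env)


def write_env_table(env: EnvTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("pop\t" + "\t".join(env.variables) + "\n")
        for p in sorted(env.pop_to_env):
            fh.write(p + "\t" + "\t".join(repr(float(x)) for x in env.pop_to_env[p]) + "\n")
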