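"""Diploid genotype records and phenotype profiles, with TSV and VCF readers.

A :class:`Genome` holds one individual's unordered diploid genotypes over a
SNP panel, keyed by rsID. Allele pairs are canonicalized to sorted order so
``"AG"`` and ``"GA"`` compare equal; genotype calls must already be on a
consistent strand. Missing genotypes are stored explicitly as ``"--"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .schema import PhenotypeSchema

MISSING = "--"
_VALID_ALLELES = set("ACGT")


def canonical_genotype(genotype: str) -> str:
    """Canonicalize an unordered diploid genotype string.

    ``"GA" -> "AG"``; the missing marker ``"--"`` passes through unchanged.
    """
    if genotype == MISSING:
        return MISSING
    if len(genotype) != 2:
        raise ValueError(f"genotype must be two alleles or {MISSING!r}, got {genotype!r}")
    a, b = sorted(genotype.upper())
    if a not in _VALID_ALLELES or b not in _VALID_ALLELES:
        raise ValueError(f"invalid alleles in genotype {genotype!r}")
    return a + b


@dataclass
class Genome:
    """One individual's diploid genotypes over a SNP panel."""

    individual_id: str
    genotypes: dict[str, str]

    def __post_init__(self) -> None:
        self.genotypes = {rsid: canonical_genotype(g) for rsid, g in self.genotypes.items()}

    def genotype_at(self, rsid: str) -> str | None:
        """Canonical genotype at ``rsid``; None if the SNP is absent or missing."""
        g = self.genotypes.get(rsid, MISSING)
        return None if g == MISSING else g


@dataclass
class PhenotypeProfile:
    """Self-reported or ground-truth phenotype values for one individual."""

    individual_id: str
    values: dict[str, str]

    def validate(self, schema: PhenotypeSchema) -> None:
        for p, v in self.values.items():
            if v not in schema.domain(p):
                raise ValueError(
                    f"{self.individual_id}: value {v!r} not in domain of phenotype {p!r}"
                )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_genotype_tsv(path: str | Path) -> list[Genome]:
    """Read a genotype table: ``individual_id<TAB>rs...<TAB>rs...``.

    Cells are two-letter genotypes or ``--`` for missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(MISSING)
    if "individual_id" not in df.columns:
        raise ValueError("genotype TSV must have an 'individual_id' column")
    snp_cols = [c for c in df.columns if c != "individual_id"]
    return [
        Genome(row["individual_id"], {c: row[c] for c in snp_cols})
        for _, row in df.iterrows()
    ]


def write_genotype_tsv(genomes: Iterable[Genome], path: str | Path) -> None:
    genomes = list(genomes)
    snps: dict[str, None] = {}
    for g in genomes:
        for rsid in g.genotypes:
            snps.setdefault(rsid, None)
    rows = [
        {"individual_id": g.individual_id, **{s: g.genotypes.get(s, MISSING) for s in snps}}
        for g in genomes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path: str | Path, schema: PhenotypeSchema | None = None) -> list[PhenotypeProfile]:
    """Read a phenotype table: ``individual_id<TAB>sex<TAB>hair<TAB>skin<TAB>eye``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "individual_id" not in df.columns:
        raise ValueError("phenotype TSV must have an 'individual_id' column")
    cols = [c for c in df.columns if c != "individual_id"]
    profiles = [
        PhenotypeProfile(row["individual_id"], {c: row[c] for c in cols})
        for _, row in df.iterrows()
    ]
    if schema is not None:
        for pr in profiles:
            pr.validate(schema)
    return profiles


def write_phenotype_tsv(profiles: Iterable[PhenotypeProfile], path: str | Path) -> None:
    profiles = list(profiles)
    cols: dict[str, None] = {}
    for pr in profiles:
        for p in pr.values:
            cols.setdefault(p, None)
    rows = [{"individual_id": pr.individual_id, **pr.values} for pr in profiles]
    pd.DataFrame(rows, columns=["individual_id", *cols]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Minimal VCF reader (GT field only)
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, snp_ids: Iterable[str] | None = None) -> list[Genome]:
    """Extract diploid allele pairs from a VCF via the GT field.

    Only the GT field is consulted; multi-allelic sites are accepted (allele
    indices resolve through REF/ALT). Missing or half-missing calls become the
    explicit missing marker. ``snp_ids`` optionally restricts to a panel.
    """
    from cyvcf2 import VCF

    wanted = set(snp_ids) if snp_ids is not None else None
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    genotypes: dict[str, dict[str, str]] = {s: {} for s in samples}
    for variant in vcf:
        rsid = variant.ID
        if rsid is None or (wanted is not None and rsid not in wanted):
            continue
        alleles = [variant.REF] + list(variant.ALT)
        for sample, call in zip(samples, variant.genotypes):
            a1, a2 = call[0], call[1]
            if a1 < 0 or a2 < 0:
                genotypes[sample][rsid] = MISSING
                continue
            b1, b2 = alleles[a1], alleles[a2]
            if len(b1) != 1 or len(b2) != 1:
                genotypes[sample][rsid] = MISSING  # indels are not panel genotypes
                continue
            genotypes[sample][rsid] = canonical_genotype(b1 + b2)
    vcf.close()
    return [Genome(s, genotypes[s]) for s in samples]


def align_cohort(
    genomes: list[Genome], profiles: list[PhenotypeProfile]
) -> tuple[list[Genome], list[PhenotypeProfile]]:
    """Align genome and phenotype lists on individual_id, erroring on mismatch."""
    if not genomes or not profiles:
        raise ValueError("cohort is empty")
    gmap = {g.individual_id: g for g in genomes}
    pmap = {p.individual_id: p for p in profiles}
    only_g = set(gmap) - set(pmap)
    only_p = set(pmap) - set(gmap)
    if only_g or only_p:
        missing = sorted(only_g | only_p)
        raise ValueError(f"individuals present in only one list: {missing}")
    ids = [g.individual_id for g in genomes]
    return [gmap[i] for i in ids], [pmap[i] for i in ids]
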