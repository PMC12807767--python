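"""Summary constants of the v1.0 source catalog release.

These are inputs (published summary tables of the release the
nomenclature was introduced with), kept here so reports and acceptance
checks can recompute their totals instead of hard-coding them.
"""

from __future__ import annotations

#: genomes per continental superpopulation in the v1.0 panel
SUPERPOPULATION_GENOMES: dict[str, int] = {
    "EAS": 130,
    "AFR": 50,
    "AMR": 44,
    "SAS": 25,
    "EUR": 9,
}

#: distinct haplotypes catalogued per level in the v1.0 release
LEVEL_HAPLOTYPE_COUNTS: dict[str, int] = {
    "A": 174_376,
    "C": 300_610,
    "T": 486_288,
    "G": 3_695_204,
}

#: genes passing coverage and quality filters, by chromosome class
GENE_COUNTS_BY_CHROM_CLASS: dict[str, int] = {
    "autosomal": 18_319,
    "X": 831,
    "Y": 44,
}

#: reference assemblies embedded in the global ranking
REFERENCE_ASSEMBLIES: tuple[str, str] = ("GRCh38", "CHM13v2")


def total_genomes() -> int:
    """Panel size: sum of the superpopulation genome counts."""
    return sum(SUPERPOPULATION_GENOMES.values())


def total_haplotypes() -> int:
    """Catalogued haplotypes across the four levels."""
    return sum(LEVEL_HAPLOTYPE_COUNTS.values())


def total_genes() -> int:
    """Genes retained across chromosome classes."""
    return sum(GENE_COUNTS_BY_CHROM_CLASS.values())
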