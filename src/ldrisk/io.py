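"""Reading and writing genotype and phenotype files.

Genotypes travel as delimited text with samples in rows and SNPs in
columns (header row of SNP ids, first column the sample id), or as VCF
converted to additive minor-allele dosages. Phenotypes are two-column
delimited text (sample id, value).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix, PhenotypeVector

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_vcf_genotypes",
    "read_phenotype",
    "write_phenotype",
]


def read_genotypes(path, delimiter: str = "\t") -> GenotypeMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    values = df.to_numpy(dtype=np.float64)
    if not np.isin(values, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype entries must be additive dosages in {0,1,2}")
    freq = values.mean(axis=0) / 2.0
    return GenotypeMatrix(values, [str(c) for c in df.columns],
                          [str(i) for i in df.index],
                          np.minimum(freq, 1.0 - freq))


def write_genotypes(path, G: GenotypeMatrix, delimiter: str = "\t") -> None:
    df = pd.DataFrame(G.values.astype(int), index=G.sample_ids, columns=G.snp_ids)
    df.to_csv(path, sep=delimiter)


def read_vcf_genotypes(path) -> GenotypeMatrix:
    """Load a VCF as additive dosages, counting the minor allele.

    The allele with the lower frequency in the file is the one counted,
    so a site where ALT is the major allele is flipped to 2 - dosage.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, ids = [], []
    for variant in vcf:
        gt = np.asarray(variant.gt_types)
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        if np.any(gt == 2):
            raise ValueError(f"missing genotypes at {variant.ID or variant.POS}")
        dos = np.where(gt == 3, 2, gt).astype(np.float64)
        alt_freq = dos.mean() / 2.0
        if alt_freq > 0.5:
            dos = 2.0 - dos
        rows.append(dos)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    values = np.asarray(rows).T
    freq = values.mean(axis=0) / 2.0
    return GenotypeMatrix(values, ids, samples, np.minimum(freq, 1.0 - freq))


def read_phenotype(path, delimiter: str = "\t") -> PhenotypeVector:
    df = pd.read_csv(path, sep=delimiter, header=None,
                     names=["sample", "value"], comment="#")
    return PhenotypeVector(df["value"].to_numpy(dtype=np.float64),
                           np.array([], dtype=int), np.array([]))


def write_phenotype(path, sample_ids, values, delimiter: str = "\t") -> None:
    pd.DataFrame({"sample": sample_ids, "value": values}).to_csv(
        path, sep=delimiter, header=False, index=False)
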