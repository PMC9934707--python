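"""VCF round-trip for dosage matrices (DS FORMAT field, VCFv4.2 text).

Writing is plain text in a fixed dialect; reading goes through cyvcf2 and accepts
either a DS field or hard GT calls (summed to a dosage).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n'
    '##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality score">\n'
)


def write_vcf(genotypes: GenotypeMatrix, path: str) -> None:
    """Write dosages as a VCF with the effect allele as ALT and a DS FORMAT field."""
    var = genotypes.variants
    has_info = "info" in var.columns
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for chrom in pd.unique(var["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, genotypes.iids)) + "\n")
        for j, row in enumerate(var.itertuples(index=False)):
            info = f"INFO={row.info:.4g}" if has_info and np.isfinite(row.info) else "."
            ds = "\t".join(f"{d:.3g}" for d in genotypes.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.oa}\t{row.ea}\t.\tPASS\t{info}\tDS\t{ds}\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix; effect allele is ALT, dosage from DS or GT."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    iids = np.array(vcf.samples)
    records, columns = [], []
    for v in vcf:
        if v.format("DS") is not None:
            ds = np.asarray(v.format("DS"), dtype=float).reshape(-1)
        else:
            gt = np.asarray(v.genotype.array())[:, :2]
            ds = gt.clip(min=0).sum(axis=1).astype(float)
        info = v.INFO.get("INFO")
        records.append(
            {
                "id": v.ID,
                "chrom": int(str(v.CHROM).removeprefix("chr")),
                "pos": int(v.POS),
                "ea": v.ALT[0],
                "oa": v.REF,
                "eaf": float(ds.mean() / 2.0),
                **({"info": float(info)} if info is not None else {}),
            }
        )
        columns.append(ds)
    variants = pd.DataFrame(records)
    dosages = np.column_stack(columns) if columns else np.empty((len(iids), 0))
    return GenotypeMatrix(iids, variants, dosages)
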