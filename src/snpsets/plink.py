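"""Reader/writer for the PLINK 1 binary genotype trio (.bed/.bim/.fam).

The .bed payload is SNP-major, two bits per genotype, one SNP per padded byte
row. Bit codes (PLINK 1.9 convention, A1 = minor allele):

====  =======================
bits  meaning
====  =======================
00    homozygous A1 (dosage 2)
01    missing
10    heterozygous (dosage 1)
11    homozygous A2 (dosage 0)
====  =======================
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

_MAGIC = bytes([0x6C, 0x1B, 0x01])  # third byte: SNP-major layout

# dosage code -> 2-bit pattern and back
_CODE_TO_BITS = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_BITS_TO_CODE = np.full(4, MISSING, dtype=np.int8)
for _code, _bits in _CODE_TO_BITS.items():
    _BITS_TO_CODE[_bits] = _code


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam."""
    prefix = Path(prefix)
    n, m = g.values.shape

    # .bed — pack 4 genotypes per byte, SNP-major
    bits = np.empty_like(g.values, dtype=np.uint8)
    for code, pattern in _CODE_TO_BITS.items():
        bits[g.values == code] = pattern
    n_bytes = (n + 3) // 4
    payload = np.zeros((m, n_bytes), dtype=np.uint8)
    for offset in range(4):
        chunk = bits[offset::4, :].T  # m x ceil((n-offset)/4)
        payload[:, : chunk.shape[1]] |= chunk << (2 * offset)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(payload.tobytes())

    # .bim — chrom, id, cM, pos, A1 (minor), A2
    bim = pd.DataFrame(
        {
            "chrom": g.snp_meta["chrom"],
            "snp_id": g.snp_meta["snp_id"],
            "cm": 0,
            "pos": g.snp_meta["pos"],
            "a1": g.snp_meta["a1"],
            "a2": g.snp_meta["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": g.subject_ids,
            "iid": g.subject_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read ``prefix``.bed/.bim/.fam into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK 1 .bed file")
    n_bytes = (n + 3) // 4
    payload = raw[3:].reshape(m, n_bytes)

    values = np.empty((n, m), dtype=np.int8)
    for offset in range(4):
        count = len(range(offset, n, 4))
        two_bits = (payload >> (2 * offset)) & 0b11  # m x n_bytes
        values[offset::4, :] = _BITS_TO_CODE[two_bits[:, :count].T]

    snp_meta = bim[["snp_id", "chrom", "pos", "a1", "a2"]].reset_index(drop=True)
    return GenotypeMatrix(values, snp_meta, fam["iid"].tolist())
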