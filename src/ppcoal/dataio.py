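"""SNP-matrix readers/writers: NEXUS binary matrix and plain TSV."""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .simulate import SNPMatrix
from .treeio import SampleMap

__all__ = [
    "write_nexus_binary",
    "read_nexus_binary",
    "write_snp_tsv",
    "read_snp_tsv",
]


def write_nexus_binary(snps: SNPMatrix, path: str | Path) -> None:
    """Write a NEXUS standard-datatype matrix with symbols 0/1."""
    n_ind, n_loci = snps.genotypes.shape
    width = max(len(i) for i in snps.individuals) + 2
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={n_ind} NCHAR={n_loci};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    for i, ind in enumerate(snps.individuals):
        row = "".join(str(int(g)) for g in snps.genotypes[i])
        lines.append(f"        {ind:<{width}}{row}")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_nexus_binary(path: str | Path, sample_map: SampleMap) -> SNPMatrix:
    """Read a NEXUS standard 0/1 matrix back into an :class:`SNPMatrix`."""
    mat = dendropy.StandardCharacterMatrix.get(
        path=str(path), schema="nexus", preserve_underscores=True
    )
    individuals = [t.label for t in mat.taxon_namespace]
    rows = []
    for taxon in mat.taxon_namespace:
        seq = mat[taxon]
        rows.append([int(str(ch)) for ch in seq.symbols_as_list()])
    return SNPMatrix(np.array(rows, dtype=np.int8), individuals, sample_map)


def write_snp_tsv(snps: SNPMatrix, path: str | Path) -> None:
    """TSV with one row per individual: individual, species, then loci."""
    df = pd.DataFrame(
        snps.genotypes,
        index=pd.Index(snps.individuals, name="individual"),
        columns=[f"locus_{i}" for i in range(snps.locus_count)],
    )
    df.insert(0, "species", [snps.sample_map.assignments[i] for i in snps.individuals])
    df.to_csv(path, sep="\t")


def read_snp_tsv(path: str | Path) -> SNPMatrix:
    df = pd.read_csv(path, sep="\t", index_col="individual")
    sample_map = SampleMap(df["species"].to_dict())
    geno = df.drop(columns="species").to_numpy(dtype=np.int8)
    return SNPMatrix(geno, list(df.index), sample_map)
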