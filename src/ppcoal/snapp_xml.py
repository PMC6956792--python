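"""Minimal SNAPP-style XML input files.

Predictive datasets are handed back to the user as XML input files so
each can be re-analyzed with the same settings as the original run.
The dialect here is a compatible subset — a binary data block, a
taxon-set grouping by species, and the recycled run settings — defined
by its own write/read round-trip rather than by any particular BEAST2
template (templates are user-specific). Unknown elements are ignored
on read so externally decorated files still load.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from lxml import etree

from .simulate import SNPMatrix
from .treeio import SampleMap

__all__ = ["SnappRunSettings", "write_snapp_xml", "read_snapp_xml"]


@dataclass(frozen=True)
class SnappRunSettings:
    """MCMC and prior settings recycled from the original analysis.

    ``lambda_prior`` is the (alpha, beta) of the gamma prior on the
    Yule speciation rate; ``mutation_u``/``mutation_v`` are the
    biallelic substitution rates.
    """

    chain_length: int = 1_000_000
    burnin_steps: int = 100_000
    sample_every: int = 1_000
    lambda_prior: tuple[float, float] = (2.0, 200.0)
    mutation_u: float = 1.0
    mutation_v: float = 1.0

    def __post_init__(self) -> None:
        if min(self.chain_length, self.sample_every) <= 0 or self.burnin_steps < 0:
            raise ValueError("chain settings must be positive")
        if min(*self.lambda_prior, self.mutation_u, self.mutation_v) <= 0:
            raise ValueError("prior parameters and rates must be > 0")


def write_snapp_xml(
    snps: SNPMatrix, settings: SnappRunSettings, path: str | Path
) -> None:
    """Write a SNP matrix plus run settings as a SNAPP-style XML file."""
    if snps.locus_count == 0 or not snps.individuals:
        raise ValueError("cannot write an empty SNP matrix")
    bad = np.argwhere(~np.isin(snps.genotypes, (0, 1)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-binary genotype for individual {snps.individuals[i]!r} "
            f"at locus {j}"
        )
    root = etree.Element("snapp", version="1.0")
    data = etree.SubElement(root, "data", id="snps", dataType="binary")
    for i, ind in enumerate(snps.individuals):
        seq = etree.SubElement(data, "sequence", taxon=ind)
        seq.text = "".join(str(int(g)) for g in snps.genotypes[i])
    taxonsets = etree.SubElement(root, "taxonsets")
    for sp in snps.species:
        ts = etree.SubElement(taxonsets, "taxonset", species=sp)
        for ind in snps.individuals:
            if snps.sample_map.assignments[ind] == sp:
                etree.SubElement(ts, "taxon", ref=ind)
    etree.SubElement(
        root,
        "run",
        chainLength=str(settings.chain_length),
        burnin=str(settings.burnin_steps),
        sampleEvery=str(settings.sample_every),
        lambdaAlpha=repr(settings.lambda_prior[0]),
        lambdaBeta=repr(settings.lambda_prior[1]),
        mutationU=repr(settings.mutation_u),
        mutationV=repr(settings.mutation_v),
    )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def read_snapp_xml(path: str | Path) -> tuple[SNPMatrix, SnappRunSettings]:
    """Inverse of :func:`write_snapp_xml` on its own output."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    data = root.find("data")
    if data is None:
        raise ValueError(f"{path}: no <data> block")
    individuals: list[str] = []
    rows: list[list[int]] = []
    for seq in data.findall("sequence"):
        individuals.append(seq.get("taxon"))
        rows.append([int(c) for c in (seq.text or "").strip()])
    if not rows:
        raise ValueError(f"{path}: empty <data> block")
    assignments: dict[str, str] = {}
    taxonsets = root.find("taxonsets")
    if taxonsets is not None:
        for ts in taxonsets.findall("taxonset"):
            for taxon in ts.findall("taxon"):
                assignments[taxon.get("ref")] = ts.get("species")
    run = root.find("run")
    if run is not None:
        settings = SnappRunSettings(
            chain_length=int(run.get("chainLength")),
            burnin_steps=int(run.get("burnin")),
            sample_every=int(run.get("sampleEvery")),
            lambda_prior=(
                float(run.get("lambdaAlpha")),
                float(run.get("lambdaBeta")),
            ),
            mutation_u=float(run.get("mutationU")),
            mutation_v=float(run.get("mutationV")),
        )
    else:
        settings = SnappRunSettings()
    snps = SNPMatrix(
        np.array(rows, dtype=np.int8), individuals, SampleMap(assignments)
    )
    return snps, settings
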