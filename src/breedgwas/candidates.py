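"""Candidate-SNP extraction around gene sets.

A SNP is a candidate for a gene set when it lies within a closed +/- window
(default 20 kb, matching typical LD decay in pedigree dogs) of any gene on
the same chromosome. Strand is ignored; coordinates are 1-based inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, validate_gene_table
from .errors import ConfigError


def snps_near_genes(
    g: GenotypeMatrix, genes: pd.DataFrame, window_bp: int = 20_000
) -> pd.DataFrame:
    """Find SNPs within ``window_bp`` of any gene interval.

    Returns one row per candidate SNP, sorted by (chromosome, position), with
    a ``genes`` column holding the comma-joined ids of every overlapping
    window (a SNP near several genes appears once).
    """
    if window_bp < 0:
        raise ConfigError("window_bp must be non-negative")
    validate_gene_table(genes)

    chroms = g.snps["chrom"].astype(str).to_numpy()
    pos = g.snps["pos"].to_numpy()
    snp_ids = g.snps["snp"].to_numpy()

    hits: dict[int, list[str]] = {}
    for chrom, chrom_genes in genes.groupby(genes["chrom"].astype(str)):
        cols = np.flatnonzero(chroms == chrom)
        if not len(cols):
            continue
        order = cols[np.argsort(pos[cols], kind="stable")]
        sorted_pos = pos[order]
        for gene in chrom_genes.itertuples(index=False):
            lo = int(gene.start) - window_bp
            hi = int(gene.end) + window_bp
            a = np.searchsorted(sorted_pos, lo, side="left")
            b = np.searchsorted(sorted_pos, hi, side="right")
            for col in order[a:b]:
                hits.setdefault(int(col), []).append(str(gene.gene))

    rows = [
        {
            "snp": snp_ids[c],
            "chrom": chroms[c],
            "pos": int(pos[c]),
            "genes": ",".join(sorted(set(glist))),
        }
        for c, glist in hits.items()
    ]
    out = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "genes"])
    if len(out):
        key = out["chrom"].map(lambda s: (0, int(s)) if s.isdigit() else (1, s))
        out = (
            out.assign(_key=key)
            .sort_values(["_key", "pos"], kind="stable")
            .drop(columns="_key")
            .reset_index(drop=True)
        )
    return out
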