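"""Greedy LD clumping of significant SNPs.

Correlated significant SNPs are reduced to one representative (index SNP)
per LD block: SNPs are sorted by association p-value, the best unassigned
SNP becomes an index, and every unassigned SNP whose dosage r² with the
index exceeds the threshold (default 0.6) joins its clump.  No physical
distance window is applied by default because the blocks of interest can be
megabases wide; a window is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from gxemig.genio import AssociationRecord, GenotypeMatrix


@dataclass
class Clump:
    index_snp: str
    index_p: float
    members: dict[str, float] = field(default_factory=dict)   # snp_id -> r² with index

    @property
    def size(self) -> int:
        return 1 + len(self.members)


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation over complete pairs."""
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        return np.nan
    aa, bb = a[ok], b[ok]
    if aa.std() == 0 or bb.std() == 0:
        return np.nan
    return float(np.corrcoef(aa, bb)[0, 1] ** 2)


def clump(
    G_total: GenotypeMatrix,
    significant: Sequence[AssociationRecord],
    r2_threshold: float = 0.6,
    bp_window: int | None = None,
) -> list[Clump]:
    """Cluster significant SNPs so each clump's members have r² >
    ``r2_threshold`` with its index SNP.

    ``significant`` should hold one record per SNP (e.g. the pooled-sample
    record of replicated hits); ordering is by ascending p, ties broken by
    genomic position.
    """
    for r in significant:
        if r.snp_id not in set(G_total.snp_ids):
            raise KeyError(f"SNP {r.snp_id!r} absent from genotype matrix")
    order = sorted(significant, key=lambda r: (r.p, str(r.chrom), r.pos))
    unassigned = {r.snp_id: r for r in order}
    clumps: list[Clump] = []
    for rec in order:
        if rec.snp_id not in unassigned:
            continue
        del unassigned[rec.snp_id]
        c = Clump(index_snp=rec.snp_id, index_p=rec.p)
        g_index = G_total.dosages[:, G_total.snp_index(rec.snp_id)]
        for other_id, other in list(unassigned.items()):
            if bp_window is not None and (
                str(other.chrom) != str(rec.chrom)
                or abs(other.pos - rec.pos) > bp_window
            ):
                continue
            r2 = _dosage_r2(g_index,
                            G_total.dosages[:, G_total.snp_index(other_id)])
            if np.isfinite(r2) and r2 > r2_threshold:
                c.members[other_id] = r2
                del unassigned[other_id]
        clumps.append(c)
    return clumps


def clump_table(clumps: Sequence[Clump]) -> pd.DataFrame:
    """PLINK ``.clumped``-style layout: index SNP, p, clumped members with r²."""
    rows = []
    for c in clumps:
        sp2 = ",".join(f"{s}({r2:.3f})" for s, r2 in sorted(c.members.items()))
        rows.append({"INDEX": c.index_snp, "P": c.index_p,
                     "N_CLUMPED": len(c.members), "SP2": sp2 or "NONE"})
    return pd.DataFrame(rows)
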