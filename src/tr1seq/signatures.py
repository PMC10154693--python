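"""Default TR1/TFH expression signatures for the synthetic generator.

The expression simulator plants cluster-specific log2 fold-changes on a
set of marker genes so that the three-population structure of a
pMHCII-NP-treated repertoire is recovered downstream: a conventional
CD4+ pool (cluster 0, baseline), a TFH-like minor cluster (cluster 1)
and a TR1-like major cluster (cluster 2).

Effect sizes are the tetramer+/Tconv magnitudes reported for
pMHCII-NP-induced TR1 cells (cytokines *Il10*, *Il21*, *Ifng*;
co-inhibitory receptors *Ctla4*, *Lag3*, *Tigit*, *Pdcd1*; transcription
factors *Bcl6*, *Maf*, *Ascl2*, *Nfil3*, *Tox2*; naive/circulating
markers *Sell*, *Ccr7*, *Lef1*, *Klf2*, *Il7r*, *Myc* down), applied with
the sign the biology dictates (TR1 signature up in the TR1-like cluster).
"""

from __future__ import annotations

import pandas as pd

#: log2FC of the TR1-like cluster (2) relative to the Tconv baseline
TR1_LOG2FC: dict[str, float] = {
    "Pdcd1": 3.420,
    "Nt5e": 3.141,
    "Cxcr5": 2.989,
    "Il10": 2.865,
    "Nfil3": 2.750,
    "Ifng": 2.704,
    "Il21": 2.703,
    "Tigit": 2.636,
    "Lag3": 2.507,
    "Ascl2": 2.445,
    "Tox2": 2.181,
    "Bcl6": 1.811,
    "Maf": 1.764,
    "Rbpj": 1.760,
    "Cxcr3": 1.697,
    "Il4": 1.686,
    "Ctla4": 1.665,
    "Icos": 1.210,
    "Cd226": 1.141,
    "Il7r": -1.415,
    "Ccr7": -1.549,
    "Lef1": -1.607,
    "Klf2": -2.667,
    "Myc": -3.455,
    "Sell": -4.367,
}

#: log2FC of the TFH-like cluster (1) relative to the Tconv baseline.
#: TFH hallmark genes (Cxcr5, Il4, Tox2, Cxcr4, Nfia, Bcl6) sit strictly
#: above their TR1-like level — the defining feature of the precursor
#: state — while naive/circulating markers are down in both tetramer+
#: states.
TFH_LOG2FC: dict[str, float] = {
    "Il4": 2.2,
    "Nfia": 1.456,
    "Cxcr5": 3.4,
    "Tox2": 2.7,
    "Cxcr4": 1.059,
    "Bcl6": 2.3,
    "Sell": -3.029,
    "Myc": -2.357,
    "Klf2": -1.542,
    "Lef1": -0.831,
    "Ccr7": -1.521,
    "Il7r": -0.873,
}

#: attenuation of TR1 effects in the TFH-like cluster (intermediate state)
_TFH_ATTENUATION = 0.3


def default_signature_table() -> pd.DataFrame:
    """Per-gene planted log2 fold-changes for clusters 1 and 2 vs cluster 0.

    Columns: ``gene``, ``log2fc_cluster1``, ``log2fc_cluster2``.
    """
    genes = sorted(set(TR1_LOG2FC) | set(TFH_LOG2FC))
    rows = []
    for g in genes:
        lfc2 = TR1_LOG2FC.get(g, 0.0)
        lfc1 = TFH_LOG2FC.get(g, _TFH_ATTENUATION * lfc2)
        rows.append({"gene": g, "log2fc_cluster1": lfc1, "log2fc_cluster2": lfc2})
    return pd.DataFrame(rows)


def tr1_gene_set() -> list[str]:
    """Genes upregulated in the TR1-like state (positive TR1 effect)."""
    return [g for g, v in TR1_LOG2FC.items() if v > 0]


def tfh_gene_set() -> list[str]:
    """Genes upregulated in the TFH-like state (positive TFH effect)."""
    return [g for g, v in TFH_LOG2FC.items() if v > 0]
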