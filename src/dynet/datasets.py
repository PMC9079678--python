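"""Curated reference values for the muscarinic M2 receptor case study.

Shortest-pathway statistics from replicate all-atom MD network analyses
of the human M2 muscarinic acetylcholine receptor bound to the
orthosteric agonist iperoxo (IXO) and/or the positive allosteric
modulator LY2119620 (2CU), with the Nb9-8 nanobody face as the
information sink, plus the alanine mutants of two pathway junction
residues.  These serve as worked-example inputs for the
transfer-efficiency statistic; they are inputs to this package, not
outputs of it.
"""

from __future__ import annotations

import pandas as pd

# system, pathway, intermediate node count, SPL mean, SPL sd
_M2_SPL_ROWS = [
    ("M2/2CU", "2CU-A191-W155-A194-V111-L115-F119-C124-K221-E223-Nb9", 9, 6.60, 1.00),
    ("M2/IXO", "IXO-S151-W400-N436-Y440-R121-Nb9", 5, 4.40, 1.10),
    ("F396A", "2CU-W422-G425-L428-I431-T434-T37-G40-L43-F451-Nb9", 9, 5.63, 1.10),
    ("F396A", "IXO-W400-Y196-V199-T203-W207-A212-R216-K218-E220-Nb9", 9, 7.58, 1.20),
    ("Y403A", "2CU-Y104-A109-W148-I144-S64-Y60-N58-N444-Nb9", 8, 5.89, 1.10),
    ("Y403A", "IXO-N108-N113-S64-Y60-N58-N444-Nb9", 6, 7.96, 1.20),
    ("Bound M2", "2CU-I178-Y403-W400-F396-L114-Y440-Nb9", 6, 4.20, 0.90),
    ("Bound M2", "IXO-V111-F396-L114-Y440-Nb9", 4, 3.60, 0.80),
]


def m2_spl_table() -> pd.DataFrame:
    """Replicate-averaged shortest-pathway lengths (SPL, mean +- sd over
    5 independent trajectories) from the ligand sites to the Nb9-8 sink
    for the M2 receptor systems."""
    return pd.DataFrame(
        _M2_SPL_ROWS,
        columns=["system", "pathway", "n_intermediate", "spl_mean", "spl_sd"],
    )


def m2_pathway_spls(system: str) -> list[float]:
    """The SPL means of all regulation pathways reported for a system."""
    table = m2_spl_table()
    vals = table.loc[table["system"] == system, "spl_mean"].tolist()
    if not vals:
        raise KeyError(f"unknown system {system!r}")
    return vals
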