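"""Published priority-miRNA and protein-target tables, encoded as fixtures.

These are the printed integration inputs from the pancreatic
tumor/adjacent-normal/PDX profiling study this pipeline reimplements:
the top-10 up/down miRNA lists per contrast, the miRNAs moving in the
same direction in both contrasts, and the per-(contrast, subcellular
fraction) fold changes of the proteins those miRNAs are predicted to
target. Encoding them lets the integration stage be exercised and
checked against the study's own multi-target summary without any
array reprocessing.

Notes on the encoding:

* Stem-loop ids (``hsa-mir-...``) and mature ids (``hsa-miR-...``) are
  distinct features and are kept verbatim.
* ``hsa-miR-432-5p``'s printed p-value carries an exponent-sign
  misprint (10^13); it is encoded as 2.10e-13 so it lies in (0, 1].
* Two cytosolic F1vT protein cells (HSP90B1, PLD3) print no p-value;
  they are encoded with p = 1.0 — attribution consumes only the
  direction of the change.
* ``hsa-miR-378e`` appears in the protein-target table without being a
  top-10 row; it is carried as an extra F1vT priority row.
"""

from __future__ import annotations

import pandas as pd

from .io import MrnaDEEntry, ProteinDEEntry, TargetRecord

# (mirna_id, fold_change, p_value) — TvN contrast, top 10 up then top 10 down
TVN_PRIORITY = [
    ("hsa-miR-21-3p", 12.89, 1.20e-3),
    ("hsa-miR-708-5p", 9.15, 6.70e-3),
    ("hsa-miR-181c-5p", 8.52, 3.00e-3),
    ("hsa-miR-125b-1-3p", 6.95, 3.18e-2),
    ("hsa-miR-21-5p", 6.89, 1.58e-2),
    ("hsa-miR-331-5p", 6.81, 3.60e-3),
    ("hsa-miR-210-3p", 6.73, 6.60e-3),
    ("hsa-miR-181d-5p", 6.51, 2.28e-2),
    ("hsa-miR-214-5p", 6.3, 1.02e-2),
    ("hsa-miR-143-5p", 5.55, 2.00e-4),
    ("hsa-mir-375", -1.67, 3.16e-2),
    ("hsa-miR-3618", -1.76, 4.70e-2),
    ("hsa-miR-509-5p", -1.85, 1.30e-3),
    ("hsa-mir-6722", -2.0, 4.62e-2),
    ("hsa-miR-4742-5p", -2.06, 2.15e-2),
    ("hsa-mir-139", -2.2, 4.92e-2),
    ("hsa-miR-451a", -2.93, 3.50e-3),
    ("hsa-miR-139-5p", -4.51, 1.20e-3),
    ("hsa-miR-486-5p", -4.65, 1.33e-2),
    ("hsa-miR-148a-5p", -8.15, 4.08e-2),
]

# F1vT contrast, top 10 up then top 10 down
F1VT_PRIORITY = [
    ("hsa-miR-206", 26.01, 8.59e-5),
    ("hsa-miR-4521", 24.27, 4.48e-6),
    ("hsa-miR-6872-5p", 21.19, 1.35e-7),
    ("hsa-miR-1290", 15.4, 6.80e-3),
    ("hsa-miR-486-5p", 12.48, 1.40e-3),
    ("hsa-miR-615-3p", 10.81, 5.59e-5),
    ("hsa-miR-203a", 9.43, 2.30e-3),
    ("hsa-miR-6778-5p", 8.56, 5.42e-8),
    ("hsa-miR-2467-3p", 7.91, 2.01e-8),
    ("hsa-miR-139-5p", 6.7, 2.78e-6),
    ("hsa-miR-409-3p", -11.45, 1.47e-6),
    ("hsa-miR-146b-3p", -12.7, 6.39e-6),
    ("hsa-miR-217", -13.39, 1.98e-2),
    ("hsa-miR-503-5p", -14.24, 2.30e-3),
    ("hsa-miR-1271-5p", -17.01, 1.88e-6),
    ("hsa-miR-125b-2-3p", -21.33, 6.58e-7),
    ("hsa-miR-708-5p", -21.66, 2.00e-3),
    ("hsa-miR-487b-3p", -34.33, 1.31e-9),
    ("hsa-miR-424-3p", -56.66, 2.27e-6),
    ("hsa-miR-432-5p", -113.44, 2.10e-13),  # exponent-sign misprint; see module docstring
    ("hsa-miR-378e", 4.2, 1.10e-3),  # carried from the protein-target table
]

# (mirna_id, fc_tvn, p_tvn, fc_f1vt, p_f1vt) — same direction in both contrasts
BOTH_PRIORITY = [
    ("hsa-miR-6831-5p", 4.82, 2.16e-2, 1.81, 1.32e-2),
    ("hsa-miR-222-3p", 1.99, 7.10e-3, 2.27, 2.41e-2),
    ("hsa-miR-4534", 1.92, 4.76e-2, 1.83, 3.49e-2),
    ("hsa-miR-4743-5p", 1.87, 1.12e-2, 1.94, 2.20e-3),
    ("hsa-miR-3154", 1.86, 3.12e-2, 5.14, 1.60e-5),
    ("hsa-miR-3935", 1.85, 2.99e-2, 2.5, 1.59e-2),
]

# printed (miRNA, predicted target gene) associations from the
# integration tables; the prediction filter fields are not printed, so a
# permissive target table is reconstructed from these pairs
TARGET_PAIRS = [
    # TvN table
    ("hsa-miR-143-5p", "GSTM3"),
    ("hsa-miR-181c-5p", "PEBP1"),
    ("hsa-miR-181d-5p", "PEBP1"),
    ("hsa-miR-210-3p", "ERP27"),
    ("hsa-miR-214-5p", "TBL2"),
    ("hsa-miR-21-5p", "DDAH1"),
    ("hsa-miR-331-5p", "DDAH1"),
    ("hsa-miR-4742-5p", "CSRP1"),
    ("hsa-miR-4742-5p", "S100A16"),
    ("hsa-miR-4742-5p", "SOD2"),
    ("hsa-miR-509-5p", "COTL1"),
    ("hsa-miR-509-5p", "LRPAP1"),
    ("hsa-miR-509-5p", "SLC4A2"),
    # F1vT table
    ("hsa-miR-125b-2-3p", "SUGT1"),
    ("hsa-miR-206", "PPIB"),
    ("hsa-miR-206", "SLC25A22"),
    ("hsa-miR-615-3p", "DPP3"),
    ("hsa-miR-615-3p", "GANAB"),
    ("hsa-miR-708-5p", "RANBP2"),
    ("hsa-miR-2467-3p", "AKR7A2"),
    ("hsa-miR-2467-3p", "ATP1B3"),
    ("hsa-miR-2467-3p", "CPM"),
    ("hsa-miR-2467-3p", "FKBP15"),
    ("hsa-miR-2467-3p", "RAB1A"),
    ("hsa-miR-2467-3p", "UGGT1"),
    ("hsa-miR-378e", "TXNL1"),
    ("hsa-miR-6778-5p", "ATP5F1A"),
    # both-directions table
    ("hsa-miR-4534", "CALR"),
    ("hsa-miR-4534", "CAPZA1"),
    ("hsa-miR-4534", "OLA1"),
    ("hsa-miR-4743-5p", "CYP20A1"),
    ("hsa-miR-222-3p", "GNAI3"),
    ("hsa-miR-222-3p", "RECK"),
    ("hsa-miR-222-3p", "SOD2"),
    ("hsa-miR-222-3p", "TOM1"),
    ("hsa-miR-3154", "HSP90B1"),
    ("hsa-miR-6831-5p", "PLD3"),
]

# (gene, comparison, fraction, fold_change, p_value), deduplicated across
# the three integration tables (repeated cells print identical values)
PROTEIN_CELLS = [
    ("GSTM3", "TvN", "membrane", -2.04, 6.48e-3),
    ("GSTM3", "F1vT", "cytosolic", -15.16, 6.46e-3),
    ("PEBP1", "TvN", "membrane", -3.20, 1.19e-2),
    ("PEBP1", "TvN", "cytosolic", -2.90, 1.33e-3),
    ("PEBP1", "F1vT", "membrane", -2.10, 1.04e-2),
    ("PEBP1", "F1vT", "cytosolic", -3.50, 3.77e-5),
    ("ERP27", "TvN", "membrane", -21.19, 9.29e-4),
    ("TBL2", "TvN", "cytosolic", -13.95, 4.01e-3),
    ("DDAH1", "TvN", "membrane", -2.13, 1.92e-3),
    ("DDAH1", "F1vT", "cytosolic", 4.16, 3.84e-4),
    ("CSRP1", "TvN", "membrane", 3.11, 1.39e-3),
    ("CSRP1", "TvN", "cytosolic", 2.34, 1.31e-2),
    ("S100A16", "TvN", "membrane", 4.20, 1.12e-2),
    ("S100A16", "F1vT", "membrane", 3.57, 8.51e-4),
    ("SOD2", "TvN", "membrane", 2.29, 5.88e-3),
    ("SOD2", "F1vT", "membrane", -4.84, 5.06e-6),
    ("SOD2", "F1vT", "cytosolic", -22.02, 2.29e-9),
    ("COTL1", "TvN", "membrane", 2.23, 3.83e-2),
    ("COTL1", "F1vT", "cytosolic", 8.77, 1.61e-4),
    ("LRPAP1", "TvN", "membrane", 2.21, 3.10e-3),
    ("LRPAP1", "F1vT", "membrane", -2.37, 1.53e-3),
    ("SLC4A2", "TvN", "membrane", 6.03, 3.11e-3),
    ("SLC4A2", "F1vT", "membrane", -1.98, 5.14e-3),
    ("SUGT1", "F1vT", "cytosolic", 3.19, 9.56e-4),
    ("PPIB", "TvN", "cytosolic", -3.55, 5.45e-3),
    ("PPIB", "F1vT", "membrane", -1.94, 2.55e-2),
    ("PPIB", "F1vT", "cytosolic", -3.30, 1.64e-2),
    ("SLC25A22", "TvN", "membrane", -2.77, 1.19e-2),
    ("DPP3", "TvN", "membrane", 2.53, 2.66e-3),
    ("DPP3", "F1vT", "membrane", -1.91, 1.20e-2),
    ("DPP3", "F1vT", "cytosolic", 2.25, 3.86e-4),
    ("GANAB", "TvN", "membrane", 1.67, 7.26e-3),
    ("GANAB", "F1vT", "membrane", -2.04, 2.12e-4),
    ("RANBP2", "F1vT", "cytosolic", 1.93, 8.16e-3),
    ("AKR7A2", "TvN", "cytosolic", -2.09, 1.56e-3),
    ("AKR7A2", "F1vT", "membrane", -1.81, 1.01e-2),
    ("ATP1B3", "TvN", "membrane", 1.88, 3.03e-2),
    ("ATP1B3", "F1vT", "membrane", -2.26, 1.59e-2),
    ("CPM", "F1vT", "membrane", -5.55, 1.31e-2),
    ("FKBP15", "F1vT", "membrane", -4.64, 5.12e-3),
    ("RAB1A", "TvN", "cytosolic", -3.33, 4.87e-3),
    ("UGGT1", "F1vT", "membrane", -1.80, 1.91e-2),
    ("TXNL1", "F1vT", "membrane", -2.54, 2.30e-3),
    ("ATP5F1A", "TvN", "membrane", -2.19, 9.76e-3),
    ("ATP5F1A", "TvN", "cytosolic", -2.70, 1.53e-3),
    ("CALR", "F1vT", "membrane", -2.18, 1.52e-4),
    ("CAPZA1", "F1vT", "membrane", -2.05, 2.49e-3),
    ("CYP20A1", "F1vT", "membrane", -2.50, 6.46e-3),
    ("GNAI3", "F1vT", "membrane", -2.56, 3.85e-4),
    ("HSP90B1", "TvN", "membrane", -6.63, 4.34e-3),
    ("HSP90B1", "F1vT", "membrane", -1.72, 1.11e-2),
    ("HSP90B1", "F1vT", "cytosolic", -2.71, 1.0),  # p not printed
    ("OLA1", "TvN", "membrane", -4.41, 3.21e-4),
    ("PLD3", "F1vT", "membrane", -3.55, 1.13e-3),
    ("PLD3", "F1vT", "cytosolic", -6.41, 1.0),  # p not printed
    ("RECK", "F1vT", "membrane", -12.65, 9.53e-8),
    ("SOD2", "TvN", "membrane", 2.29, 5.88e-3),
    ("TOM1", "F1vT", "membrane", -1.93, 3.90e-2),
]

# the study's published multi-target summary: 7 miRNAs with >= 2
# distinct inversely expressed target proteins
MULTI_TARGET_COUNTS = {
    "hsa-miR-2467-3p": 6,
    "hsa-miR-222-3p": 4,
    "hsa-miR-4742-5p": 3,
    "hsa-miR-509-5p": 3,
    "hsa-miR-4534": 3,
    "hsa-miR-615-3p": 2,
    "hsa-miR-206": 2,
}


def priority_table() -> pd.DataFrame:
    """Priority rows in the layout target integration expects
    (mirna_id, comparison, fc_tvn, p_tvn, fc_f1vt, p_f1vt)."""
    rows = []
    both_ids = {m for m, *_ in BOTH_PRIORITY}
    for m, fc_t, p_t, fc_f, p_f in BOTH_PRIORITY:
        rows.append((m, "both", fc_t, p_t, fc_f, p_f))
    for m, fc, p in TVN_PRIORITY:
        if m not in both_ids:
            rows.append((m, "TvN", fc, p, float("nan"), float("nan")))
    for m, fc, p in F1VT_PRIORITY:
        if m not in both_ids:
            rows.append((m, "F1vT", float("nan"), float("nan"), fc, p))
    return pd.DataFrame(
        rows, columns=["mirna_id", "comparison", "fc_tvn", "p_tvn", "fc_f1vt", "p_f1vt"]
    )


def protein_entries() -> list[ProteinDEEntry]:
    seen = {}
    for g, c, fr, fc, p in PROTEIN_CELLS:
        seen[(g, c, fr)] = ProteinDEEntry(
            gene_symbol=g, comparison=c, fraction=fr, fold_change=fc, p_value=p
        )
    return [seen[k] for k in sorted(seen)]


def permissive_target_table() -> list[TargetRecord]:
    """One maximally permissive prediction per printed (miRNA, gene)
    pair: binding probability 0.99, 3'UTR site, validated. The study
    prints the surviving associations, not the raw prediction scores,
    so the reconstruction is deliberately filter-proof."""
    return [
        TargetRecord(
            mirna_id=m,
            gene_symbol=g,
            binding_probability=0.99,
            region="3UTR",
            validated=True,
            source="published_tables",
        )
        for m, g in sorted(set(TARGET_PAIRS))
    ]


def mrna_entries() -> list[MrnaDEEntry]:
    """The study's printed tables carry no per-gene mRNA rows (the
    elimination was applied upstream of them), so the fixture mRNA
    table is empty."""
    return []
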