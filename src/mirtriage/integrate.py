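"""Target filtering, inverse-expression matching and mRNA elimination.

The attribution logic: a priority miRNA is matched to a protein it is
predicted to target (after the strict prediction filters) whenever the
protein's fold change is strictly opposite in sign to the miRNA's —
the signature of translational repression. Protein changes that are
mirrored by a same-direction mRNA change are then eliminated, since
those are transcriptionally explained rather than candidate miRNA
effects.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict

import numpy as np
import pandas as pd

from .io import AttributionHit, MrnaDEEntry, MultiTargetSummary, ProteinDEEntry, TargetRecord


def filter_targets(
    records: list[TargetRecord],
    min_prob: float = 0.95,
    region: str = "3UTR",
    validated_only: bool = True,
) -> list[TargetRecord]:
    """Keep predictions with binding probability >= min_prob (inclusive),
    the requested binding-site region, and (by default) an
    experimentally validated interaction."""
    return [
        r
        for r in records
        if r.binding_probability >= min_prob
        and r.region == region
        and (r.validated or not validated_only)
    ]


def _row_fc(row, comparison: str) -> float:
    fc = row.fc_tvn if comparison == "TvN" else row.fc_f1vt
    return fc if fc is not None else float("nan")


def inverse_hits(
    priority: pd.DataFrame,
    targets: list[TargetRecord],
    protein_de: list[ProteinDEEntry],
    comparison_policy: str = "same",
) -> list[AttributionHit]:
    """Match priority miRNAs to inversely expressed target proteins.

    ``priority`` is the table from :func:`mirtriage.prioritize.priority_table`
    (columns mirna_id, comparison, fc_tvn, fc_f1vt). For every filtered
    (miRNA, gene) prediction and every protein DE entry of that gene, a
    hit is emitted iff the miRNA and protein fold changes have strictly
    opposite signs. One hit per (miRNA, gene, comparison, fraction).

    comparison_policy
        ``"same"``: a protein entry is only matched against the miRNA's
        fold change in the entry's own comparison (``both`` miRNAs match
        either comparison). ``"any"``: a protein entry in either
        comparison may be attributed to the miRNA; the miRNA fold
        change used is the one from the entry's comparison when the
        miRNA has one, else the miRNA's own contrast. The published
        integration tables pair xenograft-contrast miRNAs with proteins
        whose only DE evidence sits in the tumor/normal contrast, so
        reproducing them requires ``"any"``.
    """
    if comparison_policy not in ("same", "any"):
        raise ValueError(f"unknown comparison_policy {comparison_policy!r}")

    gene_targets: dict[str, set[str]] = defaultdict(set)
    for t in targets:
        gene_targets[t.mirna_id].add(t.gene_symbol)
    by_gene: dict[str, list[ProteinDEEntry]] = defaultdict(list)
    for e in protein_de:
        by_gene[e.gene_symbol].append(e)

    # candidate hits keyed by (mirna, gene, comparison, fraction);
    # same-comparison matches take precedence when deduplicating
    best: dict[tuple, tuple[int, AttributionHit]] = {}
    for row in priority.itertuples(index=False):
        own = ("TvN", "F1vT") if row.comparison == "both" else (row.comparison,)
        for gene in sorted(gene_targets.get(row.mirna_id, ())):
            for entry in by_gene.get(gene, ()):
                same_comp = entry.comparison in own
                if comparison_policy == "same" and not same_comp:
                    continue
                if same_comp or not np.isnan(_row_fc(row, entry.comparison)):
                    mirna_fc = _row_fc(row, entry.comparison)
                else:
                    mirna_fc = _row_fc(row, own[0])
                if np.isnan(mirna_fc) or mirna_fc * entry.fold_change >= 0:
                    continue
                hit = AttributionHit(
                    mirna_id=row.mirna_id,
                    gene_symbol=gene,
                    comparison=entry.comparison,
                    fraction=entry.fraction,
                    mirna_fc=mirna_fc,
                    protein_fc=entry.fold_change,
                )
                key = (row.mirna_id, gene, entry.comparison, entry.fraction)
                rank = 0 if same_comp else 1
                if key not in best or rank < best[key][0]:
                    best[key] = (rank, hit)
    return [best[k][1] for k in sorted(best)]


def mrna_concordance_filter(
    hits: list[AttributionHit],
    mrna_de: list[MrnaDEEntry],
) -> list[AttributionHit]:
    """Eliminate transcriptionally explained hits.

    For each hit, the gene's mRNA entry in the protein's comparison is
    consulted: a same-sign mRNA change marks the hit ``concordant`` and
    removes it; an opposite-sign change marks it ``discordant``; no
    entry marks it ``absent``. Discordant and absent hits survive.
    """
    mrna = {(e.gene_symbol, e.comparison): e for e in mrna_de}
    survivors = []
    for h in hits:
        entry = mrna.get((h.gene_symbol, h.comparison))
        if entry is None:
            status = "absent"
        elif np.sign(entry.fold_change) == np.sign(h.protein_fc):
            status = "concordant"
        else:
            status = "discordant"
        if status != "concordant":
            survivors.append(dataclasses.replace(h, mrna_status=status))
    return survivors


def multi_target_summary(hits: list[AttributionHit]) -> list[MultiTargetSummary]:
    """miRNAs associated with >= 2 distinct proteins across all
    comparisons and fractions, sorted by count descending then id."""
    genes: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        genes[h.mirna_id].add(h.gene_symbol)
    rows = [
        MultiTargetSummary(
            mirna_id=m,
            n_distinct_proteins=len(gs),
            proteins=",".join(sorted(gs)),
        )
        for m, gs in genes.items()
        if len(gs) >= 2
    ]
    rows.sort(key=lambda r: (-r.n_distinct_proteins, r.mirna_id))
    return rows
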