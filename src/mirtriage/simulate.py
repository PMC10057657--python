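"""Synthetic tri-omics generator with known ground truth.

Emulates the data structure the pipeline consumes: a three-group
(N/T/F1) log2 miRNA expression matrix with planted differential
expression, a target-prediction table mixing true high-confidence
records with filter-violating decoys, and protein/mRNA DE tables in
which planted miRNA->protein regulatory edges produce inverse protein
changes with no mRNA support, while transcriptional decoy proteins
move together with their mRNA. Everything is reproducible from one
seed. What it deliberately does not model: probe-level intensities,
batch effects, or mass-spectrometry missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MrnaDEEntry, ProteinDEEntry, TargetRecord
from .stats import signed_fc

FRACTION_CHOICES = (("membrane",), ("cytosolic",), ("membrane", "cytosolic"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Cohort sizes default to the study design (5 adjacent normal, 7
    tumor, 8 first-passage xenograft). Planted log2 effects are drawn
    uniformly from [effect_low, effect_high] with random sign, all
    comfortably clearing the 1.5-fold filter at the low end; noise_sd
    is per-observation Gaussian noise on the log2 scale. The protein
    response to a regulating miRNA is attenuated by ``beta`` (log2
    protein shift = -beta * miRNA shift).
    """

    n_mirna: int = 300
    n_genes: int = 400
    n_normal: int = 5
    n_tumor: int = 7
    n_pdx: int = 8
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    de_fraction_tvn: float = 0.15
    de_fraction_f1vt: float = 0.2
    both_same_direction_count: int = 6
    effect_low: float = 0.7
    effect_high: float = 3.0
    noise_sd: float = 0.3
    targets_per_de_mirna: float = 3.0
    decoy_target_count: int = 60
    beta: float = 0.8
    transcriptional_decoy_fraction: float = 0.1
    non_human_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "de_fraction_tvn",
            "de_fraction_f1vt",
            "transcriptional_decoy_fraction",
            "non_human_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_normal, self.n_tumor, self.n_pdx) < 2:
            raise ValueError("every group needs >= 2 samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.effect_low <= self.effect_high):
            raise ValueError("need 0 < effect_low <= effect_high")


@dataclass(frozen=True)
class Edge:
    """One planted regulatory edge: miRNA m represses gene g in one contrast."""

    mirna_id: str
    gene_symbol: str
    comparison: str


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: per-contrast miRNA effects (log2), regulatory
    edges, and the mechanism behind each gene's protein change."""

    mirna_effects: dict  # (mirna_id, comparison) -> planted log2 effect
    edges: tuple[Edge, ...]
    mechanism: dict  # gene_symbol -> {"mirna_regulated", "transcriptional", "null"}
    config: SimConfig


@dataclass(frozen=True)
class SimData:
    matrix: ExpressionMatrix
    targets: list[TargetRecord]
    protein_de: list[ProteinDEEntry]
    mrna_de: list[MrnaDEEntry]
    truth: GroundTruth


def _p_true(rng) -> float:
    return float(rng.uniform(1e-6, 0.01))


def _p_null(rng) -> float:
    return float(rng.uniform(0.2, 1.0))


def generate(config: SimConfig | None = None) -> SimData:
    """Generate one tri-omics dataset plus its ground truth.

    All randomness flows through a single generator seeded from
    ``config.seed``, with a fixed draw order, so identical configs give
    byte-identical outputs.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    n_mmu = round(cfg.n_mirna * cfg.non_human_fraction)
    n_hsa = cfg.n_mirna - n_mmu
    hsa_ids = [f"hsa-miR-{i:04d}-5p" for i in range(n_hsa)]
    mmu_ids = [f"mmu-miR-{i:04d}-5p" for i in range(n_mmu)]
    feature_ids = hsa_ids + mmu_ids

    n_tvn = round(cfg.de_fraction_tvn * cfg.n_mirna)
    n_f1vt = round(cfg.de_fraction_f1vt * cfg.n_mirna)
    n_both = cfg.both_same_direction_count
    if n_tvn + n_f1vt + n_both > n_hsa:
        raise ValueError(
            f"infeasible config: {n_tvn}+{n_f1vt}+{n_both} planted DE miRNAs "
            f"exceed the {n_hsa} human features"
        )
    picked = list(rng.choice(n_hsa, size=n_tvn + n_f1vt + n_both, replace=False))
    tvn_set = [hsa_ids[i] for i in picked[:n_tvn]]
    f1vt_set = [hsa_ids[i] for i in picked[n_tvn : n_tvn + n_f1vt]]
    both_set = [hsa_ids[i] for i in picked[n_tvn + n_f1vt :]]

    def draw_effect() -> float:
        mag = rng.uniform(cfg.effect_low, cfg.effect_high)
        return float(mag if rng.random() < 0.5 else -mag)

    effects: dict[tuple[str, str], float] = {}
    for m in tvn_set:
        effects[(m, "TvN")] = draw_effect()
    for m in f1vt_set:
        effects[(m, "F1vT")] = draw_effect()
    for m in both_set:
        e = draw_effect()
        effects[(m, "TvN")] = e
        # same sign in both contrasts, independently drawn magnitude
        effects[(m, "F1vT")] = math.copysign(
            rng.uniform(cfg.effect_low, cfg.effect_high), e
        )
    # non-human transcripts shift at the combined DE rate so the species
    # filter has work to do; a fully null config plants nothing anywhere
    p_mmu = cfg.de_fraction_tvn + cfg.de_fraction_f1vt
    for m in mmu_ids:
        if rng.random() < p_mmu:
            effects[(m, "TvN")] = draw_effect()

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_mirna)
    delta_t = np.array([effects.get((m, "TvN"), 0.0) for m in feature_ids])
    delta_f1 = delta_t + np.array(
        [effects.get((m, "F1vT"), 0.0) for m in feature_ids]
    )
    sample_ids, group_of, shifts = [], {}, []
    for g, n, d in (
        ("N", cfg.n_normal, np.zeros(cfg.n_mirna)),
        ("T", cfg.n_tumor, delta_t),
        ("F1", cfg.n_pdx, delta_f1),
    ):
        for j in range(n):
            sid = f"{g}{j + 1}"
            sample_ids.append(sid)
            group_of[sid] = g
            shifts.append(d)
    signal = baseline[:, None] + np.column_stack(shifts)
    noise = rng.normal(0.0, cfg.noise_sd, size=signal.shape) if cfg.noise_sd > 0 else 0.0
    matrix = ExpressionMatrix(
        pd.DataFrame(signal + noise, index=feature_ids, columns=sample_ids),
        group_of,
    )

    # --- gene layer -------------------------------------------------------
    gene_ids = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    pool = list(gene_ids)  # genes not yet assigned a mechanism
    mechanism = {g: "null" for g in gene_ids}

    de_mirnas = tvn_set + f1vt_set + both_set
    edges: list[Edge] = []
    targets: list[TargetRecord] = []
    protein_rows: dict[tuple[str, str, str], ProteinDEEntry] = {}
    mrna_rows: dict[tuple[str, str], MrnaDEEntry] = {}

    def take_genes(k: int) -> list[str]:
        if k > len(pool):
            raise ValueError(
                "infeasible config: regulated/decoy genes exceed n_genes"
            )
        idx = rng.choice(len(pool), size=k, replace=False)
        chosen = [pool[i] for i in sorted(idx, reverse=True)]
        for i in sorted(idx, reverse=True):
            del pool[i]
        return chosen

    for m in de_mirnas:
        k = 1 + rng.poisson(cfg.targets_per_de_mirna - 1.0)
        for g in take_genes(int(k)):
            mechanism[g] = "mirna_regulated"
            targets.append(
                TargetRecord(
                    mirna_id=m,
                    gene_symbol=g,
                    binding_probability=float(rng.uniform(0.95, 1.0)),
                    region="3UTR",
                    validated=True,
                    source="sim_true",
                )
            )
            comps = [c for c in ("TvN", "F1vT") if (m, c) in effects]
            for c in comps:
                edges.append(Edge(m, g, c))
                prot_log2 = -cfg.beta * effects[(m, c)]
                for fr in FRACTION_CHOICES[int(rng.integers(3))]:
                    protein_rows[(g, c, fr)] = ProteinDEEntry(
                        gene_symbol=g,
                        comparison=c,
                        fraction=fr,
                        fold_change=float(signed_fc(prot_log2)),
                        p_value=_p_true(rng),
                    )
                # no mRNA entry: the protein change is post-transcriptional

    # decoys hang off planted miRNAs; a fully null configuration has none
    n_decoy_genes = (
        round(cfg.transcriptional_decoy_fraction * cfg.n_genes) if de_mirnas else 0
    )
    for g in take_genes(n_decoy_genes):
        mechanism[g] = "transcriptional"
        m = de_mirnas[int(rng.integers(len(de_mirnas)))]
        c = [cc for cc in ("TvN", "F1vT") if (m, cc) in effects][0]
        # inverse to the miRNA (so it shows up as a hit) but driven by
        # transcription: the mRNA moves with the protein
        prot_log2 = -math.copysign(rng.uniform(0.7, 2.5), effects[(m, c)])
        targets.append(
            TargetRecord(
                mirna_id=m,
                gene_symbol=g,
                binding_probability=float(rng.uniform(0.95, 1.0)),
                region="3UTR",
                validated=True,
                source="sim_transcriptional_decoy",
            )
        )
        for fr in FRACTION_CHOICES[int(rng.integers(3))]:
            protein_rows[(g, c, fr)] = ProteinDEEntry(
                gene_symbol=g,
                comparison=c,
                fraction=fr,
                fold_change=float(signed_fc(prot_log2)),
                p_value=_p_true(rng),
            )
        mrna_rows[(g, c)] = MrnaDEEntry(
            gene_symbol=g,
            comparison=c,
            fold_change=float(signed_fc(math.copysign(rng.uniform(0.7, 2.5), prot_log2))),
            p_value=_p_true(rng),
        )

    # decoy predictions violating >= 1 filter rule, aimed at null genes
    null_genes = [g for g in gene_ids if mechanism[g] == "null"]
    for _ in range(cfg.decoy_target_count):
        m = feature_ids[int(rng.integers(len(feature_ids)))]
        g = null_genes[int(rng.integers(len(null_genes)))]
        kind = int(rng.integers(3))
        targets.append(
            TargetRecord(
                mirna_id=m,
                gene_symbol=g,
                binding_probability=(
                    float(rng.uniform(0.5, 0.949)) if kind == 0 else float(rng.uniform(0.95, 1.0))
                ),
                region="3UTR" if kind != 1 else ("5UTR", "CDS")[int(rng.integers(2))],
                validated=kind != 2,
                source="sim_decoy",
            )
        )
    # background protein/mRNA noise on null genes (direction random,
    # p-values null-sized); no filtered prediction points at them
    for g in null_genes:
        if rng.random() < 0.3:
            c = ("TvN", "F1vT")[int(rng.integers(2))]
            fr = ("membrane", "cytosolic")[int(rng.integers(2))]
            protein_rows[(g, c, fr)] = ProteinDEEntry(
                gene_symbol=g,
                comparison=c,
                fraction=fr,
                fold_change=float(signed_fc(math.copysign(rng.uniform(0.6, 2.0), rng.standard_normal()))),
                p_value=_p_null(rng),
            )
        if rng.random() < 0.3:
            c = ("TvN", "F1vT")[int(rng.integers(2))]
            mrna_rows[(g, c)] = MrnaDEEntry(
                gene_symbol=g,
                comparison=c,
                fold_change=float(signed_fc(math.copysign(rng.uniform(0.6, 2.0), rng.standard_normal()))),
                p_value=_p_null(rng),
            )

    truth = GroundTruth(
        mirna_effects=dict(effects),
        edges=tuple(edges),
        mechanism=mechanism,
        config=cfg,
    )
    protein_de = [protein_rows[k] for k in sorted(protein_rows)]
    return SimData(
        matrix=matrix,
        targets=targets,
        protein_de=protein_de,
        mrna_de=[mrna_rows[k] for k in sorted(mrna_rows)],
        truth=truth,
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    """Recovery of planted structure by the pipeline."""

    edge_recall: float  # recovered / planted edges among DE-passing miRNAs
    edge_precision: float  # NaN (with flag) when there are no hits
    n_eligible_edges: int
    n_recovered_edges: int
    n_hits: int
    de_sensitivity: dict = field(default_factory=dict)  # per comparison
    de_specificity: dict = field(default_factory=dict)
    precision_defined: bool = True


def truth_report(
    truth: GroundTruth,
    hits,
    de_passed: dict[str, set] | None = None,
) -> RecoveryMetrics:
    """Score pipeline hits against the planted truth.

    ``de_passed`` maps comparison -> set of feature ids that passed the
    DE cascade; when given, edge recall is computed over planted edges
    whose miRNA passed in the edge's comparison (edges silenced by the
    DE filter are not counted against recall). Precision is the
    fraction of hits that land on a planted edge; with no hits it is
    undefined and reported as NaN with ``precision_defined=False``.
    """
    hit_keys = {(h.mirna_id, h.gene_symbol, h.comparison) for h in hits}
    if de_passed is None:
        eligible = list(truth.edges)
    else:
        eligible = [
            e for e in truth.edges if e.mirna_id in de_passed.get(e.comparison, set())
        ]
    recovered = [
        e for e in eligible if (e.mirna_id, e.gene_symbol, e.comparison) in hit_keys
    ]
    recall = len(recovered) / len(eligible) if eligible else float("nan")

    edge_keys = {(e.mirna_id, e.gene_symbol, e.comparison) for e in truth.edges}
    if hit_keys:
        precision = len(hit_keys & edge_keys) / len(hit_keys)
        defined = True
    else:
        precision = float("nan")
        defined = False

    sens, spec = {}, {}
    if de_passed is not None:
        for c, called in de_passed.items():
            planted = {m for (m, cc) in truth.mirna_effects if cc == c and m.startswith("hsa")}
            hsa_nulls = {m for m in _all_hsa(truth) if m not in planted}
            sens[c] = len(called & planted) / len(planted) if planted else float("nan")
            spec[c] = (
                len(hsa_nulls - called) / len(hsa_nulls) if hsa_nulls else float("nan")
            )
    return RecoveryMetrics(
        edge_recall=recall,
        edge_precision=precision,
        n_eligible_edges=len(eligible),
        n_recovered_edges=len(recovered),
        n_hits=len(hit_keys),
        de_sensitivity=sens,
        de_specificity=spec,
        precision_defined=defined,
    )


def _all_hsa(truth: GroundTruth) -> list[str]:
    n_mmu = round(truth.config.n_mirna * truth.config.non_human_fraction)
    n_hsa = truth.config.n_mirna - n_mmu
    return [f"hsa-miR-{i:04d}-5p" for i in range(n_hsa)]
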