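"""End-to-end orchestration: DE -> priority lists -> target attribution.

Used by both the command-line interface and the analysis drivers. All
outputs are deterministic TSVs carrying a provenance header (input
hashes and the parameters in force) so reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from . import provenance as prov
from .integrate import filter_targets, inverse_hits, mrna_concordance_filter, multi_target_summary
from .io import AttributionHit, MultiTargetSummary
from .prioritize import priority_table, same_direction, top_k
from .stats import FilterSpec, de_filter, run_de

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; mirrors the YAML config file."""

    expression: str = ""
    sample_sheet: str = ""
    targets: str = ""
    protein_de: str = ""
    mrna_de: str = ""
    origin_calls: str = ""  # optional provenance filter for F1vT proteins
    out_dir: str = "results"
    fc_min: float = 1.5
    p_max: float = 0.05
    f_fdr_max: float = 0.005
    species_prefix: str = "hsa"
    min_prob: float = 0.95
    region: str = "3UTR"
    validated_only: bool = True
    top_k: int = 10
    apply_mrna_filter: bool = True
    comparison_policy: str = "same"
    seed: int = 0  # used by the simulate subcommand only

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            fc_min=self.fc_min,
            p_max=self.p_max,
            f_fdr_max=self.f_fdr_max,
            species_prefix=self.species_prefix,
        )


def _sha(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _header(stage: str, cfg: PipelineConfig, inputs: list[str]) -> list[str]:
    params = (
        f"fc_min={cfg.fc_min} p_max={cfg.p_max} f_fdr_max={cfg.f_fdr_max} "
        f"species={cfg.species_prefix} min_prob={cfg.min_prob} region={cfg.region} "
        f"validated_only={cfg.validated_only} top_k={cfg.top_k} "
        f"apply_mrna_filter={cfg.apply_mrna_filter} policy={cfg.comparison_policy}"
    )
    lines = [f"mirtriage {stage}", f"params: {params}"]
    lines += [f"input: {Path(p).name} sha256:{_sha(p)}" for p in inputs if p]
    return lines


@dataclass
class RunBundle:
    de_tables: dict[str, pd.DataFrame]
    de_filtered: dict[str, pd.DataFrame]
    priority: pd.DataFrame
    hits: list[AttributionHit]
    summary: list[MultiTargetSummary]
    out_dir: Path | None = None
    written: list[str] = field(default_factory=list)


def check_inputs(cfg: PipelineConfig) -> None:
    """Fail before any computation if a referenced input is missing."""
    labels = {
        "expression": cfg.expression,
        "sample_sheet": cfg.sample_sheet,
        "targets": cfg.targets,
        "protein_de": cfg.protein_de,
    }
    if cfg.apply_mrna_filter:
        labels["mrna_de"] = cfg.mrna_de
    if cfg.origin_calls:
        labels["origin_calls"] = cfg.origin_calls
    for name, p in labels.items():
        if not p:
            raise FileNotFoundError(f"configuration error: {name} is not set")
        if not Path(p).is_file():
            raise FileNotFoundError(f"configuration error: {name} file not found: {p}")


def run(cfg: PipelineConfig) -> RunBundle:
    """Execute the full pipeline and write the report bundle."""
    check_inputs(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cfg.filter_spec()

    stage = "de"
    try:
        matrix = mio.read_expression_matrix(cfg.expression, cfg.sample_sheet)
        de = run_de(matrix, spec)
        filtered = {c: de_filter(t, spec) for c, t in de.items()}
        written = []
        for c, t in de.items():
            p = out / f"de_{c}.tsv"
            mio.write_frame(
                t,
                p,
                _header("de", cfg, [cfg.expression, cfg.sample_sheet]),
            )
            written.append(str(p))

        stage = "prioritize"
        for c, t in filtered.items():
            for direction in ("up", "down"):
                p = out / f"top{cfg.top_k}_{direction}_{c}.tsv"
                mio.write_frame(
                    top_k(t, cfg.top_k, direction),
                    p,
                    _header("prioritize", cfg, [cfg.expression]),
                )
                written.append(str(p))
        both = same_direction(filtered["TvN"], filtered["F1vT"])
        p = out / "same_direction.tsv"
        mio.write_frame(both, p, _header("prioritize", cfg, [cfg.expression]))
        written.append(str(p))
        priority = priority_table(filtered["TvN"], filtered["F1vT"], k=cfg.top_k)

        stage = "integrate"
        targets = filter_targets(
            mio.read_target_table(cfg.targets),
            min_prob=cfg.min_prob,
            region=cfg.region,
            validated_only=cfg.validated_only,
        )
        known = {t.mirna_id for t in targets}
        orphan = sorted(known - set(priority["mirna_id"]))
        if orphan:
            log.warning(
                "integrate: %d target-table miRNA(s) absent from the priority list",
                len(orphan),
            )
        protein = mio.read_protein_de_table(cfg.protein_de)
        if cfg.origin_calls:
            stage = "provenance"
            calls = mio.read_origin_calls(cfg.origin_calls)
            protein = prov.filter_human_proteins(protein, calls)
            stage = "integrate"
        hits = inverse_hits(
            priority, targets, protein, comparison_policy=cfg.comparison_policy
        )
        if cfg.apply_mrna_filter:
            mrna = mio.read_mrna_de_table(cfg.mrna_de)
            hits = mrna_concordance_filter(hits, mrna)
        summary = multi_target_summary(hits)

        hdr_in = [cfg.expression, cfg.targets, cfg.protein_de]
        if cfg.apply_mrna_filter:
            hdr_in.append(cfg.mrna_de)
        p = out / "hits.tsv"
        mio.write_report(hits, p, _header("integrate", cfg, hdr_in), cls=AttributionHit)
        written.append(str(p))
        p = out / "multi_target_summary.tsv"
        mio.write_report(
            summary, p, _header("integrate", cfg, hdr_in), cls=MultiTargetSummary
        )
        written.append(str(p))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return RunBundle(
        de_tables=de,
        de_filtered=filtered,
        priority=priority,
        hits=hits,
        summary=summary,
        out_dir=out,
        written=written,
    )
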