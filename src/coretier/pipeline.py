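"""End-to-end orchestration: filter -> transform -> tiers -> partition -> NCM -> DOC -> networks.

One root seed deterministically spawns per-stage seeds; all tabular
outputs are written with fixed float formatting so a re-run with an
identical configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import conet, core_tiers, doc, ncm, preprocess, tables
from .tables import CountTable, SampleMetadata

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

STAGES = ("filter", "core", "ncm", "doc", "net")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    counts_path: str
    metadata_path: str
    seed: int | None = None
    host: str | None = None
    counts_format: str = "tsv"
    min_depth: int = 1000
    drop_max_total: int = 2
    subsample: int = 30
    reps: int = 100
    target_abundance: float = 0.5
    scale_factor: int = 1000
    ncm_n_boot: int = 1000
    ncm_band_method: str = "bootstrap"
    doc_lowess_frac: float = 2.0 / 3.0
    doc_n_boot: int = 100
    doc_null_reps: int = 100
    rho_min: float = 0.8
    p_max: float = 0.001
    min_edge_freq: int = 20
    d_weights: tuple[float, float, float] = (0.45, 0.45, 0.10)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "d_weights" in data:
            data["d_weights"] = tuple(data["d_weights"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["d_weights"] = list(self.d_weights)
        return d


def stage_seeds(root_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from one root seed."""
    rng = np.random.default_rng(root_seed)
    draws = rng.integers(0, 2**31 - 1, size=len(STAGES))
    return {stage: int(s) for stage, s in zip(STAGES, draws)}


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute every stage for one host; returns the machine-readable report.

    Outputs land in ``out_dir``: the serialized config, filtered table,
    threshold sweep, tier table, partition, NCM fit and per-taxon labels,
    DOC summaries per partition, and the combined co-occurrence network.
    Any stage failure halts the run, after writing a partial report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    report: dict = {"config": cfg.to_dict(), "seeds": seeds}
    _write_json(report["config"], out / "config.json")

    try:
        stage = "filter"
        raw = tables.read_count_table(cfg.counts_path, format=cfg.counts_format)
        meta = tables.read_metadata(cfg.metadata_path)
        if cfg.host is not None:
            rows = meta.for_samples(raw.sample_ids)
            keep = np.flatnonzero((rows["host"] == cfg.host).to_numpy())
            raw = raw.select_samples(keep)
        filtered = preprocess.filter_table(raw, cfg.min_depth, cfg.drop_max_total)
        abundance = preprocess.hellinger(filtered)
        tables.write_count_table(filtered, out / "filtered.tsv")
        report["filter"] = {
            "n_samples_in": raw.n_samples,
            "n_taxa_in": raw.n_taxa,
            "n_samples_kept": filtered.n_samples,
            "n_taxa_kept": filtered.n_taxa,
        }

        stage = "core"
        real_subs = core_tiers.subcommunities_by_site(filtered, meta)
        sim_subs = core_tiers.simulate_subcommunities(
            filtered, n_samples=cfg.subsample, reps=cfg.reps, seed=seeds["core"]
        )
        sweep = core_tiers.threshold_sweep(real_subs, sim_subs, abundance)
        tiers = core_tiers.identify_tiers(sweep)
        sweep.to_dataframe().to_csv(out / "sweep.csv", index=False, float_format=FLOAT_FMT)
        _write_json(tiers.to_records(), out / "tiers.json")
        if not tiers:
            raise ValueError("no tiers identified; cannot partition the community")
        partition = core_tiers.select_tier(tiers, cfg.target_abundance, host=cfg.host)
        partition.to_series().to_csv(out / "partition.tsv", sep="\t", index_label="taxon")
        report["core"] = {
            "n_sites": len(real_subs),
            "n_tiers": len(tiers.tiers),
            "selected_tier": partition.tier_index,
            "core_size": len(partition.core),
        }

        stage = "ncm"
        scaled = preprocess.scale_round(abundance, cfg.scale_factor)
        fit = ncm.fit_ncm(
            scaled, seed=seeds["ncm"], n_boot=cfg.ncm_n_boot, band_method=cfg.ncm_band_method
        )
        labels = ncm.classify_taxa(fit)
        fit.taxa.to_csv(out / "ncm_taxa.csv", index=False, float_format=FLOAT_FMT)
        props = ncm.partition_proportions(labels, sweep)
        props.to_csv(out / "ncm_partition_proportions.csv", index=False, float_format=FLOAT_FMT)
        _write_json(
            {
                "m": fit.m,
                "N": fit.N,
                "Nm": fit.Nm,
                "r_squared": fit.r_squared,
                "m_ci": list(fit.m_ci),
                "band_method": fit.band_method,
                "n_boot": fit.n_boot,
            },
            out / "ncm_fit.json",
        )
        report["ncm"] = {"m": fit.m, "Nm": fit.Nm, "r_squared": fit.r_squared}

        stage = "doc"
        report["doc"] = {}
        for which, taxa in (("core", partition.core), ("noncore", partition.noncore)):
            sub_taxa = [t for t in abundance.taxon_ids if t in taxa]
            cols = [j for j, t in enumerate(abundance.taxon_ids) if t in taxa]
            values = abundance.values[:, cols]
            keep_rows = np.flatnonzero(values.sum(axis=1) > 0)
            part_table = tables.AbundanceTable(
                [abundance.sample_ids[i] for i in keep_rows], sub_taxa,
                np.minimum(values[keep_rows], 1.0),
            )
            points = doc.doc_points(part_table)
            result = doc.fit_doc(
                points, lowess_frac=cfg.doc_lowess_frac, n_boot=cfg.doc_n_boot,
                seed=seeds["doc"],
            )
            nulls = doc.doc_null(
                part_table, reps=cfg.doc_null_reps, seed=seeds["doc"],
                lowess_frac=cfg.doc_lowess_frac, grid=result.grid,
            )
            points.pairs.to_csv(out / f"doc_points_{which}.csv", index=False, float_format=FLOAT_FMT)
            np.savetxt(
                out / f"doc_curve_{which}.csv",
                np.column_stack([result.grid, result.curve, result.band_low, result.band_high]),
                delimiter=",", header="overlap,curve,band_low,band_high", comments="", fmt=FLOAT_FMT,
            )
            np.savetxt(out / f"doc_null_{which}.csv", np.array(nulls), delimiter=",", fmt=FLOAT_FMT)
            report["doc"][which] = {
                "n_pairs": len(points),
                "change_point": result.change_point,
                "fraction_negative_slope": result.fraction_negative_slope,
                "terminal_slope": doc.terminal_slope(result.grid, result.curve),
            }

        stage = "net"
        nets = [
            conet.spearman_network(v, rho_min=cfg.rho_min, p_max=cfg.p_max)
            for v in sim_subs
        ]
        combined = conet.combine_networks(nets, min_freq=cfg.min_edge_freq)
        combined.histogram.to_csv(out / "edge_frequency_histogram.csv", index=False)
        metrics = conet.node_metrics(combined)
        metrics.to_csv(out / "combined_node_metrics.csv", index=False, float_format=FLOAT_FMT)
        edge_rows = [
            {"taxon_a": min(e), "taxon_b": max(e), "frequency": c}
            for e, c in sorted(combined.edges.items(), key=lambda kv: sorted(kv[0]))
        ]
        _write_json(edge_rows, out / "combined_edges.json")
        report["net"] = {
            "n_networks": len(nets),
            "n_combined_edges": len(combined.edges),
            "n_connected_vertices": int(sum(1 for r in metrics.itertuples() if r.degree > 0)),
        }
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        _write_json(_jsonable(report), out / "report.json")
        raise PipelineError(stage, exc) from exc

    _write_json(_jsonable(report), out / "report.json")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
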