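"""End-to-end orchestration: filter -> normalize -> contrasts -> waves -> projection.

A run is driven by one JSON config (archivable, hashable) and a mandatory
seed; outputs are plain TSV/CSV plus a ``manifest.json`` recording the
config hash, seed, per-stage gene counts, and the SHA-256 of every file
written, so identical configs reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cascade import StageMap, assign_stages, consecutive_contrasts, stringent_filter
from .counts import (
    CountMatrix,
    filter_low_expression,
    normalize_counts,
    size_factors_median_ratio,
)
from .diffexpr import DEThresholds
from .errors import ConfigurationError
from .io import (
    read_count_matrix,
    read_reference_atlas,
    write_count_matrix,
)
from .projection import ReferenceAtlas, map_samples_to_atlas, projection_results_frame
from .simulate import (
    AtlasConfig,
    SimConfig,
    generate_reference_atlas,
    generate_time_course,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated form of the JSON run configuration.

    ``bulk`` is either ``{"synthetic": {...SimConfig fields...}}`` or
    ``{"counts_tsv": path}`` (metadata sidecar resolved automatically);
    ``projection`` is null to skip, or carries either ``{"synthetic_atlas":
    {...AtlasConfig fields...}}`` or ``{"atlas_dir": path}`` plus the
    projection parameters.
    """

    seed: int
    bulk: dict
    outdir: Path
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    stage_map: StageMap = field(default_factory=StageMap)
    stringent: str = "none"
    de_method: str = "moderated_t"
    min_any_sample: int = 10
    max_le: float = 30.0
    projection: dict | None = None

    @classmethod
    def from_dict(cls, raw: dict, outdir: str | Path | None = None, seed: int | None = None) -> "PipelineConfig":
        if seed is None:
            seed = raw.get("seed")
        if seed is None:
            raise ConfigurationError("seed is mandatory (config key 'seed' or --seed)")
        out = outdir if outdir is not None else raw.get("outdir")
        if out is None:
            raise ConfigurationError("output directory is mandatory (config key 'outdir' or --outdir)")
        bulk = raw.get("bulk")
        if not isinstance(bulk, dict) or not ({"synthetic", "counts_tsv"} & set(bulk)):
            raise ConfigurationError("bulk must provide 'synthetic' or 'counts_tsv'")
        if "counts_tsv" in bulk and not Path(bulk["counts_tsv"]).exists():
            raise ConfigurationError(f"bulk.counts_tsv does not exist: {bulk['counts_tsv']}")
        projection = raw.get("projection")
        if projection is not None:
            if not isinstance(projection, dict) or not (
                {"synthetic_atlas", "atlas_dir"} & set(projection)
            ):
                raise ConfigurationError(
                    "projection must provide 'synthetic_atlas' or 'atlas_dir' (or be null)"
                )
            if "atlas_dir" in projection and not Path(projection["atlas_dir"]).is_dir():
                raise ConfigurationError(
                    f"projection.atlas_dir does not exist: {projection['atlas_dir']}"
                )
        th = raw.get("thresholds", {})
        thresholds = DEThresholds(
            fdr_max=th.get("fdr_max", 0.05), min_abs_fold=th.get("min_abs_fold", 2.0)
        )
        stage_map = (
            StageMap.from_dict(raw["stage_map"]) if "stage_map" in raw else StageMap()
        )
        stringent = raw.get("stringent", "none")
        if stringent not in ("none", "sustained"):
            raise ConfigurationError(f"stringent must be 'none' or 'sustained', got {stringent!r}")
        filters = raw.get("filters", {})
        return cls(
            seed=int(seed),
            bulk=bulk,
            outdir=Path(out),
            thresholds=thresholds,
            stage_map=stage_map,
            stringent=stringent,
            de_method=raw.get("de_method", "moderated_t"),
            min_any_sample=int(filters.get("min_any_sample", 10)),
            max_le=float(filters.get("max_le", 30.0)),
            projection=projection,
        )

    @classmethod
    def from_json(cls, path: str | Path, outdir=None, seed=None) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()), outdir=outdir, seed=seed)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "bulk": self.bulk,
            "outdir": str(self.outdir),
            "thresholds": {
                "fdr_max": self.thresholds.fdr_max,
                "min_abs_fold": self.thresholds.min_abs_fold,
            },
            "stage_map": self.stage_map.to_dict(),
            "stringent": self.stringent,
            "de_method": self.de_method,
            "filters": {"min_any_sample": self.min_any_sample, "max_le": self.max_le},
            "projection": self.projection,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_bulk(config: PipelineConfig) -> tuple[CountMatrix, object | None]:
    if "synthetic" in config.bulk:
        sim = SimConfig(**{**config.bulk["synthetic"], "seed": config.seed})
        matrix, truth = generate_time_course(sim)
        return matrix, truth
    return read_count_matrix(config.bulk["counts_tsv"], format="tsv"), None


def _load_atlas(config: PipelineConfig) -> ReferenceAtlas:
    proj = config.projection
    if "synthetic_atlas" in proj:
        atlas_cfg = AtlasConfig(**{**proj["synthetic_atlas"], "seed": config.seed + 1})
        atlas, _ = generate_reference_atlas(atlas_cfg)
        return atlas
    return read_reference_atlas(proj["atlas_dir"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the manifest dict."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    stage_name = "load"
    try:
        matrix, truth = _load_bulk(config)
        write_count_matrix(matrix, emit(outdir / "counts_raw.tsv"))
        emit(outdir / "counts_raw.samples.csv")
        if truth is not None:
            truth.to_csv(emit(outdir / "stage_truth.csv"))

        stage_name = "filter"
        filtered = filter_low_expression(matrix, config.min_any_sample, config.max_le)
        write_count_matrix(filtered, emit(outdir / "counts_filtered.tsv"))
        emit(outdir / "counts_filtered.samples.csv")

        stage_name = "normalize"
        sf = size_factors_median_ratio(filtered)
        sf.rename("size_factor").to_csv(emit(outdir / "size_factors.csv"))
        norm = normalize_counts(filtered, sf)
        norm.values.to_csv(emit(outdir / "normalized.tsv"), sep="\t")

        stage_name = "contrasts"
        contrasts = consecutive_contrasts(norm, method=config.de_method)
        for table in contrasts:
            name = f"contrast_{table.group_a}_{table.group_b}.tsv"
            table.to_tsv(emit(outdir / name))

        stage_name = "stages"
        assignment = assign_stages(contrasts, config.stage_map, config.thresholds)
        assignment = stringent_filter(assignment, norm, mode=config.stringent)
        assignment.to_tsv(emit(outdir / "stage_assignment.tsv"))
        stage_counts = assignment.stage_counts()

        projection_rows = None
        if config.projection is not None:
            stage_name = "projection"
            atlas = _load_atlas(config)
            results = map_samples_to_atlas(
                atlas,
                filtered,
                n_components=config.projection.get("n_components", 30),
                n_cells=config.projection.get("n_cells", 100),
                depth=config.projection.get("depth"),
                k_neighbors=config.projection.get("k_neighbors", 15),
                seed=config.seed + 2,
            )
            frame = projection_results_frame(results)
            frame.to_csv(emit(outdir / "projection_results.tsv"), sep="\t")
            projection_rows = len(frame)
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    config_dict = config.to_dict()
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_genes_raw": matrix.n_genes,
        "n_genes_filtered": filtered.n_genes,
        "n_samples": matrix.n_samples,
        "n_contrasts": len(contrasts),
        "contrasts": [f"{t.group_a}|{t.group_b}" for t in contrasts],
        "stage_counts": stage_counts,
        "stringent_mode": assignment.stringent_mode,
        "n_projection_results": projection_rows,
        "outputs": {p.name: _sha256(p) for p in written if p.exists()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline finished: %d outputs in %s", len(written), outdir)
    return manifest
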