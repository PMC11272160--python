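"""Temporal wave classification from consecutive-timepoint contrasts.

Each gene is assigned to one of five activation waves — immediate, early,
intermediate-1, intermediate-2, late — by the *earliest* adjacent-timepoint
contrast at which it shows significant upregulation (FDR < 0.05 and fold
> 2, fold change positive).  The mapping from "first significant timepoint"
to wave is a configurable :class:`StageMap`; the default places 0.5 and
1 hr in the immediate wave, 3 and 6 hr in early, then 12 / 24 / 48 hr in
intermediate-1 / intermediate-2 / late.  Genes never significantly
upregulated are labeled ``unassigned``.

Only upregulation defines a wave; downregulated dynamics are visible in the
contrast tables but are not staged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import NormalizedMatrix
from .diffexpr import DETable, DEThresholds, de_test
from .errors import ConfigurationError

STAGE_LABELS = ("immediate", "early", "intermediate-1", "intermediate-2", "late")
UNASSIGNED = "unassigned"

ASSIGNMENT_COLUMNS = [
    "stage",
    "first_significant_timepoint_hr",
    "log2_fc_at_first",
    "fdr_at_first",
]


@dataclass(frozen=True)
class StageMap:
    """Ordered map from wave label to the timepoints (hours) that define it."""

    stages: tuple[tuple[str, frozenset], ...] = (
        ("immediate", frozenset({0.5, 1.0})),
        ("early", frozenset({3.0, 6.0})),
        ("intermediate-1", frozenset({12.0})),
        ("intermediate-2", frozenset({24.0})),
        ("late", frozenset({48.0})),
    )

    def __post_init__(self) -> None:
        seen: set[float] = set()
        for label, timepoints in self.stages:
            if seen & set(timepoints):
                raise ConfigurationError(
                    f"stage {label!r} reuses timepoints {sorted(seen & set(timepoints))}"
                )
            seen |= set(timepoints)

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.stages]

    def stage_for(self, timepoint_hr: float) -> str:
        for label, timepoints in self.stages:
            if timepoint_hr in timepoints:
                return label
        raise ConfigurationError(f"timepoint {timepoint_hr} hr is not covered by the stage map")

    def to_dict(self) -> dict:
        return {label: sorted(tp) for label, tp in self.stages}

    @classmethod
    def from_dict(cls, mapping: dict) -> "StageMap":
        return cls(tuple((label, frozenset(float(t) for t in tps)) for label, tps in mapping.items()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class StageAssignment:
    """Gene -> wave assignment with the contrast evidence that defined it.

    ``data`` is indexed by gene ID with columns ``stage``,
    ``first_significant_timepoint_hr`` (NaN when unassigned),
    ``log2_fc_at_first`` and ``fdr_at_first``.
    """

    data: pd.DataFrame
    stage_map: StageMap = field(default_factory=StageMap)
    stringent_mode: str = "none"

    @property
    def stages(self) -> pd.Series:
        return self.data["stage"]

    def genes_in_stage(self, label: str) -> list[str]:
        return list(self.data.index[self.data["stage"] == label])

    def stage_counts(self) -> dict[str, int]:
        counts = self.data["stage"].value_counts().to_dict()
        return {label: int(counts.get(label, 0)) for label in (*self.stage_map.labels, UNASSIGNED)}

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def consecutive_contrasts(
    norm: NormalizedMatrix,
    sample_meta: pd.DataFrame | None = None,
    method: str = "moderated_t",
) -> list[DETable]:
    """One differential-expression table per adjacent timepoint pair.

    Samples are grouped by ``timepoint_hr``; contrasts run in temporal
    order with group B the later timepoint, so positive fold changes mean
    upregulation over time.
    """
    meta = norm.sample_meta if sample_meta is None else sample_meta
    timepoint = meta["timepoint_hr"].astype(float)
    if timepoint.isna().any():
        bad = list(meta.index[timepoint.isna()])
        raise ValueError(f"samples without a timepoint: {bad[:5]}")
    grid = sorted(timepoint.unique())
    if len(grid) < 2:
        raise ValueError(f"need >= 2 timepoints, got {grid}")
    groups = {t: list(meta.index[timepoint == t]) for t in grid}
    for t, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"timepoint {t:g} hr has {len(samples)} replicate(s); need >= 2")

    tables = []
    for t_prev, t_next in zip(grid[:-1], grid[1:]):
        table = de_test(
            norm,
            groups[t_prev],
            groups[t_next],
            method=method,
            group_a_label=f"{t_prev:g}hr",
            group_b_label=f"{t_next:g}hr",
        )
        table.timepoint_a = float(t_prev)
        table.timepoint_b = float(t_next)
        tables.append(table)
    return tables


def assign_stages(
    contrasts: list[DETable],
    stage_map: StageMap = StageMap(),
    thresholds: DEThresholds = DEThresholds(),
) -> StageAssignment:
    """Stage each gene by its earliest significantly upregulated contrast."""
    if not contrasts:
        raise ValueError("no contrasts given")
    genes = contrasts[0].data.index
    for table in contrasts[1:]:
        if not table.data.index.equals(genes):
            raise ValueError("contrast tables do not share a gene universe")
    for table in contrasts:
        if table.timepoint_b is None:
            raise ConfigurationError(f"contrast {table.contrast} lacks timepoint annotation")
        stage_map.stage_for(table.timepoint_b)  # fail fast on uncovered grid

    n = len(genes)
    stage = np.full(n, UNASSIGNED, dtype=object)
    first_tp = np.full(n, np.nan)
    lfc_at = np.full(n, np.nan)
    fdr_at = np.full(n, np.nan)
    unassigned = np.ones(n, dtype=bool)
    cutoff = thresholds.min_abs_log2_fc
    for table in contrasts:
        data = table.data
        hit = (
            unassigned
            & (data["fdr"].to_numpy() < thresholds.fdr_max)
            & (data["log2_fc"].to_numpy() > cutoff)
        )
        if hit.any():
            label = stage_map.stage_for(table.timepoint_b)
            stage[hit] = label
            first_tp[hit] = table.timepoint_b
            lfc_at[hit] = data["log2_fc"].to_numpy()[hit]
            fdr_at[hit] = data["fdr"].to_numpy()[hit]
            unassigned &= ~hit

    frame = pd.DataFrame(
        {
            "stage": stage,
            "first_significant_timepoint_hr": first_tp,
            "log2_fc_at_first": lfc_at,
            "fdr_at_first": fdr_at,
        },
        index=genes,
    )
    return StageAssignment(frame, stage_map=stage_map)


def stringent_filter(
    assignment: StageAssignment,
    norm: NormalizedMatrix,
    mode: str = "sustained",
    margin: float = 1.0,
) -> StageAssignment:
    """Optional stricter wave membership: demand sustained activation.

    In ``sustained`` mode a staged gene is kept only if its mean log2
    expression at *every* timepoint at or after first activation stays
    above its pre-activation baseline mean plus ``margin`` (log2 units);
    transient spikes fall back to ``unassigned``.  ``none`` is the
    identity.  The applied mode is recorded on the result.
    """
    if mode not in ("sustained", "none"):
        raise ValueError(f"unknown stringent-filter mode {mode!r}")
    if mode == "none":
        return StageAssignment(assignment.data.copy(), assignment.stage_map, stringent_mode="none")

    log2 = norm.log2()
    timepoint = norm.sample_meta["timepoint_hr"].astype(float)
    grid = sorted(timepoint.dropna().unique())
    per_tp_mean = pd.DataFrame(
        {t: log2[timepoint.index[timepoint == t]].mean(axis=1) for t in grid}
    )

    data = assignment.data.copy()
    staged = data.index[data["stage"] != UNASSIGNED]
    for gene in staged:
        onset = data.at[gene, "first_significant_timepoint_hr"]
        baseline_tps = [t for t in grid if t < onset]
        post_tps = [t for t in grid if t >= onset]
        baseline = per_tp_mean.loc[gene, baseline_tps].mean() if baseline_tps else 0.0
        if not (per_tp_mean.loc[gene, post_tps] > baseline + margin).all():
            data.loc[gene, "stage"] = UNASSIGNED
            data.loc[gene, ["first_significant_timepoint_hr", "log2_fc_at_first", "fdr_at_first"]] = np.nan
    return StageAssignment(data, assignment.stage_map, stringent_mode="sustained")


def zscore_profiles(
    norm: NormalizedMatrix,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Row-Z-scored log2 profiles for heatmap display.

    Each gene's log2 values are centered and scaled to unit SD (population
    SD).  Constant genes get an all-zero row and are flagged in the second
    return value.
    """
    log2 = norm.log2() if genes is None else norm.log2().loc[list(genes)]
    values = log2.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe_sd
    z[constant] = 0.0
    frame = pd.DataFrame(z, index=log2.index, columns=log2.columns)
    flags = pd.Series(constant, index=log2.index, name="constant")
    return frame, flags
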