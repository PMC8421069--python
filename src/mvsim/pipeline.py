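"""Campaign orchestration and summary statistics.

A *campaign* runs the full experiment matrix on one network: baseline
simulation, MSC candidate selection with per-criterion bookkeeping, one
stroke per selected MSC (quota per MSC type), per-stroke local analyses,
and summary tables with bootstrap confidence intervals.  Raw per-vessel
tables are written next to the summaries so every aggregate is recomputable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graph import MVNGraph, write_network
from .hemodynamics import BoundaryConditions
from .rbc import TimeAveragedField
from .stroke import (SelectionResult, StrokeConfig, StrokeResult,
                     run_single_stroke, select_msc_candidates, _compute_field)
from .synthetic import GeneratorConfig, generate_lattice_mvn
from .topology import (box_inflow_difference, box_total_flow_difference,
                       categorize_box_vessels, count_flow_decrease,
                       msc_analysis_box, supplied_tissue_volume)
from .units import MMHG_TO_PA

MSC_TYPE_ORDER = ("2-2", "2-1", "1-2", "1-1")


@dataclass
class RunConfig:
    """Fully serializable campaign configuration."""
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    mode: str = "steady"               # "steady" | "rbc"
    seed: int = 0
    per_type_quota: int = 20
    stroke: StrokeConfig = field(default_factory=StrokeConfig)
    volume_factors: tuple[float, ...] = (1.0, 2.0, 3.0)
    n_bootstrap: int = 10_000
    out_dir: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump({"generator": asdict(self.generator),
                               "stroke": asdict(self.stroke),
                               "mode": self.mode, "seed": self.seed,
                               "per_type_quota": self.per_type_quota,
                               "volume_factors": list(self.volume_factors),
                               "n_bootstrap": self.n_bootstrap})


def bootstrap_ci(values, n_boot: int = 10_000, level: float = 0.95,
                 seed: int = 0, stat=np.median) -> tuple[float, float]:
    """Percentile bootstrap CI of a statistic (median by default)."""
    v = np.asarray([x for x in np.asarray(values, dtype=float)
                    if np.isfinite(x)])
    if len(v) == 0:
        return (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    stats = stat(v[idx], axis=1)
    a = (1.0 - level) / 2.0
    return (float(np.quantile(stats, a)), float(np.quantile(stats, 1.0 - a)))


# ----------------------------------------------------------------- summaries

def generation_table(results: list[StrokeResult]) -> pd.DataFrame:
    """Per-simulation, per-generation mean thresholded relative change of the
    vessels that experienced a flow *decrease*, plus the decrease frequency."""
    rows = []
    for res in results:
        for gen in range(-5, 6):
            if gen == 0:
                continue
            vids = res.generations.at(gen)
            if not vids:
                continue
            dq = res.dq.loc[vids].dropna()
            dec = dq[dq < 0]
            rows.append((res.msc, res.msc_type, gen,
                         float(dec.mean()) if len(dec) else np.nan,
                         len(dec), len(dq),
                         len(dec) / len(dq) if len(dq) else np.nan))
    return pd.DataFrame(rows, columns=["msc", "msc_type", "generation",
                                       "mean_dq_decrease", "n_decrease",
                                       "n_vessels", "decrease_frequency"])


def summarize_generations(gen_table: pd.DataFrame, n_boot: int = 10_000,
                          seed: int = 0) -> pd.DataFrame:
    """Median (over simulations) of the per-simulation generation means, with
    bootstrap confidence intervals."""
    rows = []
    for (mt, gen), grp in gen_table.groupby(["msc_type", "generation"]):
        vals = grp["mean_dq_decrease"].dropna().to_numpy()
        if len(vals) == 0:
            continue
        lo, hi = bootstrap_ci(vals, n_boot=n_boot, seed=seed)
        rows.append((mt, gen, float(np.median(vals)), lo, hi, len(vals)))
    return pd.DataFrame(rows, columns=["msc_type", "generation", "median_dq",
                                       "ci_lo", "ci_hi", "n_sims"])


def type_census(g: MVNGraph, field_: TimeAveragedField,
                candidates: list, tissue_volumes: pd.Series | None = None,
                edge_path_counts: dict[int, int] | None = None,
                n_boot: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Per-MSC-type frequency / median flow / median supplied tissue volume /
    median DA->AV path count over the eligible capillaries."""
    absq = field_.mean_abs_q if field_.mean_abs_q is not None else field_.q.abs()
    rows = []
    by_type: dict[str, list[int]] = {t: [] for t in MSC_TYPE_ORDER}
    for c in candidates:
        if c.msc_type in by_type:
            by_type[c.msc_type].append(c.vessel)
    n_total = sum(len(v) for v in by_type.values())
    for mt in MSC_TYPE_ORDER:
        vids = by_type[mt]
        flows = absq.loc[vids].to_numpy() if vids else np.array([])
        row = {"msc_type": mt, "n": len(vids),
               "frequency": len(vids) / n_total if n_total else np.nan,
               "median_flow": float(np.median(flows)) if len(flows) else np.nan}
        if tissue_volumes is not None and vids:
            tv = tissue_volumes.loc[vids].to_numpy()
            row["median_supplied_volume"] = float(np.median(tv))
        if edge_path_counts is not None and vids:
            pc = [edge_path_counts.get(v, 0) for v in vids]
            row["median_path_count"] = float(np.median(pc))
        rows.append(row)
    return pd.DataFrame(rows)


def box_metric_table(g: MVNGraph, results: list[StrokeResult],
                     volume_factors=(1.0, 2.0, 3.0)) -> pd.DataFrame:
    """Per-stroke analysis-box perfusion metrics at growing volume factors."""
    rows = []
    for res in results:
        for vf in volume_factors:
            box = msc_analysis_box(g, res.msc, volume_nl=0.2 * vf)
            d_in = box_inflow_difference(g, res.baseline, res.stroke, box)
            d_tot = box_total_flow_difference(g, res.baseline, res.stroke, box)
            n_dec = count_flow_decrease(g, res.baseline, res.stroke, box,
                                        exclude=set(res.occluded))
            rows.append((res.msc, res.msc_type, vf, d_in, d_tot, n_dec))
    return pd.DataFrame(rows, columns=["msc", "msc_type", "volume_factor",
                                       "inflow_diff", "totalflow_diff",
                                       "n_decrease"])


def category_flow_table(g: MVNGraph, results: list[StrokeResult],
                        volume_factors=(1.0, 2.0, 3.0)) -> pd.DataFrame:
    """Relative total-flow difference per vessel category (upstream/downstream,
    parallel, distant) at growing volume factors."""
    from .topology import box_total_flow, clipped_centerline_length
    rows = []
    for res in results:
        for vf in volume_factors:
            box = msc_analysis_box(g, res.msc, volume_nl=0.2 * vf)
            cats = categorize_box_vessels(g, res.baseline, res.msc, box,
                                          genmap=res.generations)
            for name, vset in (("updown", cats.updown),
                               ("parallel", cats.parallel),
                               ("distant", cats.distant)):
                tb = ts = 0.0
                for vid in vset:
                    ln = clipped_centerline_length(g, vid, box)
                    tb += abs(float(res.baseline.q.loc[vid])) * ln
                    ts += abs(float(res.stroke.q.loc[vid])) * ln
                diff = (ts - tb) / tb if tb > 0 else np.nan
                rows.append((res.msc, res.msc_type, vf, name, len(vset), diff))
    return pd.DataFrame(rows, columns=["msc", "msc_type", "volume_factor",
                                       "category", "n_vessels", "flow_diff"])


# ------------------------------------------------------------------ campaign

def run_campaign(cfg: RunConfig,
                 network: tuple[MVNGraph, BoundaryConditions] | None = None
                 ) -> dict:
    """Execute the full campaign; returns the artifact dictionary and, when
    ``cfg.out_dir`` is set, writes CSV/JSON outputs there.

    Deterministic: identical (network, cfg, seed) give identical outputs.
    """
    if network is None:
        gen_cfg = cfg.generator
        gen_cfg.seed = cfg.seed
        g, bc = generate_lattice_mvn(gen_cfg)
    else:
        g, bc = network
    baseline = _compute_field(g, bc, cfg.mode, cfg.seed)
    selection = select_msc_candidates(g, baseline, cfg.stroke)

    # quota per type, lowest vessel id first (deterministic)
    chosen: list = []
    for mt in MSC_TYPE_ORDER:
        of_type = sorted([c for c in selection.candidates if c.msc_type == mt],
                         key=lambda c: c.vessel)
        chosen.extend(of_type[:cfg.per_type_quota])

    results = [run_single_stroke(g, c.vessel, bc, mode=cfg.mode, seed=cfg.seed,
                                 cfg=cfg.stroke, baseline=baseline)
               for c in chosen]
    gen_tab = generation_table(results)
    gen_sum = summarize_generations(gen_tab, n_boot=cfg.n_bootstrap,
                                    seed=cfg.seed)
    box_tab = box_metric_table(g, results, cfg.volume_factors)
    census = type_census(g, baseline, selection.candidates,
                         n_boot=cfg.n_bootstrap, seed=cfg.seed)
    artifacts = {
        "graph": g, "bc": bc, "baseline": baseline, "selection": selection,
        "results": results, "generation_table": gen_tab,
        "generation_summary": gen_sum, "box_metrics": box_tab,
        "type_census": census,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_network(g, out / "network")
        pd.DataFrame({"node_id": list(bc.pressures),
                      "pressure_mmhg": [p / MMHG_TO_PA
                                        for p in bc.pressures.values()]}
                     ).to_csv(out / "network" / "bc.csv", index=False)
        gen_tab.to_csv(out / "generations_raw.csv", index=False)
        gen_sum.to_csv(out / "generations_summary.csv", index=False)
        box_tab.to_csv(out / "box_metrics.csv", index=False)
        census.to_csv(out / "type_census.csv", index=False)
        per_vessel = pd.DataFrame({
            f"dq_msc{res.msc}": res.dq for res in results})
        per_vessel.to_csv(out / "dq_per_vessel.csv")
        (out / "selection_counts.json").write_text(json.dumps(
            {name: n for name, n in selection.surviving_counts}, indent=2))
        (out / "config.yaml").write_text(cfg.to_yaml())
    return artifacts
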